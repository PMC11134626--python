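import numpy as np
import pytest

from longenrich import Hyperparams, LongitudinalCohort, SimConfig, simulate_cohort


@pytest.fixture
def tiny_cohort():
    """Hand-built 3-participant cohort with two modalities."""
    rng = np.random.default_rng(42)
    d, n = 4, 3
    histories = [rng.standard_normal((d, k)) for k in (3, 2, 4)]
    return LongitudinalCohort(
        histories=histories,
        last_records=rng.standard_normal((d, n)),
        modality_slices={"A": slice(0, 2), "B": slice(2, 4)},
        snp_matrix=rng.standard_normal((6, n)),
        snp_groups=[np.array([0, 1, 2]), np.array([3, 4, 5])],
        labels=rng.standard_normal((2, 2)),
        ids=["p1", "p2", "p3"],
    )


@pytest.fixture
def small_sim():
    """Small simulated cohort + truth, noisy, generic."""
    cfg = SimConfig(
        n=10, l=7, d_per_modality={"VBM": 4, "FS": 4}, d_snp=12, K=3, c=2,
        r1_true=3, r2_true=2, active_group_count=2,
        noise_sd_imaging=0.2, noise_sd_snp=0.1, noise_sd_labels=0.1,
        visit_count_range=(4, 6), seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def small_hp():
    return Hyperparams(r1=3, r2=2, max_outer=6, max_inner=40,
                       tol_residual=1e-4, seed=0)
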