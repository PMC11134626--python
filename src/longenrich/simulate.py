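"""Synthetic cohorts with the statistical structure the model assumes.

Each participant's visits follow a smooth low-rank trajectory inside a
participant-specific subspace, the last retained visit encodes the shared
latent representation, the SNP matrix is a group-sparse factorization of
that same representation, and labels are a linear read-out of it. The
latest visit is dropped with a configurable probability to emulate missing
records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .core import LongitudinalCohort, validate_cohort

__all__ = ["SimConfig", "GroundTruth", "simulate_cohort", "inject_outliers"]


@dataclass
class SimConfig:
    n: int = 50
    l: int = 40
    d_per_modality: dict = field(default_factory=lambda: {"VBM": 15, "FS": 15})
    d_snp: int = 40
    K: int = 8
    c: int = 2
    r1_true: int = 5
    r2_true: int = 3
    visit_count_range: tuple = (4, 7)   # total records n_i + 1 before discard
    p_discard_last: float = 0.5
    noise_sd_imaging: float = 0.05
    noise_sd_snp: float = 0.05
    noise_sd_labels: float = 0.05
    outlier_fraction: float = 0.0
    outlier_scale: float = 10.0
    active_group_count: int = 8
    subspace_jitter: float = 0.3    # per-participant deviation from the shared basis
    coeff_decay: float = 0.7        # shared variance decay over trajectory coefficients
    coeff_scale: float = 3.0        # overall trajectory amplitude (sets signal-to-noise)
    coeff_wander: float = 1.0       # per-visit in-subspace variation relative to profile
    seed: int = 0

    @property
    def d(self) -> int:
        return sum(self.d_per_modality.values())

    def validate(self) -> None:
        if not (0.0 <= self.p_discard_last <= 1.0):
            raise ValueError("p_discard_last must be in [0, 1]")
        if not (0.0 <= self.outlier_fraction <= 1.0):
            raise ValueError("outlier_fraction must be in [0, 1]")
        if min(self.n, self.d_snp, self.K, self.c,
               self.r1_true, self.r2_true, self.d) < 1:
            raise ValueError("all dimensions must be positive")
        if not (1 <= self.l <= self.n):
            raise ValueError("l must be in 1..n")
        if self.active_group_count > self.K:
            raise ValueError("active_group_count exceeds K")
        if self.visit_count_range[0] < 2:
            raise ValueError("participants need at least 2 records")
        if self.r1_true > self.d or self.r2_true > self.r1_true:
            raise ValueError("require r2_true <= r1_true <= d")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Latent quantities the generator used, for recovery tests."""

    G_star: np.ndarray                  # r2_true x n shared representation
    H0_star: np.ndarray                 # d_snp x r2_true, group-sparse rows
    subspaces_star: list[np.ndarray]    # per-participant orthonormal bases
    U_star: np.ndarray                  # r2_true x c
    active_groups: np.ndarray           # indices of groups with support
    discarded: np.ndarray               # bool per participant: last visit dropped


def _partition(total: int, k: int) -> list[np.ndarray]:
    """Split 0..total-1 into k contiguous groups of near-equal size."""
    bounds = np.linspace(0, total, k + 1).astype(int)
    return [np.arange(bounds[j], bounds[j + 1]) for j in range(k)]


def simulate_cohort(cfg: SimConfig) -> tuple[LongitudinalCohort, GroundTruth]:
    """Generate a cohort plus its generating ground truth; seeded, deterministic."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    d, n, r1, r2 = cfg.d, cfg.n, cfg.r1_true, cfg.r2_true

    G_star = rng.standard_normal((r2, n))
    U_star = rng.standard_normal((r2, cfg.c))

    groups = _partition(cfg.d_snp, cfg.K)
    active = np.sort(rng.choice(cfg.K, size=cfg.active_group_count, replace=False))
    H0_star = np.zeros((cfg.d_snp, r2))
    for k in active:
        H0_star[groups[k]] = rng.standard_normal((len(groups[k]), r2))

    snp = H0_star @ G_star
    snp = snp + cfg.noise_sd_snp * rng.standard_normal(snp.shape)

    labels_full = U_star.T @ G_star
    labels_full = labels_full + cfg.noise_sd_labels * rng.standard_normal(labels_full.shape)

    # Shared variance profile over coefficient directions: dominant modes of
    # variation are common to the cohort (what makes per-participant
    # principal directions comparable at all), with decaying strength.
    profile = cfg.coeff_scale * cfg.coeff_decay ** np.arange(r1)
    # maps the shared representation into the coefficient space: a
    # well-conditioned (orthogonal, profile-scaled) block on the leading
    # coefficients so the latent representation is linearly recoverable
    # from the strongest, best-determined coordinates
    O_map = np.linalg.qr(rng.standard_normal((r2, r2)))[0]
    T_map = np.zeros((r1, r2))
    T_map[:r2] = profile[:r2, None] * O_map

    # participants share one imaging basis up to a controllable perturbation;
    # the projection-consistency coupling of the model presumes exactly this
    Q_shared = np.linalg.qr(rng.standard_normal((d, r1)))[0]

    lo, hi = cfg.visit_count_range
    totals = rng.integers(lo, hi + 1, size=n)
    discard = rng.random(n) < cfg.p_discard_last

    histories: list[np.ndarray] = []
    last_cols: list[np.ndarray] = []
    subspaces: list[np.ndarray] = []
    for i in range(n):
        m = int(totals[i]) - int(discard[i])        # retained records
        if m < 2:
            raise ValueError(
                f"participant {i}: only {m} record(s) remain after discard; "
                "increase visit_count_range"
            )
        # jitter is relative to the unit-norm basis columns
        Q, _ = np.linalg.qr(
            Q_shared
            + (cfg.subspace_jitter / np.sqrt(d)) * rng.standard_normal((d, r1))
        )
        subspaces.append(Q)
        start = 0.3 * profile * rng.standard_normal(r1)
        final = T_map @ G_star[:, i]
        t = np.linspace(0.0, 1.0, m) ** 4   # late-acting ramp toward the endpoint
        # smooth drift from a random start to the latent-encoding endpoint,
        # plus per-visit in-subspace variation so histories have full rank r1
        coeffs = np.outer(start, 1.0 - t) + np.outer(final, t)
        # independent per-visit variation carrying the shared profile; this,
        # not the two-point drift, is what gives histories full rank r1 and
        # per-participant principal axes comparable across the cohort
        coeffs[:, :-1] += cfg.coeff_wander * profile[:, None] * rng.standard_normal((r1, m - 1))
        visits = Q @ coeffs
        visits = visits + cfg.noise_sd_imaging * rng.standard_normal(visits.shape)
        histories.append(visits[:, :-1])
        last_cols.append(visits[:, -1])

    slices: dict[str, slice] = {}
    offset = 0
    for name, dm in cfg.d_per_modality.items():
        slices[name] = slice(offset, offset + dm)
        offset += dm

    cohort = LongitudinalCohort(
        histories=histories,
        last_records=np.column_stack(last_cols),
        modality_slices=slices,
        snp_matrix=snp,
        snp_groups=groups,
        labels=labels_full[:, : cfg.l],
        ids=[f"P{i:04d}" for i in range(n)],
    )
    if cfg.outlier_fraction > 0:
        cohort = inject_outliers(
            cohort, cfg.outlier_fraction, cfg.outlier_scale,
            seed=int(rng.integers(2 ** 31)),
        )

    truth = GroundTruth(
        G_star=G_star, H0_star=H0_star, subspaces_star=subspaces,
        U_star=U_star, active_groups=active, discarded=discard,
    )
    report = validate_cohort(cohort)
    assert report.valid, report.violations
    return cohort, truth


def inject_outliers(cohort: LongitudinalCohort, fraction: float,
                    scale: float, seed: int = 0) -> LongitudinalCohort:
    """Corrupt a share of visit columns with additive heavy-tailed noise.

    The pool of columns is every history column plus every last record;
    ``round(fraction * pool)`` columns are drawn without replacement and
    perturbed by ``scale`` times the per-feature standard deviation times
    standard-Cauchy draws. Untouched columns are bitwise identical.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    out = cohort.copy()
    slots: list[tuple[int, int]] = []               # (participant, column); -1 = last record
    for i, X in enumerate(cohort.histories):
        slots.extend((i, j) for j in range(X.shape[1]))
    slots.extend((i, -1) for i in range(cohort.n))

    n_hit = int(round(fraction * len(slots)))
    if n_hit == 0 or scale == 0.0:
        return out
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(slots), size=n_hit, replace=False)

    all_cols = np.hstack([*cohort.histories, cohort.last_records])
    feat_sd = np.maximum(all_cols.std(axis=1), 1e-12)
    for idx in chosen:
        i, j = slots[idx]
        noise = scale * feat_sd * rng.standard_cauchy(cohort.d)
        if j < 0:
            out.last_records[:, i] += noise
        else:
            out.histories[i][:, j] += noise
    return out
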