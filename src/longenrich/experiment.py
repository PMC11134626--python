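"""Reproducible end-to-end experiment: split, transductive fit, downstream RMSE.

The fit is transductive: imaging and SNP features of every participant are
visible to the solver, clinical scores only for the training split. Test
labels are read exclusively at final scoring.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field

import numpy as np

from .core import LongitudinalCohort, Hyperparams
from .importance import compare_representations
from .solver import fit

__all__ = ["ExperimentConfig", "run_experiment", "random_search", "split_cohort"]


@dataclass
class ExperimentConfig:
    hyperparams: Hyperparams = field(default_factory=Hyperparams)
    split_fraction: float = 0.8
    cv_folds: int = 5
    downstream_model: str = "ridge"
    standardize: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.split_fraction < 1.0):
            raise ValueError("split_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def split_cohort(cohort: LongitudinalCohort, full_labels: np.ndarray,
                 split_fraction: float, seed: int
                 ) -> tuple[LongitudinalCohort, np.ndarray, np.ndarray, np.ndarray]:
    """Random train/test split; returns a cohort reordered train-first.

    ``full_labels`` is ``c x n`` (scores for every participant). The
    returned cohort carries labels for the training participants only;
    test labels are returned separately so callers can keep them isolated
    until final scoring.
    """
    n = cohort.n
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(split_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    train_idx = perm[:n_train]
    test_idx = perm[n_train:]
    order = np.concatenate([train_idx, test_idx])

    reordered = LongitudinalCohort(
        histories=[cohort.histories[i] for i in order],
        last_records=cohort.last_records[:, order],
        modality_slices=dict(cohort.modality_slices),
        snp_matrix=cohort.snp_matrix[:, order],
        snp_groups=[g.copy() for g in cohort.snp_groups],
        labels=full_labels[:, train_idx],
        ids=[cohort.ids[i] for i in order],
        original_order=order,
    )
    return reordered, full_labels[:, test_idx], train_idx, test_idx


def run_experiment(cohort: LongitudinalCohort, full_labels: np.ndarray,
                   cfg: ExperimentConfig) -> dict:
    """Run the full protocol and return a JSON-serializable report."""
    cfg.validate()
    ordered, y_test, train_idx, test_idx = split_cohort(
        cohort, full_labels, cfg.split_fraction, cfg.seed
    )
    n_train = len(train_idx)

    result = fit(ordered, cfg.hyperparams, standardize=cfg.standardize)

    Z = result.Z
    X = ordered.last_records
    y_train = ordered.labels
    comparison = compare_representations(
        Z[:, :n_train], y_train, Z[:, n_train:], y_test,
        X[:, :n_train], X[:, n_train:],
        model=cfg.downstream_model, cv_folds=cfg.cv_folds,
    )

    cfg_json = json.dumps(cfg.to_dict(), sort_keys=True)
    report = {
        "config": cfg.to_dict(),
        "provenance": {
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "seed": cfg.seed,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
        "n_train": int(n_train),
        "n_test": int(len(test_idx)),
        "train_idx": train_idx.tolist(),
        "test_idx": test_idx.tolist(),
        "converged": result.converged,
        "n_outer": result.n_outer,
        "objective_history": [float(v) for v in result.objective_history],
        "rmse_enriched": comparison["enriched"]["rmse"],
        "rmse_original": comparison["original"]["rmse"],
        "mean_rmse_enriched": comparison["enriched"]["mean_rmse"],
        "mean_rmse_original": comparison["original"]["mean_rmse"],
        "relative_change": comparison["relative_change"],
        "predictions_enriched": comparison["enriched"]["predictions"].tolist(),
        "predictions_original": comparison["original"]["predictions"].tolist(),
        "y_test": y_test.tolist(),
    }
    return report


def random_search(grids: dict[str, list], budget: int, seed: int,
                  objective_fn) -> tuple[dict, float, list]:
    """Randomized hyperparameter search with incumbent-keeping exploration.

    The first candidate samples every parameter from its grid. Each later
    candidate keeps, independently per parameter with probability 1/2, the
    best value found so far, otherwise resamples from the grid. Returns
    ``(best_config, best_value, history)`` minimizing ``objective_fn``.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if not grids or any(len(v) == 0 for v in grids.values()):
        raise ValueError("grids must be nonempty")
    rng = np.random.default_rng(seed)
    names = list(grids)

    best_cfg: dict | None = None
    best_val = np.inf
    history = []
    for step in range(budget):
        cand = {}
        for name in names:
            if step > 0 and best_cfg is not None and rng.random() < 0.5:
                cand[name] = best_cfg[name]
            else:
                cand[name] = grids[name][rng.integers(len(grids[name]))]
        val = float(objective_fn(cand))
        history.append({"step": step, "config": dict(cand), "value": val})
        if val < best_val:
            best_val = val
            best_cfg = dict(cand)
    return best_cfg, best_val, history
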