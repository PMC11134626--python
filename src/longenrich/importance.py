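"""Biomarker relevance scores and the downstream prediction harness.

The relevance of imaging feature ``q`` is the summed l1 norm of row ``q``
across all participant projections; SNP relevance is the l1 norm of the
SNP's row of the genetic loading matrix, aggregated per group as mean and
standard deviation of member scores.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge
from sklearn.metrics import mean_squared_error
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

__all__ = [
    "imaging_importance", "snp_importance", "group_importance",
    "downstream_rmse", "compare_representations",
]

_PARAM_GRID = [10.0 ** p for p in range(3, -4, -1)]  # 1e3 .. 1e-3


def imaging_importance(W: Sequence[np.ndarray],
                       modality_slices: dict[str, slice] | None = None
                       ) -> pd.DataFrame:
    """Per-feature relevance: score_q = sum_i ||row q of W_i||_1.

    Returns a frame with columns ``feature, modality, score, rank`` where
    rank 1 is the highest score; ties break by feature index.
    """
    if not W:
        raise ValueError("empty projection list")
    shapes = {w.shape for w in W}
    if len(shapes) != 1:
        raise ValueError("inconsistent projection shapes")
    scores = np.sum([np.abs(w).sum(axis=1) for w in W], axis=0)
    d = scores.shape[0]
    modality = np.array(["all"] * d, dtype=object)
    if modality_slices:
        for name, sl in modality_slices.items():
            modality[sl] = name
    order = np.lexsort((np.arange(d), -scores))
    rank = np.empty(d, dtype=int)
    rank[order] = np.arange(1, d + 1)
    return pd.DataFrame({
        "feature": np.arange(d),
        "modality": modality,
        "score": scores,
        "rank": rank,
    })


def snp_importance(H0: np.ndarray, groups: Sequence[np.ndarray]) -> pd.DataFrame:
    """Per-SNP relevance: l1 norm of the SNP's row of the loading matrix."""
    H0 = np.asarray(H0, dtype=float)
    scores = np.abs(H0).sum(axis=1)
    group_id = np.full(H0.shape[0], -1, dtype=int)
    for k, g in enumerate(groups):
        group_id[np.asarray(g)] = k
    if (group_id < 0).any():
        raise ValueError("groups do not cover all SNP rows")
    d = scores.shape[0]
    order = np.lexsort((np.arange(d), -scores))
    rank = np.empty(d, dtype=int)
    rank[order] = np.arange(1, d + 1)
    return pd.DataFrame({
        "snp": np.arange(d),
        "group": group_id,
        "score": scores,
        "rank": rank,
    })


def group_importance(H0: np.ndarray, groups: Sequence[np.ndarray],
                     aggregate: str = "mean") -> pd.DataFrame:
    """Aggregate per-SNP scores per group (mean by default, sum optional)."""
    per_snp = snp_importance(H0, groups)
    rows = []
    for k, g in enumerate(groups):
        member = per_snp.loc[per_snp["group"] == k, "score"].to_numpy()
        agg = member.sum() if aggregate == "sum" else member.mean()
        rows.append({"group": k, "size": len(member),
                     "score": agg, "sd": member.std()})
    frame = pd.DataFrame(rows)
    order = np.lexsort((frame["group"].to_numpy(), -frame["score"].to_numpy()))
    rank = np.empty(len(frame), dtype=int)
    rank[order] = np.arange(1, len(frame) + 1)
    frame["rank"] = rank
    return frame


def _make_search(model: str, cv_folds: int) -> GridSearchCV:
    if model == "ridge":
        est = Pipeline([("scale", StandardScaler()), ("reg", Ridge())])
        grid = {"reg__alpha": _PARAM_GRID}
    elif model == "svr":
        est = Pipeline([("scale", StandardScaler()), ("reg", SVR())])
        grid = {"reg__kernel": ["sigmoid", "rbf"], "reg__C": _PARAM_GRID}
    else:
        raise ValueError(f"unknown downstream model {model!r}")
    return GridSearchCV(
        est, grid, cv=KFold(n_splits=cv_folds),
        scoring="neg_root_mean_squared_error", n_jobs=1,
    )


def downstream_rmse(train_X: np.ndarray, train_y: np.ndarray,
                    test_X: np.ndarray, test_y: np.ndarray,
                    model: str = "ridge", cv_folds: int = 5) -> dict:
    """Cross-validated downstream regression; per-score test RMSE.

    ``train_X``/``test_X`` are features-x-samples; ``train_y``/``test_y``
    are scores-x-samples (one regressor fitted per score row). Model
    selection uses the training data only.
    """
    train_X = np.atleast_2d(train_X)
    test_X = np.atleast_2d(test_X)
    train_y = np.atleast_2d(train_y)
    test_y = np.atleast_2d(test_y)
    if train_X.shape[1] != train_y.shape[1]:
        raise ValueError("mismatched train sample counts")
    if test_X.shape[1] != test_y.shape[1]:
        raise ValueError("mismatched test sample counts")
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    if train_X.shape[1] < cv_folds:
        raise ValueError("fewer training samples than CV folds")

    rmses, params, preds = [], [], []
    for q in range(train_y.shape[0]):
        search = _make_search(model, cv_folds)
        search.fit(train_X.T, train_y[q])
        pred = search.predict(test_X.T)
        rmses.append(float(np.sqrt(mean_squared_error(test_y[q], pred))))
        params.append({k: (v if isinstance(v, str) else float(v))
                       for k, v in search.best_params_.items()})
        preds.append(pred)
    return {
        "model": model,
        "rmse": rmses,
        "mean_rmse": float(np.mean(rmses)),
        "best_params": params,
        "predictions": np.array(preds),
    }


def compare_representations(enriched_train, y_train, enriched_test, y_test,
                            original_train, original_test,
                            model: str = "ridge", cv_folds: int = 5) -> dict:
    """Test RMSE for enriched vs original features plus the relative change.

    A negative ``relative_change`` means the enriched representation has the
    lower error (the effect the enrichment model aims for).
    """
    enr = downstream_rmse(enriched_train, y_train, enriched_test, y_test,
                          model=model, cv_folds=cv_folds)
    orig = downstream_rmse(original_train, y_train, original_test, y_test,
                           model=model, cv_folds=cv_folds)
    rel = (enr["mean_rmse"] - orig["mean_rmse"]) / orig["mean_rmse"]
    return {"enriched": enr, "original": orig, "relative_change": float(rel)}
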