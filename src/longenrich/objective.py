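"""Objective terms of the enrichment model.

Evaluates the eight terms of the non-smooth objective, the nine reweighting
objects of its smooth quadratic surrogate, and the surrogate itself.
All ``l2,1`` norms are row-wise sums of row l2 norms, exactly as the model
defines them.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import scipy.linalg

from .core import LongitudinalCohort, Hyperparams, ModelState, WeightMatrices

__all__ = [
    "l21_norm", "group_l2_norm", "trace_norm", "unfold", "refold",
    "enrich_all", "TermValues", "eval_objective", "reweight", "eval_smoothed",
]


def l21_norm(M: np.ndarray) -> float:
    """Sum of row l2 norms; 0 for an empty matrix."""
    M = np.asarray(M, dtype=float)
    if M.size == 0:
        return 0.0
    return float(np.linalg.norm(M, axis=1).sum())


def group_l2_norm(H0: np.ndarray, groups: Sequence[np.ndarray]) -> float:
    """Sum over row-blocks of each block's Frobenius norm.

    ``groups`` must partition the rows of ``H0``.
    """
    H0 = np.asarray(H0, dtype=float)
    flat = np.concatenate([np.asarray(g) for g in groups]) if groups else np.array([])
    if sorted(flat.tolist()) != list(range(H0.shape[0])):
        raise ValueError("groups do not partition the rows of H0")
    return float(sum(np.linalg.norm(H0[np.asarray(g)]) for g in groups))


def trace_norm(M: np.ndarray) -> float:
    """Sum of singular values."""
    M = np.asarray(M, dtype=float)
    if M.size == 0:
        return 0.0
    return float(np.linalg.svd(M, compute_uv=False).sum())


def unfold(W: Sequence[np.ndarray], mode: int) -> np.ndarray:
    """Unfold the projection stack along a mode.

    mode 1: ``[W_1, ..., W_n]`` (``d x r1*n``); mode 2: ``[W_1^T, ..., W_n^T]``
    (``r1 x d*n``).
    """
    shapes = {w.shape for w in W}
    if len(shapes) != 1:
        raise ValueError(f"mixed projection shapes: {sorted(shapes)}")
    if mode == 1:
        return np.hstack(list(W))
    if mode == 2:
        return np.hstack([w.T for w in W])
    raise ValueError(f"mode must be 1 or 2, got {mode}")


def refold(M: np.ndarray, mode: int, d: int, r1: int) -> list[np.ndarray]:
    """Inverse of :func:`unfold`."""
    if mode == 1:
        if M.shape[0] != d or M.shape[1] % r1:
            raise ValueError("unfolding shape inconsistent with (d, r1)")
        return [M[:, j:j + r1].copy() for j in range(0, M.shape[1], r1)]
    if mode == 2:
        if M.shape[0] != r1 or M.shape[1] % d:
            raise ValueError("unfolding shape inconsistent with (d, r1)")
        return [M[:, j:j + d].T.copy() for j in range(0, M.shape[1], d)]
    raise ValueError(f"mode must be 1 or 2, got {mode}")


def enrich_all(cohort: LongitudinalCohort, W: Sequence[np.ndarray]) -> np.ndarray:
    """Enriched matrix Z (r1 x n) with column i = W_i^T x_i."""
    X = cohort.last_records
    return np.column_stack([W[i].T @ X[:, i] for i in range(cohort.n)])


@dataclass
class TermValues:
    """The individual terms of the full objective plus their weighted sum."""

    label_fit: float
    pca_fit: float
    imaging_factor: float
    snp_factor: float
    align: float
    group_reg: float
    trace_reg: float
    sparsity_reg: float
    total: float

    def to_dict(self) -> dict:
        return asdict(self)


def _check_state_shapes(state: ModelState, cohort: LongitudinalCohort) -> None:
    d, n, c = cohort.d, cohort.n, cohort.n_scores
    if len(state.W) != n:
        raise ValueError(f"{len(state.W)} projections for {n} participants")
    if state.W[0].shape[0] != d:
        raise ValueError(f"projection rows {state.W[0].shape[0]} != d={d}")
    if state.F.shape != (c, n):
        raise ValueError(f"F has shape {state.F.shape}, expected {(c, n)}")
    if state.H0.shape[0] != cohort.d_snp:
        raise ValueError(f"H0 rows {state.H0.shape[0]} != d_snp={cohort.d_snp}")


def eval_objective(state: ModelState, cohort: LongitudinalCohort,
                   hp: Hyperparams) -> TermValues:
    """Evaluate every term of the full (non-smooth) objective."""
    _check_state_shapes(state, cohort)
    label_fit = l21_norm(state.F - state.U.T @ state.G1)
    pca_fit = sum(
        l21_norm(X - W @ (W.T @ X))
        for X, W in zip(cohort.histories, state.W)
    )
    Z = enrich_all(cohort, state.W)
    imaging_factor = l21_norm(Z - state.H1 @ state.G1)
    snp_factor = l21_norm(cohort.snp_matrix - state.H0 @ state.G0)
    align = l21_norm(state.G1 - state.G0)
    group_reg = group_l2_norm(state.H0, cohort.snp_groups)
    trace_reg = trace_norm(unfold(state.W, 1)) + trace_norm(unfold(state.W, 2))
    sparsity_reg = float(np.abs(state.U).sum())
    total = (
        label_fit
        + hp.gamma1 * pca_fit
        + hp.gamma2 * imaging_factor
        + hp.gamma3 * snp_factor
        + hp.gamma4 * align
        + hp.gamma5 * group_reg
        + hp.gamma6 * trace_reg
        + hp.gamma7 * sparsity_reg
    )
    return TermValues(label_fit, pca_fit, imaging_factor, snp_factor,
                      align, group_reg, trace_reg, sparsity_reg, total)


def _row_weights(R: np.ndarray, delta: float) -> np.ndarray:
    # 1 / (2 sqrt(||row||^2 + delta)) per row; inf is the honest delta=0
    # limit for an exactly-zero row
    with np.errstate(divide="ignore"):
        return 1.0 / (2.0 * np.sqrt(np.einsum("ij,ij->i", R, R) + delta))


def inv_sqrt_gram(M: np.ndarray, delta: float) -> np.ndarray:
    """(1/2) (M M^T + delta I)^(-1/2) via symmetric eigendecomposition.

    The Gram matrix is symmetrized before decomposition and eigenvalues are
    floored at zero before the delta shift (floating-point hygiene).
    """
    G = M @ M.T
    G = 0.5 * (G + G.T)
    evals, evecs = scipy.linalg.eigh(G)
    evals = np.maximum(evals, 0.0) + delta
    return 0.5 * (evecs * evals ** -0.5) @ evecs.T


def reweight(state: ModelState, cohort: LongitudinalCohort,
             delta: float) -> WeightMatrices:
    """Build all nine reweighting objects from the current state."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    d1 = _row_weights(state.U.T @ state.G1 - state.F, delta)
    d2 = [
        _row_weights(X - W @ (W.T @ X), delta)
        for X, W in zip(cohort.histories, state.W)
    ]
    Z = enrich_all(cohort, state.W)
    d3 = _row_weights(Z - state.H1 @ state.G1, delta)
    d4 = _row_weights(cohort.snp_matrix - state.H0 @ state.G0, delta)
    d5 = _row_weights(state.G1 - state.G0, delta)
    d6_blocks = np.array([
        0.5 * (np.linalg.norm(state.H0[g]) ** 2 + delta) ** -0.5
        for g in cohort.snp_groups
    ])
    D7 = inv_sqrt_gram(unfold(state.W, 1), delta)
    D8 = inv_sqrt_gram(unfold(state.W, 2), delta)
    d9 = [
        1.0 / (2.0 * np.sqrt(state.U[:, q] ** 2 + delta))
        for q in range(state.U.shape[1])
    ]
    return WeightMatrices(d1, d2, d3, d4, d5, d6_blocks, D7, D8, d9)


def _weighted_sq(R: np.ndarray, diag: np.ndarray) -> float:
    # tr(R^T diag(w) R) = sum_j w_j ||row_j||^2
    return float(np.einsum("i,ij,ij->", diag, R, R))


def eval_smoothed(state: ModelState, cohort: LongitudinalCohort,
                  hp: Hyperparams, weights: WeightMatrices) -> float:
    """Value of the smoothed surrogate (pre-ADMM: copies A=U, B=W substituted)."""
    _check_state_shapes(state, cohort)
    w = weights
    val = _weighted_sq(state.U.T @ state.G1 - state.F, w.d1)
    val += hp.gamma1 * sum(
        _weighted_sq(X - Wi @ (Wi.T @ X), di)
        for X, Wi, di in zip(cohort.histories, state.W, w.d2)
    )
    Z = enrich_all(cohort, state.W)
    val += hp.gamma2 * _weighted_sq(Z - state.H1 @ state.G1, w.d3)
    val += hp.gamma3 * _weighted_sq(cohort.snp_matrix - state.H0 @ state.G0, w.d4)
    val += hp.gamma4 * _weighted_sq(state.G1 - state.G0, w.d5)
    val += hp.gamma5 * sum(
        scal * np.linalg.norm(state.H0[g]) ** 2
        for scal, g in zip(w.d6_blocks, cohort.snp_groups)
    )
    W1 = unfold(state.W, 1)
    W2 = unfold(state.W, 2)
    val += hp.gamma6 * float(np.sum(W1 * (w.D7 @ W1)))  # tr(W1^T D7 W1)
    val += hp.gamma6 * float(np.sum(W2 * (w.D8 @ W2)))
    val += hp.gamma7 * sum(
        float(state.U[:, q] @ (w.d9[q] * state.U[:, q]))
        for q in range(state.U.shape[1])
    )
    return float(val)
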