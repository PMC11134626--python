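"""Two-level solver: outer iterative reweighting, inner ADMM.

The outer loop refreshes the quadratic surrogate's weight matrices from the
current iterate; the inner loop minimizes the augmented Lagrangian (the
surrogate with copies ``A = U`` and ``B_i = W_i`` split off) by cyclic block
updates, each a stationary point of the augmented Lagrangian in that block
with all others fixed, followed by multiplier and penalty updates.

Every block update is a linear solve; the SNP loading block is a Sylvester
equation after left-normalization by its diagonal weight, and the projection
blocks ``W_i`` are solved exactly column by column because the imaging
factor weight is diagonal.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import scipy.linalg

from .core import (
    LongitudinalCohort, Hyperparams, ModelState, WeightMatrices, FitResult,
    validate_cohort,
)
from .objective import enrich_all, eval_objective, reweight, unfold

__all__ = [
    "init_state", "update_block", "update_multipliers", "solve_sylvester",
    "admm_objective", "constraint_residuals", "fit", "standardize_cohort",
    "BLOCK_ORDER",
]

logger = logging.getLogger(__name__)

_JITTER = 1e-10

#: Cyclic order of block updates within one inner ADMM sweep.
BLOCK_ORDER = ("F", "U", "A", "H1", "G1", "H0", "G0", "WB")


def _solve(K: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Linear solve with a ridge-jitter fallback for singular systems."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", scipy.linalg.LinAlgWarning)
            return scipy.linalg.solve(K, rhs)
    except scipy.linalg.LinAlgError:
        logger.warning("singular block system; solving with ridge jitter")
        return scipy.linalg.solve(K + _JITTER * np.eye(K.shape[0]), rhs)


def _reg(K: np.ndarray) -> np.ndarray:
    """Scale-relative ridge jitter for systems that may be rank-deficient."""
    scale = max(1.0, float(np.trace(K)) / K.shape[0])
    return K + _JITTER * scale * np.eye(K.shape[0])


def solve_sylvester(P: np.ndarray, Q: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Solve ``P X + X Q = R``, verifying solvability and the residual.

    Raises ``ValueError`` naming the shared eigenvalue when the spectra of
    ``P`` and ``-Q`` overlap (the equation is then singular).
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    R = np.asarray(R, dtype=float)
    eP = np.linalg.eigvals(P)
    eQ = np.linalg.eigvals(Q)
    sums = np.abs(eP[:, None] + eQ[None, :])
    scale = max(1.0, np.abs(eP).max(initial=0.0), np.abs(eQ).max(initial=0.0))
    if sums.min() < 1e-12 * scale:
        i, j = np.unravel_index(np.argmin(sums), sums.shape)
        raise ValueError(
            f"Sylvester equation is singular: eigenvalue {eP[i]:.6g} of P "
            f"coincides with {-eQ[j]:.6g} (= -eigenvalue of Q)"
        )
    X = scipy.linalg.solve_sylvester(P, Q, R)
    resid = np.linalg.norm(P @ X + X @ Q - R)
    if resid > 1e-8 * max(np.linalg.norm(R), 1e-300):
        warnings.warn(f"Sylvester residual {resid:.3e} above tolerance")
    return X


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each column positive (determinism)."""
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def _orthonormal_basis(X: np.ndarray, r1: int, rng: np.random.Generator) -> np.ndarray:
    """Top-r1 left singular vectors of X, padded with random orthonormal
    complement columns when rank(X) < r1."""
    d = X.shape[0]
    if X.shape[1] == 0:
        Q, _ = np.linalg.qr(rng.standard_normal((d, r1)))
        return _fix_signs(Q)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int((s > s.max(initial=0.0) * 1e-12).sum())
    k = min(rank, r1)
    W = U[:, :k]
    if k < r1:
        # random directions projected off the current span, re-orthonormalized
        extra = rng.standard_normal((d, r1 - k))
        extra -= W @ (W.T @ extra)
        Qe, _ = np.linalg.qr(extra)
        W = np.hstack([W, Qe[:, : r1 - k]])
    return _fix_signs(W)


def _canonicalize_signs(W: list[np.ndarray]) -> None:
    """Resolve the per-participant sign ambiguity of singular vectors
    cohort-wide, in place.

    Each column k of every projection is a singular vector, so its sign is
    arbitrary; block updates cannot cross the resulting discrete barrier
    later (the orthogonality penalty blows up on the path through zero).
    For each coordinate we take the leading eigenvector of the
    sign-invariant second moment of that column across participants as the
    shared reference and flip columns to correlate positively with it.
    """
    n = len(W)
    if n < 2:
        return
    for k in range(W[0].shape[1]):
        M = np.column_stack([w[:, k] for w in W])
        C = M @ M.T
        _, vecs = scipy.linalg.eigh(C)
        ref = _fix_signs(vecs[:, -1:])[:, 0]
        for i in range(n):
            if W[i][:, k] @ ref < 0:
                W[i][:, k] = -W[i][:, k]


def init_state(cohort: LongitudinalCohort, hp: Hyperparams) -> ModelState:
    """Deterministic (seeded) initialization of all optimization variables."""
    d, n, c, l = cohort.d, cohort.n, cohort.n_scores, cohort.n_labeled
    r1, r2 = hp.r1, hp.r2
    if r1 > d:
        raise ValueError(f"r1={r1} exceeds d={d}")
    if r2 > n:
        raise ValueError(f"r2={r2} exceeds n={n}")
    rng = np.random.default_rng(hp.seed)

    W = [_orthonormal_basis(X, r1, rng) for X in cohort.histories]
    _canonicalize_signs(W)
    B = [w.copy() for w in W]

    # The robust-PCA coupling perturbs the W_i/B_i block systems by up to
    # ~2*gamma1*max_j(d2_j)*sigma_max(X_i)^2 around a fixed point; the
    # per-participant penalties must start above that local Lipschitz
    # constant or the cyclic updates amplify roundoff and diverge.
    mu_scale = np.ones(n)
    for i, (X, Wi) in enumerate(zip(cohort.histories, W)):
        if X.size == 0:
            continue
        sigma = np.linalg.norm(X, 2)
        resid = X - Wi @ (Wi.T @ X)
        row_norms2 = np.einsum("ij,ij->i", resid, resid)
        # median-row weight: stiff enough to damp the amplification (and
        # exact in the all-rows-tiny noiseless case) without freezing the
        # projections on ordinary noisy data
        d2_med = 1.0 / (2.0 * np.sqrt(np.median(row_norms2) + hp.delta))
        mu_scale[i] += 2.0 * hp.gamma1 * d2_med * sigma ** 2

    # G0 = G1 = top-r2 right factor of a seeded randomized factorization of
    # the SNP matrix (range finder); keeps the first factor solves
    # well-conditioned instead of starting from near-zero noise.
    sketch = cohort.snp_matrix @ rng.standard_normal((n, min(r2 + 2, n)))
    Qs, _ = np.linalg.qr(sketch)
    Us, ss, Vt = np.linalg.svd(Qs.T @ cohort.snp_matrix, full_matrices=False)
    G = (ss[:r2, None] * Vt[:r2]) + 0.01 * rng.standard_normal((r2, n))
    H0 = (Qs @ Us)[:, :r2]
    H1 = 0.01 * rng.standard_normal((r1, r2))
    # Refine projection-column signs against the genetic factor: each
    # enriched coordinate should relate to the shared representation by one
    # cohort-wide map, which pins down the per-participant sign that
    # imaging alone cannot identify. Sign synchronization again goes
    # through a sign-invariant second moment, now in factor space.
    Z0 = np.column_stack([W[i].T @ cohort.last_records[:, i] for i in range(n)])
    for k in range(r1):
        V = Z0[k][None, :] * G                      # column i = z_ik * g_i
        _, vecs = scipy.linalg.eigh(V @ V.T)
        s = np.sign(V.T @ vecs[:, -1])
        s[s == 0] = 1.0
        for i in range(n):
            if s[i] < 0:
                W[i][:, k] = -W[i][:, k]
        Z0[k] *= s
    for w_i, b_i in zip(W, B):
        b_i[:] = w_i

    # U from a tiny ridge regression of the labels on the initial factor
    Gl = G[:, :l]
    U = np.linalg.solve(Gl @ Gl.T + 1e-6 * np.eye(r2), Gl @ cohort.labels.T)
    F = np.zeros((c, n))
    F[:, :l] = cohort.labels
    return ModelState(
        W=W, H0=H0, G0=G.copy(), H1=H1, G1=G.copy(), U=U, F=F,
        A=U.copy(), B=B,
        Lambda1=np.zeros((c, l)),
        Lambda2=[np.zeros((r1, r1)) for _ in range(n)],
        Lambda3=np.zeros((r2, c)),
        Lambda4=[np.zeros((d, r1)) for _ in range(n)],
        mu1=hp.mu1_init,
        mu2=hp.mu2_init * mu_scale,
        mu3=hp.mu3_init,
        mu4=hp.mu4_init * mu_scale,
    )


# ----------------------------------------------------------------------
# Augmented Lagrangian (ADMM objective) and residuals
# ----------------------------------------------------------------------

def _wsq_pair(M: np.ndarray, N: np.ndarray, diag: np.ndarray) -> float:
    # tr(M^T diag(w) N)
    return float(np.einsum("i,ij,ij->", diag, M, N))


def admm_objective(state: ModelState, cohort: LongitudinalCohort,
                   hp: Hyperparams, weights: WeightMatrices) -> float:
    """Value of the augmented Lagrangian at the current state."""
    st, w = state, weights
    Yl = cohort.labels
    l = cohort.n_labeled

    val = _wsq_pair(st.A.T @ st.G1 - st.F, st.U.T @ st.G1 - st.F, w.d1)
    val += hp.gamma1 * sum(
        _wsq_pair(X - Wi @ (Wi.T @ X), X - Bi @ (Bi.T @ X), di)
        for X, Wi, Bi, di in zip(cohort.histories, st.W, st.B, w.d2)
    )
    Z = enrich_all(cohort, st.W)
    R3 = Z - st.H1 @ st.G1
    val += hp.gamma2 * _wsq_pair(R3, R3, w.d3)
    R4 = cohort.snp_matrix - st.H0 @ st.G0
    val += hp.gamma3 * _wsq_pair(R4, R4, w.d4)
    R5 = st.G1 - st.G0
    val += hp.gamma4 * _wsq_pair(R5, R5, w.d5)
    val += hp.gamma5 * sum(
        scal * np.linalg.norm(st.H0[g]) ** 2
        for scal, g in zip(w.d6_blocks, cohort.snp_groups)
    )
    W1 = unfold(st.W, 1)
    W2 = unfold(st.W, 2)
    B2 = unfold(st.B, 2)
    val += hp.gamma6 * float(np.sum(W1 * (w.D7 @ W1)))
    val += hp.gamma6 * float(np.sum(W2 * (w.D8 @ B2)))
    val += hp.gamma7 * sum(
        float(st.A[:, q] @ (w.d9[q] * st.A[:, q]))
        for q in range(st.A.shape[1])
    )

    val += 0.5 * st.mu1 * np.linalg.norm(
        st.F[:, :l] - Yl + st.Lambda1 / st.mu1) ** 2
    I = np.eye(st.r1)
    for i in range(st.n):
        val += 0.5 * st.mu2[i] * np.linalg.norm(
            st.W[i].T @ st.B[i] - I + st.Lambda2[i] / st.mu2[i]) ** 2
        val += 0.5 * st.mu4[i] * np.linalg.norm(
            st.B[i] - st.W[i] + st.Lambda4[i] / st.mu4[i]) ** 2
    val += 0.5 * st.mu3 * np.linalg.norm(st.A - st.U + st.Lambda3 / st.mu3) ** 2
    return float(val)


def constraint_residuals(state: ModelState, cohort: LongitudinalCohort) -> dict:
    """Frobenius norms of the four constraint families (max over participants)."""
    l = cohort.n_labeled
    I = np.eye(state.r1)
    return {
        "label": float(np.linalg.norm(state.F[:, :l] - cohort.labels)),
        "ortho": float(max(
            np.linalg.norm(W.T @ B - I) for W, B in zip(state.W, state.B))),
        "copy_U": float(np.linalg.norm(state.A - state.U)),
        "copy_W": float(max(
            np.linalg.norm(B - W) for W, B in zip(state.W, state.B))),
    }


# ----------------------------------------------------------------------
# Block updates (each the exact stationary point of the augmented
# Lagrangian in that block, all others fixed)
# ----------------------------------------------------------------------

def _update_F(st: ModelState, cohort: LongitudinalCohort,
              hp: Hyperparams, w: WeightMatrices) -> np.ndarray:
    l = cohort.n_labeled
    P = st.A.T @ st.G1
    Q = st.U.T @ st.G1
    F = 0.5 * (P + Q)
    denom = (2.0 * w.d1 + st.mu1)[:, None]
    F[:, :l] = (
        w.d1[:, None] * (P[:, :l] + Q[:, :l])
        + st.mu1 * cohort.labels - st.Lambda1
    ) / denom
    return F


def _update_U(st: ModelState, hp: Hyperparams, w: WeightMatrices) -> np.ndarray:
    M = st.A.T @ st.G1 - st.F                       # c x n
    grad_lin = st.G1 @ (w.d1[:, None] * M).T        # r2 x c
    return st.A + (st.Lambda3 - grad_lin) / st.mu3


def _update_A(st: ModelState, hp: Hyperparams, w: WeightMatrices) -> np.ndarray:
    N = st.U.T @ st.G1 - st.F
    G_lin = st.G1 @ (w.d1[:, None] * N).T           # r2 x c
    A = np.empty_like(st.A)
    r2 = st.r2
    for q in range(st.A.shape[1]):
        K = np.diag(2.0 * hp.gamma7 * w.d9[q]) + st.mu3 * np.eye(r2)
        rhs = st.mu3 * st.U[:, q] - st.Lambda3[:, q] - G_lin[:, q]
        A[:, q] = _solve(K, rhs)
    return A


def _update_H1(st: ModelState, cohort: LongitudinalCohort,
               hp: Hyperparams, w: WeightMatrices) -> np.ndarray:
    if hp.gamma2 == 0:
        return st.H1.copy()
    Z = enrich_all(cohort, st.W)
    K = st.G1 @ st.G1.T
    return _solve(_reg(K), st.G1 @ Z.T).T


def _update_G1(st: ModelState, cohort: LongitudinalCohort,
               hp: Hyperparams, w: WeightMatrices) -> np.ndarray:
    Ad = st.A * w.d1[None, :]
    Ud = st.U * w.d1[None, :]
    K = Ad @ st.U.T + Ud @ st.A.T + 2.0 * hp.gamma4 * np.diag(w.d5)
    rhs = (Ad + Ud) @ st.F
    rhs += 2.0 * hp.gamma4 * w.d5[:, None] * st.G0
    if hp.gamma2 > 0:
        Z = enrich_all(cohort, st.W)
        H1d = w.d3[:, None] * st.H1                 # D3 H1
        K = K + 2.0 * hp.gamma2 * st.H1.T @ H1d
        rhs = rhs + 2.0 * hp.gamma2 * st.H1.T @ (w.d3[:, None] * Z)
    if np.linalg.norm(K) == 0:
        return st.G1.copy()
    return _solve(_reg(K), rhs)


def _update_H0(st: ModelState, cohort: LongitudinalCohort,
               hp: Hyperparams, w: WeightMatrices) -> np.ndarray:
    g3, g5 = hp.gamma3, hp.gamma5
    if g3 == 0 and g5 == 0:
        return st.H0.copy()
    if g3 == 0:
        return np.zeros_like(st.H0)                 # only the PD group penalty
    d6 = w.d6_full(cohort.snp_groups)
    P = np.diag(g5 * d6 / w.d4)                     # left-normalized by D4
    Q = g3 * (st.G0 @ st.G0.T)
    R = g3 * cohort.snp_matrix @ st.G0.T
    if g5 == 0:
        return _solve(_reg(Q).T, R.T).T
    return solve_sylvester(P, Q, R)


def _update_G0(st: ModelState, cohort: LongitudinalCohort,
               hp: Hyperparams, w: WeightMatrices) -> np.ndarray:
    g3, g4 = hp.gamma3, hp.gamma4
    K = np.zeros((st.r2, st.r2))
    rhs = np.zeros_like(st.G0)
    if g3 > 0:
        H0d = w.d4[:, None] * st.H0                 # D4 H0
        K += g3 * st.H0.T @ H0d
        rhs += g3 * H0d.T @ cohort.snp_matrix
    if g4 > 0:
        K += g4 * np.diag(w.d5)
        rhs += g4 * w.d5[:, None] * st.G1
    if np.linalg.norm(K) == 0:
        return st.G0.copy()
    return _solve(_reg(K), rhs)


def _W_system(st: ModelState, cohort: LongitudinalCohort, hp: Hyperparams,
              w: WeightMatrices, i: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Assemble L, RHS and the rank-one pieces of the W_i stationarity system:
    ``(L + 2 gamma2 d3_j x_i x_i^T) w_j = rhs_j`` for each column j."""
    Xi = cohort.histories[i]
    xi = cohort.last_records[:, i]
    Bi = st.B[i]
    d = cohort.d
    Ni = Xi - Bi @ (Bi.T @ Xi)
    C = (w.d2[i][:, None] * Ni) @ Xi.T              # D2i Ni Xi^T
    L = -hp.gamma1 * (C + C.T)
    L += 2.0 * hp.gamma6 * w.D7
    L += st.mu2[i] * (Bi @ Bi.T)
    L += st.mu4[i] * np.eye(d)
    m_i = st.H1 @ st.G1[:, i]
    rhs = 2.0 * hp.gamma2 * np.outer(xi, m_i * w.d3)
    rhs += -hp.gamma6 * (Bi @ w.D8)
    rhs += st.mu2[i] * Bi - Bi @ st.Lambda2[i].T
    rhs += st.mu4[i] * Bi + st.Lambda4[i]
    return L, rhs, xi, 2.0 * hp.gamma2


def _update_Wi(st: ModelState, cohort: LongitudinalCohort,
               hp: Hyperparams, w: WeightMatrices, i: int) -> np.ndarray:
    L, rhs, xi, coef = _W_system(st, cohort, hp, w, i)
    Wi = np.empty_like(st.W[i])
    xxT = np.outer(xi, xi)
    for j in range(Wi.shape[1]):
        Kj = L + coef * w.d3[j] * xxT
        Wi[:, j] = _solve(Kj, rhs[:, j])
    return Wi


def _update_Bi(st: ModelState, cohort: LongitudinalCohort,
               hp: Hyperparams, w: WeightMatrices, i: int) -> np.ndarray:
    Xi = cohort.histories[i]
    Wi = st.W[i]
    d = cohort.d
    Mi = Xi - Wi @ (Wi.T @ Xi)
    C = (w.d2[i][:, None] * Mi) @ Xi.T              # D2i Mi Xi^T
    L = -hp.gamma1 * (C + C.T)
    L += st.mu2[i] * (Wi @ Wi.T)
    L += st.mu4[i] * np.eye(d)
    rhs = -hp.gamma6 * (Wi @ w.D8)
    rhs += st.mu2[i] * Wi - Wi @ st.Lambda2[i]
    rhs += st.mu4[i] * Wi - st.Lambda4[i]
    return _solve(L, rhs)


def update_block(state: ModelState, cohort: LongitudinalCohort,
                 hp: Hyperparams, weights: WeightMatrices,
                 block_name: str) -> ModelState:
    """Return a copy of ``state`` with one block replaced by the stationary
    point of the augmented Lagrangian in that block.

    ``block_name`` is one of ``U, F, A, H1, G1, H0, G0`` or ``W_<i>`` /
    ``B_<i>`` for a participant index ``i``.
    """
    st = state.copy()
    if block_name == "F":
        st.F = _update_F(st, cohort, hp, weights)
    elif block_name == "U":
        st.U = _update_U(st, hp, weights)
    elif block_name == "A":
        st.A = _update_A(st, hp, weights)
    elif block_name == "H1":
        st.H1 = _update_H1(st, cohort, hp, weights)
    elif block_name == "G1":
        st.G1 = _update_G1(st, cohort, hp, weights)
    elif block_name == "H0":
        st.H0 = _update_H0(st, cohort, hp, weights)
    elif block_name == "G0":
        st.G0 = _update_G0(st, cohort, hp, weights)
    elif block_name.startswith("W_"):
        i = int(block_name[2:])
        st.W[i] = _update_Wi(st, cohort, hp, weights, i)
    elif block_name.startswith("B_"):
        i = int(block_name[2:])
        st.B[i] = _update_Bi(st, cohort, hp, weights, i)
    else:
        raise ValueError(f"unknown block {block_name!r}")
    return st


def update_multipliers(state: ModelState, hp: Hyperparams,
                       cohort: LongitudinalCohort) -> ModelState:
    """Gradient-ascent multiplier step followed by geometric penalty growth."""
    st = state.copy()
    l = cohort.n_labeled
    I = np.eye(st.r1)
    st.Lambda1 = st.Lambda1 + st.mu1 * (st.F[:, :l] - cohort.labels)
    for i in range(st.n):
        st.Lambda2[i] = st.Lambda2[i] + st.mu2[i] * (st.W[i].T @ st.B[i] - I)
        st.Lambda4[i] = st.Lambda4[i] + st.mu4[i] * (st.B[i] - st.W[i])
    st.Lambda3 = st.Lambda3 + st.mu3 * (st.A - st.U)
    st.mu1 = min(st.mu1 * hp.rho1, hp.mu_max)
    st.mu2 = np.minimum(st.mu2 * hp.rho2, hp.mu_max)
    st.mu3 = min(st.mu3 * hp.rho3, hp.mu_max)
    st.mu4 = np.minimum(st.mu4 * hp.rho4, hp.mu_max)
    return st


def _sweep_inplace(st: ModelState, cohort: LongitudinalCohort,
                   hp: Hyperparams, w: WeightMatrices) -> None:
    """One cyclic pass over all blocks, mutating ``st`` (internal fast path)."""
    st.F = _update_F(st, cohort, hp, w)
    st.U = _update_U(st, hp, w)
    st.A = _update_A(st, hp, w)
    st.H1 = _update_H1(st, cohort, hp, w)
    st.G1 = _update_G1(st, cohort, hp, w)
    st.H0 = _update_H0(st, cohort, hp, w)
    st.G0 = _update_G0(st, cohort, hp, w)
    for i in range(st.n):
        st.W[i] = _update_Wi(st, cohort, hp, w, i)
        st.B[i] = _update_Bi(st, cohort, hp, w, i)


def _multipliers_inplace(st: ModelState, hp: Hyperparams,
                         cohort: LongitudinalCohort) -> None:
    l = cohort.n_labeled
    I = np.eye(st.r1)
    st.Lambda1 += st.mu1 * (st.F[:, :l] - cohort.labels)
    for i in range(st.n):
        st.Lambda2[i] += st.mu2[i] * (st.W[i].T @ st.B[i] - I)
        st.Lambda4[i] += st.mu4[i] * (st.B[i] - st.W[i])
    st.Lambda3 += st.mu3 * (st.A - st.U)
    st.mu1 = min(st.mu1 * hp.rho1, hp.mu_max)
    st.mu2 = np.minimum(st.mu2 * hp.rho2, hp.mu_max)
    st.mu3 = min(st.mu3 * hp.rho3, hp.mu_max)
    st.mu4 = np.minimum(st.mu4 * hp.rho4, hp.mu_max)


def standardize_cohort(cohort: LongitudinalCohort,
                       n_reference: int | None = None
                       ) -> tuple[LongitudinalCohort, dict]:
    """Per-feature z-scoring of imaging and SNP blocks.

    Statistics are computed on the first ``n_reference`` participants only
    (default: the labeled ones, i.e. the training set) and applied to all.
    """
    n_ref = cohort.n_labeled if n_reference is None else n_reference
    ref_cols = np.hstack(
        [cohort.histories[i] for i in range(n_ref)]
        + [cohort.last_records[:, :n_ref]]
    )
    img_mean = ref_cols.mean(axis=1)
    img_sd = np.maximum(ref_cols.std(axis=1), 1e-12)
    snp_ref = cohort.snp_matrix[:, :n_ref]
    snp_mean = snp_ref.mean(axis=1)
    snp_sd = np.maximum(snp_ref.std(axis=1), 1e-12)

    out = cohort.copy()
    out.histories = [
        (X - img_mean[:, None]) / img_sd[:, None] for X in out.histories
    ]
    out.last_records = (out.last_records - img_mean[:, None]) / img_sd[:, None]
    out.snp_matrix = (out.snp_matrix - snp_mean[:, None]) / snp_sd[:, None]
    info = {
        "imaging_mean": img_mean, "imaging_sd": img_sd,
        "snp_mean": snp_mean, "snp_sd": snp_sd,
        "n_reference": n_ref,
    }
    return out, info


def fit(cohort: LongitudinalCohort, hp: Hyperparams, *,
        standardize: bool = True, interleaved: bool = True,
        callback=None) -> FitResult:
    """Fit the enrichment model.

    Parameters
    ----------
    cohort
        Validated cohort (labeled participants first).
    hp
        Hyperparameters and solver controls.
    standardize
        Z-score imaging and SNP features using labeled participants'
        statistics before fitting (recorded in the result).
    interleaved
        Refresh the surrogate weights after every inner sweep (default;
        keeps weights consistent with the residuals they majorize and is
        markedly more stable) instead of once per outer iteration.
    callback
        Optional ``callback(outer, state, objective, residuals)`` hook.
    """
    report = validate_cohort(cohort)
    if not report.valid:
        raise ValueError("invalid cohort: " + "; ".join(report.violations))
    hp.validate(d=cohort.d, d_snp=cohort.d_snp)

    std_info = None
    if standardize:
        cohort, std_info = standardize_cohort(cohort)

    st = init_state(cohort, hp)
    obj_history: list[float] = []
    res_history: list[dict] = []
    n_inner_total = 0
    prev_obj = None
    converged = False

    for outer in range(hp.max_outer):
        weights = reweight(st, cohort, hp.delta)
        for _ in range(hp.max_inner):
            _sweep_inplace(st, cohort, hp, weights)
            _multipliers_inplace(st, hp, cohort)
            n_inner_total += 1
            res = constraint_residuals(st, cohort)
            if interleaved:
                weights = reweight(st, cohort, hp.delta)
            if max(res.values()) < hp.tol_residual:
                break
        obj = eval_objective(st, cohort, hp).total
        if not np.isfinite(obj):
            raise FloatingPointError(
                f"non-finite objective at outer iteration {outer}; "
                f"residuals={res}"
            )
        obj_history.append(obj)
        res_history.append(res)
        logger.debug("outer %d: objective=%.6e residuals=%s", outer, obj, res)
        if callback is not None:
            callback(outer, st, obj, res)
        feasible = max(res.values()) < hp.tol_residual
        if prev_obj is not None and abs(prev_obj - obj) < hp.tol_obj * (1 + abs(obj)):
            if feasible:
                converged = True
                break
        prev_obj = obj

    return FitResult(
        state=st,
        Z=enrich_all(cohort, st.W),
        objective_history=obj_history,
        residual_history=res_history,
        converged=converged,
        n_outer=len(obj_history),
        n_inner_total=n_inner_total,
        standardization=std_info,
    )
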