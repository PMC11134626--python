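"""Core data model: cohorts, hyperparameters, optimization state.

Conventions used throughout the package:

* features are rows, participants are columns (``d x n`` matrices);
* participant ``i`` owns a history matrix ``X_i`` (``d x n_i``, baseline
  through second-to-last visit) and a last record ``x_i`` (column ``i`` of
  the ``d x n`` matrix ``last_records``);
* the first ``l`` participants are the labeled ones;
* missing visits are represented by absence (ragged ``n_i``), never by NaN.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "LongitudinalCohort",
    "Hyperparams",
    "ModelState",
    "WeightMatrices",
    "FitResult",
    "ValidationReport",
    "validate_cohort",
]


@dataclass
class LongitudinalCohort:
    """An imaging-genetic cohort with ragged longitudinal histories.

    Parameters
    ----------
    histories
        Length-``n`` list; element ``i`` is the ``d x n_i`` matrix of the
        participant's visits from baseline through the second-to-last visit.
    last_records
        ``d x n`` matrix whose column ``i`` is the participant's most recent
        visit (the record that gets enriched).
    modality_slices
        Ordered mapping from modality name to a ``slice`` of feature rows.
        Slices must be contiguous, disjoint, and cover ``0..d``.
    snp_matrix
        ``d_snp x n`` static genotype-derived matrix.
    snp_groups
        Ordered list of ``K`` integer index arrays partitioning the SNP rows.
    labels
        ``c x l`` clinical-score matrix for the first ``l`` participants.
    ids
        Participant identifiers, labeled participants first.
    original_order
        Optional permutation recording each participant's position in the
        source file, so outputs can be reported in the original order.
    """

    histories: list[np.ndarray]
    last_records: np.ndarray
    modality_slices: dict[str, slice]
    snp_matrix: np.ndarray
    snp_groups: list[np.ndarray]
    labels: np.ndarray
    ids: list[str] = field(default_factory=list)
    original_order: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.histories = [np.asarray(X, dtype=float) for X in self.histories]
        self.last_records = np.asarray(self.last_records, dtype=float)
        self.snp_matrix = np.asarray(self.snp_matrix, dtype=float)
        self.snp_groups = [np.asarray(g, dtype=int) for g in self.snp_groups]
        self.labels = np.asarray(self.labels, dtype=float)
        if not self.ids:
            self.ids = [f"P{i:04d}" for i in range(self.n)]

    # -- derived sizes -------------------------------------------------
    @property
    def n(self) -> int:
        return self.last_records.shape[1]

    @property
    def d(self) -> int:
        return self.last_records.shape[0]

    @property
    def d_snp(self) -> int:
        return self.snp_matrix.shape[0]

    @property
    def n_labeled(self) -> int:
        return self.labels.shape[1]

    @property
    def n_scores(self) -> int:
        return self.labels.shape[0]

    @property
    def n_groups(self) -> int:
        return len(self.snp_groups)

    @property
    def visit_counts(self) -> np.ndarray:
        """History lengths ``n_i`` (total records per participant = n_i + 1)."""
        return np.array([X.shape[1] for X in self.histories], dtype=int)

    def copy(self) -> "LongitudinalCohort":
        return LongitudinalCohort(
            histories=[X.copy() for X in self.histories],
            last_records=self.last_records.copy(),
            modality_slices=dict(self.modality_slices),
            snp_matrix=self.snp_matrix.copy(),
            snp_groups=[g.copy() for g in self.snp_groups],
            labels=self.labels.copy(),
            ids=list(self.ids),
            original_order=None if self.original_order is None else self.original_order.copy(),
        )


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # truthy iff valid
        return self.valid


def validate_cohort(cohort: LongitudinalCohort) -> ValidationReport:
    """Check every structural invariant of a cohort; pure, report-based.

    The report lists one message per violated invariant; an empty report
    means the cohort is valid.
    """
    v: list[str] = []
    n, d = cohort.n, cohort.d

    if len(cohort.histories) != n:
        v.append(
            f"history count {len(cohort.histories)} != participant count {n}"
        )
    for i, X in enumerate(cohort.histories):
        if X.ndim != 2 or X.shape[0] != d:
            v.append(f"participant {i}: history has {X.shape} shape, expected ({d}, n_i)")
        elif X.shape[1] < 1:
            v.append(f"participant {i}: n_i < 1 (empty history)")
        if X.size and not np.isfinite(X).all():
            v.append(f"participant {i}: history contains NaN/Inf")
    if not np.isfinite(cohort.last_records).all():
        v.append("last_records contains NaN/Inf")
    if not np.isfinite(cohort.snp_matrix).all():
        v.append("snp_matrix contains NaN/Inf")
    if not np.isfinite(cohort.labels).all():
        v.append("labels contains NaN/Inf")

    if cohort.snp_matrix.shape[1] != n:
        v.append(f"snp_matrix has {cohort.snp_matrix.shape[1]} columns, expected {n}")

    l = cohort.n_labeled
    if not (1 <= l <= n):
        v.append(f"labeled count l={l} outside 1..n={n}")

    # snp_groups must be a disjoint cover of 0..d_snp-1
    if cohort.snp_groups:
        flat = np.concatenate(cohort.snp_groups)
    else:
        flat = np.array([], dtype=int)
    if len(flat) != cohort.d_snp or len(np.unique(flat)) != len(flat) or (
        len(flat) and (flat.min() != 0 or flat.max() != cohort.d_snp - 1)
    ):
        v.append("snp_groups is not a disjoint cover (partition) of the SNP rows")
    for g in cohort.snp_groups:
        if g.size == 0:
            v.append("snp_groups contains an empty group")
            break

    # modality slices: contiguous, disjoint, cover 0..d
    covered = np.zeros(d, dtype=int)
    for name, sl in cohort.modality_slices.items():
        if sl.step not in (None, 1):
            v.append(f"modality '{name}' slice has non-unit step")
            continue
        covered[sl] += 1
    if covered.size and (covered != 1).any():
        v.append("modality slices do not form a disjoint cover of the features")

    if len(cohort.ids) != n:
        v.append(f"{len(cohort.ids)} ids for {n} participants")
    elif len(set(cohort.ids)) != n:
        v.append("participant ids are not unique")

    return ValidationReport(v)


@dataclass
class Hyperparams:
    """Weights, dimensions and solver controls of the enrichment model.

    The ``gamma`` defaults are the values used in the original experiments;
    solver controls (``mu`` schedules, tolerances) are configurable defaults.
    """

    gamma1: float = 1e-1
    gamma2: float = 1e-4
    gamma3: float = 1e-2
    gamma4: float = 1e-3
    gamma5: float = 1e-1
    gamma6: float = 1e-1
    gamma7: float = 1e-1
    r1: int = 5
    r2: int = 3
    delta: float = 1e-8
    rho1: float = 1.05
    rho2: float = 1.05
    rho3: float = 1.15
    rho4: float = 1.15
    mu1_init: float = 1.0
    mu2_init: float = 1.0
    mu3_init: float = 1.0
    mu4_init: float = 1.0
    mu_max: float = 1e8
    max_outer: int = 30
    max_inner: int = 50
    tol_obj: float = 1e-6
    tol_residual: float = 1e-6
    seed: int = 0

    @property
    def gammas(self) -> tuple[float, ...]:
        return (self.gamma1, self.gamma2, self.gamma3, self.gamma4,
                self.gamma5, self.gamma6, self.gamma7)

    def validate(self, d: int | None = None, d_snp: int | None = None) -> None:
        if any(g < 0 for g in self.gammas):
            raise ValueError("all gamma weights must be nonnegative")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if min(self.rho1, self.rho2, self.rho3, self.rho4) < 1:
            raise ValueError("all rho growth factors must be >= 1")
        if min(self.mu1_init, self.mu2_init, self.mu3_init, self.mu4_init) <= 0:
            raise ValueError("all initial mu penalties must be > 0")
        if self.r1 < 1 or self.r2 < 1:
            raise ValueError("r1 and r2 must be positive")
        if d is not None and self.r1 > d:
            raise ValueError(f"r1={self.r1} exceeds feature dimension d={d}")
        if self.r2 > self.r1:
            raise ValueError(f"r2={self.r2} exceeds r1={self.r1}")
        if d_snp is not None and self.r2 > d_snp:
            raise ValueError(f"r2={self.r2} exceeds d_snp={d_snp}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Hyperparams":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class ModelState:
    """All optimization variables, ADMM copies, multipliers and penalties."""

    W: list[np.ndarray]            # n matrices, d x r1
    H0: np.ndarray                 # d_snp x r2
    G0: np.ndarray                 # r2 x n
    H1: np.ndarray                 # r1 x r2
    G1: np.ndarray                 # r2 x n
    U: np.ndarray                  # r2 x c
    F: np.ndarray                  # c x n, [F_l | F_u]
    A: np.ndarray                  # r2 x c, ADMM copy of U
    B: list[np.ndarray]            # n matrices, d x r1, ADMM copies of W_i
    Lambda1: np.ndarray            # c x l
    Lambda2: list[np.ndarray]      # n matrices, r1 x r1
    Lambda3: np.ndarray            # r2 x c
    Lambda4: list[np.ndarray]      # n matrices, d x r1
    mu1: float
    mu2: np.ndarray                # n scalars
    mu3: float
    mu4: np.ndarray                # n scalars

    @property
    def n(self) -> int:
        return len(self.W)

    @property
    def r1(self) -> int:
        return self.W[0].shape[1]

    @property
    def r2(self) -> int:
        return self.G1.shape[0]

    def copy(self) -> "ModelState":
        return ModelState(
            W=[w.copy() for w in self.W],
            H0=self.H0.copy(), G0=self.G0.copy(),
            H1=self.H1.copy(), G1=self.G1.copy(),
            U=self.U.copy(), F=self.F.copy(), A=self.A.copy(),
            B=[b.copy() for b in self.B],
            Lambda1=self.Lambda1.copy(),
            Lambda2=[m.copy() for m in self.Lambda2],
            Lambda3=self.Lambda3.copy(),
            Lambda4=[m.copy() for m in self.Lambda4],
            mu1=self.mu1, mu2=self.mu2.copy(), mu3=self.mu3, mu4=self.mu4.copy(),
        )


@dataclass
class WeightMatrices:
    """The nine reweighting objects of the smoothed surrogate.

    Diagonal matrices are stored as their diagonals; the block-diagonal SNP
    group matrix as one scalar per group; the two Gram-based matrices as
    full symmetric positive-definite matrices.
    """

    d1: np.ndarray                 # len c
    d2: list[np.ndarray]           # n vectors, len d
    d3: np.ndarray                 # len r1
    d4: np.ndarray                 # len d_snp
    d5: np.ndarray                 # len r2
    d6_blocks: np.ndarray          # len K (one scalar per SNP group)
    D7: np.ndarray                 # d x d, symmetric PD
    D8: np.ndarray                 # r1 x r1, symmetric PD
    d9: list[np.ndarray]           # c vectors, len r2

    def d6_full(self, groups: Sequence[np.ndarray]) -> np.ndarray:
        """Expand the per-group scalars into the full diagonal (len d_snp)."""
        size = sum(len(g) for g in groups)
        diag = np.empty(size)
        for scal, g in zip(self.d6_blocks, groups):
            diag[g] = scal
        return diag


@dataclass
class FitResult:
    """Converged (or best-effort) model plus diagnostics."""

    state: ModelState
    Z: np.ndarray                          # r1 x n enriched representations
    objective_history: list[float]         # full objective per outer iteration
    residual_history: list[dict]           # constraint residuals per outer iteration
    converged: bool
    n_outer: int
    n_inner_total: int
    standardization: dict | None = None    # per-block means/sds if applied
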