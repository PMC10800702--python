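"""Domain containers for the AHP-ARAS pipeline.

All numeric payloads are numpy arrays held at full precision; rounding is a
display concern and happens only in reports.  Containers are plain frozen
dataclasses: construction-time checks guard the invariants that are cheap to
state locally, while the heavier validation (reciprocity, Saaty range) lives
in the operations that build them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DomainError, StructuralError

BENEFIT = "benefit"
COST = "cost"


@dataclass(frozen=True)
class CriterionSpec:
    """One evaluation criterion: short id, human name, optimisation direction."""

    id: str
    name: str = ""
    direction: str = BENEFIT

    def __post_init__(self) -> None:
        if self.direction not in (BENEFIT, COST):
            raise DomainError(
                f"criterion {self.id!r}: direction must be 'benefit' or 'cost', "
                f"got {self.direction!r}"
            )


def as_criteria(criteria: Sequence, n: int, prefix: str = "C") -> tuple[CriterionSpec, ...]:
    """Coerce labels/specs to a tuple of CriterionSpec; default ids C1..Cn."""
    if criteria is None:
        return tuple(CriterionSpec(f"{prefix}{j + 1}") for j in range(n))
    out = []
    for c in criteria:
        out.append(c if isinstance(c, CriterionSpec) else CriterionSpec(str(c)))
    if len(out) != n:
        raise StructuralError(f"expected {n} criteria, got {len(out)}")
    ids = [c.id for c in out]
    if len(set(ids)) != len(ids):
        raise StructuralError(f"criterion ids are not unique: {ids}")
    return tuple(out)


@dataclass(frozen=True)
class PairwiseMatrix:
    """Square positive reciprocal matrix of criterion-vs-criterion judgments."""

    criteria: tuple[CriterionSpec, ...]
    entries: np.ndarray  # (n, n), validated by validate_pairwise
    warnings: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return len(self.criteria)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.criteria)


@dataclass(frozen=True)
class WeightVector:
    """Nonnegative per-criterion weights summing to one."""

    criteria: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 1 or len(w) != len(self.criteria):
            raise StructuralError("weights and criteria lengths differ")
        if np.any(w < 0):
            raise DomainError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise DomainError(f"weights must sum to 1, got {w.sum()!r}")

    @property
    def n(self) -> int:
        return len(self.criteria)

    def as_dict(self) -> dict[str, float]:
        return {c: float(v) for c, v in zip(self.criteria, self.weights)}


@dataclass(frozen=True)
class ConsistencyReport:
    """Consistency diagnostics of a pairwise matrix.

    lambda_max is the mean of per-criterion ratios (weighted-sum value over
    weight); CI = (lambda_max - n)/(n - 1); CR = CI/RI with Saaty's random
    index.  status is 'consistent' when CR <= threshold, else 'warning' -
    an inconsistent matrix is flagged, never rejected.
    """

    lambda_max: float
    ci: float
    ri: float
    cr: float
    n: int
    threshold: float
    status: str
    row_ratios: np.ndarray
    weighted_sum_values: np.ndarray
    eigenvector_delta: float | None = None

    def to_dict(self) -> dict:
        d = {
            "lambda_max": float(self.lambda_max),
            "ci": float(self.ci),
            "ri": float(self.ri),
            "cr": float(self.cr),
            "n": int(self.n),
            "threshold": float(self.threshold),
            "status": self.status,
            "weighted_sum_values": [float(v) for v in self.weighted_sum_values],
            "row_ratios": [float(v) for v in self.row_ratios],
        }
        if self.eigenvector_delta is not None:
            d["eigenvector_delta"] = float(self.eigenvector_delta)
        return d


@dataclass(frozen=True)
class DecisionMatrix:
    """Alternatives x criteria raw scores plus the optimal-value (ideal) row.

    The optimal row holds, per criterion, the best attainable value: the
    column maximum for benefit criteria, the minimum for cost criteria (or a
    user-supplied ideal).
    """

    alternatives: tuple[str, ...]
    criteria: tuple[CriterionSpec, ...]
    scores: np.ndarray  # (m, n), strictly positive
    optimal_row: np.ndarray  # (n,)
    optimal_source: str = "derived"  # 'derived' | 'user'
    warnings: tuple[str, ...] = ()

    @property
    def m(self) -> int:
        return len(self.alternatives)

    @property
    def n(self) -> int:
        return len(self.criteria)

    @property
    def criterion_labels(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.criteria)


@dataclass(frozen=True)
class NormalizedDecision:
    """Share-normalized decision matrix; row 0 is the optimal row, rows 1..m
    the alternatives; every column sums to one."""

    alternatives: tuple[str, ...]
    criteria: tuple[str, ...]
    values: np.ndarray  # (m + 1, n)


@dataclass(frozen=True)
class WeightedDecision:
    """Weighted normalized matrix; column j sums to weight W_j."""

    alternatives: tuple[str, ...]
    criteria: tuple[str, ...]
    values: np.ndarray  # (m + 1, n)


@dataclass(frozen=True)
class ArasResult:
    """Additive-ratio assessment outcome.

    s0/s_values are optimality-function row sums (ideal row and alternatives),
    k_values the utility degrees S_i/S_0, ranks the competition ranking
    (1 = best; ties share the minimum rank).
    """

    alternatives: tuple[str, ...]
    s0: float
    s_values: np.ndarray  # (m,)
    k_values: np.ndarray  # (m,)
    ranks: np.ndarray  # (m,) ints
    normalized: NormalizedDecision | None = None
    weighted: WeightedDecision | None = None
    warnings: tuple[str, ...] = ()

    def ordering(self) -> tuple[str, ...]:
        """Alternatives from best to worst (stable for ties)."""
        idx = sorted(range(len(self.alternatives)),
                     key=lambda i: (self.ranks[i], i))
        return tuple(self.alternatives[i] for i in idx)

    def to_dict(self) -> dict:
        return {
            "alternatives": list(self.alternatives),
            "S0": float(self.s0),
            "S": [float(v) for v in self.s_values],
            "K": [float(v) for v in self.k_values],
            "ranks": [int(r) for r in self.ranks],
            "ordering": list(self.ordering()),
            "warnings": list(self.warnings),
        }


@dataclass(frozen=True)
class StudyConfig:
    """Run configuration shared by the full pipeline."""

    cr_threshold: float = 0.10
    reciprocity_tol: float = 0.05
    scale_tol: float = 0.05
    scale_action: str = "warn"  # 'warn' | 'error' | 'ignore'
    weight_decimals: int = 2
    table_decimals: int = 3
    eigenvector_check: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cr_threshold <= 0:
            raise DomainError("cr_threshold must be > 0")
        if self.reciprocity_tol < 0:
            raise DomainError("reciprocity_tol must be >= 0")

    def to_dict(self) -> dict:
        return {
            "cr_threshold": self.cr_threshold,
            "reciprocity_tol": self.reciprocity_tol,
            "scale_tol": self.scale_tol,
            "scale_action": self.scale_action,
            "weight_decimals": self.weight_decimals,
            "table_decimals": self.table_decimals,
            "eigenvector_check": self.eigenvector_check,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class Scenario:
    """A synthetic study: ground-truth weights plus generated input matrices."""

    true_weights: WeightVector
    pairwise: PairwiseMatrix
    decision: DecisionMatrix
    seed: int
    inconsistency_level: float = 0.0
    snap_to_saaty: bool = False


@dataclass(frozen=True)
class SensitivityResult:
    """Rank-stability frequencies under weight perturbation and per-criterion
    knockout rankings."""

    alternatives: tuple[str, ...]
    rank_stability: np.ndarray | None = None  # (m,) frequencies in [0, 1]
    knockout: dict = field(default_factory=dict)  # criterion id -> ordering list
    epsilon: float | None = None
    samples: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        d: dict = {"alternatives": list(self.alternatives)}
        if self.rank_stability is not None:
            d["rank_stability"] = {
                a: float(f) for a, f in zip(self.alternatives, self.rank_stability)
            }
            d["parameters"] = {
                "epsilon": self.epsilon, "samples": self.samples, "seed": self.seed,
            }
        if self.knockout:
            d["knockout"] = {c: list(order) for c, order in self.knockout.items()}
        return d
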