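"""Alternative ranking by Additive Ratio Assessment.

The decision matrix holds raw performance scores of m alternatives on n
criteria, extended by an optimal-value row: the ideal alternative that takes,
per criterion, the best attainable value (column maximum for benefit criteria,
minimum for cost criteria).  Each column - optimal row included - is
share-normalized to sum to one (cost criteria are first inverted, x -> 1/x),
multiplied by the criterion weights, and summed per row into the optimality
function S_i.  The utility degree K_i = S_i / S_0 measures each alternative
against the ideal; rank 1 goes to the largest K.

With a derived optimal row every K_i lies in (0, 1]: the ideal row's share is
the column-wise maximum, so no alternative's weighted row sum can exceed S_0.
A user-supplied optimal row may break that bound, which is flagged as a
warning at construction time.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import DomainError, ReconciliationError, StructuralError
from .types import (
    COST,
    ArasResult,
    DecisionMatrix,
    NormalizedDecision,
    WeightedDecision,
    WeightVector,
    as_criteria,
)


def build_decision_matrix(
    scores,
    alternatives: Sequence[str] | None = None,
    criteria: Sequence | None = None,
    optimal_row=None,
) -> DecisionMatrix:
    """Assemble and validate a decision matrix, deriving the optimal row if absent."""
    grid = np.asarray(scores, dtype=float)
    if grid.ndim != 2:
        raise StructuralError(f"scores must be a 2-D grid, got shape {grid.shape}")
    m, n = grid.shape
    if m < 1 or n < 1:
        raise StructuralError("decision matrix needs at least one alternative and one criterion")
    specs = as_criteria(criteria, n)
    if alternatives is None:
        alternatives = tuple(f"Ap{i + 1}" for i in range(m))
    else:
        alternatives = tuple(str(a) for a in alternatives)
        if len(alternatives) != m:
            raise StructuralError(f"expected {m} alternative labels, got {len(alternatives)}")
    if not np.all(np.isfinite(grid)):
        raise DomainError("scores contain non-finite values")
    bad = np.argwhere(grid <= 0)
    if len(bad):
        i, j = bad[0]
        raise DomainError(
            f"score ({alternatives[i]}, {specs[j].id}) = {grid[i, j]} is not strictly positive"
        )

    is_cost = np.array([c.direction == COST for c in specs])
    derived = np.where(is_cost, grid.min(axis=0), grid.max(axis=0))

    warnings: list[str] = []
    if optimal_row is None:
        ov = derived
        source = "derived"
    else:
        ov = np.asarray(optimal_row, dtype=float)
        if ov.shape != (n,):
            raise StructuralError(f"optimal row must have {n} values, got shape {ov.shape}")
        if np.any(ov <= 0):
            raise DomainError("optimal-row values must be strictly positive")
        source = "user"
        for j, spec in enumerate(specs):
            worse = ov[j] < derived[j] if not is_cost[j] else ov[j] > derived[j]
            if worse:
                warnings.append(
                    f"user optimal value for {spec.id} ({ov[j]}) is beaten by an "
                    f"alternative ({derived[j]}); utility degrees may exceed 1"
                )
    return DecisionMatrix(
        alternatives=alternatives,
        criteria=specs,
        scores=grid,
        optimal_row=ov,
        optimal_source=source,
        warnings=tuple(warnings),
    )


def normalize_decision(d: DecisionMatrix) -> NormalizedDecision:
    """Share-normalize each column of the (optimal row + alternatives) stack.

    Benefit criterion: x_ij / sum_i x_ij over rows 0..m (row 0 = optimal).
    Cost criterion: invert scores first (x -> 1/x), then the same share
    normalization, so cheaper is better.
    """
    stack = np.vstack([d.optimal_row, d.scores])
    is_cost = np.array([c.direction == COST for c in d.criteria])
    work = stack.copy()
    work[:, is_cost] = 1.0 / work[:, is_cost]
    values = work / work.sum(axis=0)
    return NormalizedDecision(
        alternatives=d.alternatives, criteria=d.criterion_labels, values=values
    )


def apply_weights(nd: NormalizedDecision, w: WeightVector) -> WeightedDecision:
    """Multiply each normalized column by its criterion weight (full precision)."""
    if len(nd.criteria) != w.n:
        raise StructuralError(
            f"normalized matrix has {len(nd.criteria)} criteria, weights have {w.n}"
        )
    if tuple(nd.criteria) != tuple(w.criteria):
        raise ReconciliationError(
            f"criterion ids differ between matrix {list(nd.criteria)} and "
            f"weights {list(w.criteria)}"
        )
    return WeightedDecision(
        alternatives=nd.alternatives,
        criteria=nd.criteria,
        values=nd.values * w.weights,
    )


def optimality_function(wd: WeightedDecision) -> np.ndarray:
    """Row sums S_i of the weighted normalized matrix; index 0 is the optimal row.

    Because each column sums to its weight and the weights sum to one, the
    S values over all rows (ideal included) always sum to one.
    """
    return wd.values.sum(axis=1)


def utility_degrees(s: np.ndarray) -> np.ndarray:
    """K_i = S_i / S_0 for every alternative (s[0] is the optimal row's S_0)."""
    s = np.asarray(s, dtype=float)
    if s[0] <= 0:
        raise DomainError("optimal-row optimality value S_0 must be positive")
    return s[1:] / s[0]


def rank_alternatives(k: np.ndarray) -> np.ndarray:
    """Competition ranks: 1 for the largest K; ties share the minimum rank."""
    k = np.asarray(k, dtype=float)
    if k.size == 0:
        raise StructuralError("cannot rank an empty utility vector")
    # rank_i = 1 + number of strictly better alternatives
    return 1 + (k[None, :] > k[:, None]).sum(axis=1)


def aras_full(d: DecisionMatrix, w: WeightVector) -> ArasResult:
    """Full pipeline: normalize, weight, sum, divide by the ideal, rank."""
    if tuple(d.criterion_labels) != tuple(w.criteria):
        raise ReconciliationError(
            f"criterion ids differ between decision matrix {list(d.criterion_labels)} "
            f"and weights {list(w.criteria)}"
        )
    nd = normalize_decision(d)
    wd = apply_weights(nd, w)
    s = optimality_function(wd)
    k = utility_degrees(s)
    ranks = rank_alternatives(k)
    return ArasResult(
        alternatives=d.alternatives,
        s0=float(s[0]),
        s_values=s[1:],
        k_values=k,
        ranks=ranks,
        normalized=nd,
        weighted=wd,
        warnings=d.warnings,
    )
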