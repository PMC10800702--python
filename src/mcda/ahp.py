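"""Criterion weighting by the Analytic Hierarchy Process.

A panel's pairwise importance judgments on the Saaty 1-9 scale form a positive
reciprocal matrix ``A`` with ``a_ji = 1/a_ij``.  Weights are derived by column
normalization followed by row averaging (the arithmetic-mean method): each
entry is divided by its column sum, then each row of the normalized matrix is
averaged over the ``n`` criteria.  Consistency of the judgments is quantified
through the maximum-eigenvalue estimate

    lambda_max = mean_i  (A w)_i / w_i,
    CI = (lambda_max - n) / (n - 1),
    CR = CI / RI(n),

with Saaty's random index RI.  CR <= 0.10 is the conventional acceptance
threshold; a larger CR yields a warning status, never a hard failure, so the
analyst can decide whether to revisit the judgments.

Saaty's principal-eigenvector weights are available as an optional
cross-check; the column-mean method remains the weighting route.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    DomainError,
    ReciprocityError,
    ScaleError,
    StructuralError,
)
from .types import ConsistencyReport, CriterionSpec, PairwiseMatrix, WeightVector, as_criteria

SAATY_MIN = 1.0 / 9.0
SAATY_MAX = 9.0

#: Saaty's random index by matrix order (average CI of random reciprocal
#: matrices); order 1 and 2 matrices are always consistent.
RANDOM_INDEX: dict[int, float] = {
    1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32, 8: 1.41,
    9: 1.45, 10: 1.49, 11: 1.51, 12: 1.48, 13: 1.56, 14: 1.57, 15: 1.59,
}


def validate_pairwise(
    raw_grid,
    criteria: Sequence | None = None,
    *,
    reciprocity_tol: float = 0.05,
    scale_tol: float = 0.05,
    scale_action: str = "warn",
) -> PairwiseMatrix:
    """Check a raw judgment grid and wrap it as a :class:`PairwiseMatrix`.

    Reciprocity is checked multiplicatively, ``|a_ij * a_ji - 1| <= tol``,
    which admits printed two-decimal roundings of reciprocals (0.33 for 1/3,
    0.13 for 1/8).  Entries outside the Saaty range ``[1/9, 9]`` (with the
    same relative slack) raise or warn according to *scale_action*
    ('error' | 'warn' | 'ignore').
    """
    grid = np.asarray(raw_grid, dtype=float)
    if grid.ndim != 2 or grid.shape[0] != grid.shape[1]:
        raise StructuralError(f"pairwise grid must be square, got shape {grid.shape}")
    n = grid.shape[0]
    if n < 2:
        raise StructuralError("pairwise matrix needs at least 2 criteria")
    specs = as_criteria(criteria, n)
    labels = [c.id for c in specs]

    if not np.all(np.isfinite(grid)):
        raise DomainError("pairwise grid contains non-finite entries")
    bad = np.argwhere(grid <= 0)
    if len(bad):
        i, j = bad[0]
        raise DomainError(
            f"judgment ({labels[i]}, {labels[j]}) = {grid[i, j]} is not strictly positive"
        )
    for i in range(n):
        if abs(grid[i, i] - 1.0) > reciprocity_tol:
            raise ReciprocityError(
                f"diagonal entry ({labels[i]}, {labels[i]}) = {grid[i, i]} differs from 1"
            )
    for i in range(n):
        for j in range(i + 1, n):
            prod = grid[i, j] * grid[j, i]
            if abs(prod - 1.0) > reciprocity_tol:
                raise ReciprocityError(
                    f"entries ({labels[i]}, {labels[j]}) = {grid[i, j]} and "
                    f"({labels[j]}, {labels[i]}) = {grid[j, i]} are not reciprocal "
                    f"(product {prod:.4f})"
                )

    warnings: list[str] = []
    if scale_action != "ignore":
        lo = SAATY_MIN * (1.0 - scale_tol)
        hi = SAATY_MAX * (1.0 + scale_tol)
        off = np.argwhere((grid < lo) | (grid > hi))
        for i, j in off:
            msg = (
                f"judgment ({labels[i]}, {labels[j]}) = {grid[i, j]} lies outside "
                f"the Saaty scale [1/9, 9]"
            )
            if scale_action == "error":
                raise ScaleError(msg)
            warnings.append(msg)

    return PairwiseMatrix(criteria=specs, entries=grid, warnings=tuple(warnings))


def normalize_pairwise(m: PairwiseMatrix) -> np.ndarray:
    """Divide every judgment by its column sum; result columns each sum to 1."""
    return m.entries / m.entries.sum(axis=0)


def derive_weights(normalized: np.ndarray, criteria: Sequence | None = None) -> WeightVector:
    """Average each row of the column-normalized matrix over the n criteria."""
    normalized = np.asarray(normalized, dtype=float)
    n = normalized.shape[0]
    colsums = normalized.sum(axis=0)
    if not np.allclose(colsums, 1.0, atol=1e-9):
        raise DomainError("input is not column-normalized (column sums differ from 1)")
    specs = as_criteria(criteria, n)
    weights = normalized.sum(axis=1) / n
    return WeightVector(criteria=tuple(c.id for c in specs), weights=weights)


def weighted_sum_values(m: PairwiseMatrix, w: WeightVector) -> np.ndarray:
    """Per-criterion weighted sums ``(A w)_i`` of the raw judgment matrix."""
    if m.n != w.n:
        raise StructuralError(f"matrix order {m.n} != weight count {w.n}")
    return m.entries @ w.weights


def lambda_max(wsv: np.ndarray, w: WeightVector) -> float:
    """Arithmetic mean over criteria of (A w)_i / w_i.

    For a positive reciprocal matrix this never falls below n (each symmetric
    pair contributes a_ij r + 1/(a_ij r) >= 2 with r = w_j/w_i).
    """
    zero = np.argwhere(w.weights <= 0)
    if len(zero):
        raise DomainError(
            f"criterion {w.criteria[zero[0][0]]} has non-positive weight; "
            "cannot form the ratio (A w)_i / w_i"
        )
    return float(np.mean(np.asarray(wsv, dtype=float) / w.weights))


def consistency_index(lmax: float, n: int) -> float:
    """CI = (lambda_max - n) / (n - 1); zero for perfectly consistent judgments."""
    if n < 2:
        raise DomainError("consistency index requires n >= 2")
    return (lmax - n) / (n - 1)


def consistency_ratio(
    ci: float,
    n: int,
    threshold: float = 0.10,
    ri: float | None = None,
) -> tuple[float, float, str]:
    """CR = CI / RI(n) and its status against the acceptance threshold.

    Returns ``(cr, ri_used, status)``.  For n <= 2 the random index is zero
    and CR is defined as 0 (such matrices are always consistent).  Orders
    outside the bundled RI table require an explicit *ri*.
    """
    if ri is None:
        if n not in RANDOM_INDEX:
            raise ConfigurationError(
                f"no random-index value for n={n}; supply ri= explicitly"
            )
        ri = RANDOM_INDEX[n]
    cr = 0.0 if ri == 0 else ci / ri
    status = "consistent" if cr <= threshold else "warning"
    return cr, float(ri), status


def eigenvector_weights(m: PairwiseMatrix) -> np.ndarray:
    """Principal-eigenvector weights (Saaty's classical method), summing to 1."""
    vals, vecs = np.linalg.eig(m.entries)
    k = int(np.argmax(vals.real))
    v = np.abs(vecs[:, k].real)
    return v / v.sum()


def ahp_full(
    m: PairwiseMatrix,
    *,
    cr_threshold: float = 0.10,
    ri: float | None = None,
    method: str = "column-mean",
    eigenvector_check: bool = False,
) -> tuple[WeightVector, ConsistencyReport]:
    """Weights plus consistency diagnostics in one pass, all at full precision.

    *method* selects the weighting route: ``column-mean`` (column
    normalization + row averaging, the default) or ``eigenvector`` (Saaty's
    principal eigenvector).  With *eigenvector_check* the report also carries
    the maximum absolute difference between the two routes' weights (zero for
    a perfectly consistent matrix).
    """
    if method == "column-mean":
        weights = derive_weights(normalize_pairwise(m), m.criteria)
    elif method == "eigenvector":
        weights = WeightVector(m.labels, eigenvector_weights(m))
    else:
        raise ConfigurationError(f"unknown weighting method {method!r}")
    wsv = weighted_sum_values(m, weights)
    ratios = wsv / weights.weights
    lmax = lambda_max(wsv, weights)
    ci = consistency_index(lmax, m.n)
    cr, ri_used, status = consistency_ratio(ci, m.n, threshold=cr_threshold, ri=ri)
    delta = None
    if eigenvector_check:
        column_mean = derive_weights(normalize_pairwise(m), m.criteria).weights
        delta = float(np.max(np.abs(eigenvector_weights(m) - column_mean)))
    report = ConsistencyReport(
        lambda_max=lmax,
        ci=ci,
        ri=ri_used,
        cr=cr,
        n=m.n,
        threshold=cr_threshold,
        status=status,
        row_ratios=ratios,
        weighted_sum_values=wsv,
        eigenvector_delta=delta,
    )
    return weights, report
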