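"""Rank-stability diagnostics for a finished evaluation.

Two probes of how fragile a ranking is:

* weight perturbation - each weight is jittered by a relative factor drawn
  uniformly from [-epsilon, +epsilon], the vector renormalized, and the
  ranking recomputed; the result is the frequency with which each alternative
  keeps its original rank.  The perturbation is relative because derived
  weights typically span an order of magnitude.
* criterion knockout - each criterion in turn is removed, the remaining
  weights renormalized to sum to one, and the ranking recomputed.

Both reuse the report's own decision matrix and weights, so the probes always
refer to the exact study that produced the ranking.
"""

from __future__ import annotations

import numpy as np

from .aras import aras_full
from .errors import DomainError, StructuralError
from .hybrid import HybridReport
from .types import DecisionMatrix, SensitivityResult, WeightVector


def _base_noise(samples: int, n: int, seed: int) -> np.ndarray:
    # One noise panel shared across epsilon values for a given seed, so
    # stability at different epsilons is comparable draw-by-draw.
    return np.random.default_rng(seed).uniform(-1.0, 1.0, size=(samples, n))


def weight_perturbation_stability(
    report: HybridReport,
    epsilon: float = 0.05,
    samples: int = 1000,
    seed: int = 0,
) -> SensitivityResult:
    """Frequency each alternative keeps its rank under relative weight jitter."""
    if epsilon < 0:
        raise DomainError("epsilon must be >= 0")
    if samples < 1:
        raise DomainError("samples must be >= 1")
    w = report.weights.weights
    base_ranks = report.ranking.ranks
    noise = _base_noise(samples, len(w), seed)
    kept = np.zeros(len(base_ranks))
    for row in noise:
        wp = w * (1.0 + epsilon * row)
        wp = wp / wp.sum()
        res = aras_full(report.decision, WeightVector(report.weights.criteria, wp))
        kept += res.ranks == base_ranks
    return SensitivityResult(
        alternatives=report.ranking.alternatives,
        rank_stability=kept / samples,
        epsilon=epsilon,
        samples=samples,
        seed=seed,
    )


def criterion_knockout(report: HybridReport) -> SensitivityResult:
    """Ranking with each criterion removed and the rest renormalized."""
    d = report.decision
    if d.n < 2:
        raise StructuralError("knockout needs at least 2 criteria")
    w = report.weights.weights
    rankings: dict[str, list[str]] = {}
    for j, label in enumerate(report.weights.criteria):
        keep = np.arange(d.n) != j
        w_rest = w[keep]
        if w_rest.sum() <= 0:
            raise DomainError(f"all weight sits on criterion {label}; cannot renormalize")
        reduced = DecisionMatrix(
            alternatives=d.alternatives,
            criteria=tuple(c for k, c in enumerate(d.criteria) if keep[k]),
            scores=d.scores[:, keep],
            optimal_row=d.optimal_row[keep],
            optimal_source=d.optimal_source,
        )
        wv = WeightVector(
            tuple(c for k, c in enumerate(report.weights.criteria) if keep[k]),
            w_rest / w_rest.sum(),
        )
        rankings[label] = list(aras_full(reduced, wv).ordering())
    return SensitivityResult(alternatives=d.alternatives, knockout=rankings)


def sensitivity_suite(
    report: HybridReport,
    epsilon: float = 0.05,
    samples: int = 1000,
    seed: int = 0,
) -> SensitivityResult:
    """Both probes in one result object."""
    stab = weight_perturbation_stability(report, epsilon=epsilon, samples=samples, seed=seed)
    ko = criterion_knockout(report)
    return SensitivityResult(
        alternatives=stab.alternatives,
        rank_stability=stab.rank_stability,
        knockout=ko.knockout,
        epsilon=epsilon,
        samples=samples,
        seed=seed,
    )
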