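"""Synthetic AHP/ARAS inputs with known ground truth.

The generator emulates what an expert panel produces: a reciprocal Saaty-scale
judgment matrix and an integer 1-9 performance score matrix.  A pairwise
matrix is built from a ground-truth weight vector as ``a_ij = (w_i/w_j) e_ij``
with log-symmetric multiplicative jitter (``e_ji = 1/e_ij``), so reciprocity
holds exactly at every inconsistency level; at level zero the matrix is
perfectly consistent and the weighting stage must recover the truth.
Optionally each upper-triangle entry snaps to the nearest admissible Saaty
value (nearest in log-space, so x and 1/x are treated symmetrically), the
discretization a human judge is forced into.

Every stochastic operation takes an explicit seed; there is no hidden global
random state.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .aras import build_decision_matrix
from .ahp import SAATY_MAX, SAATY_MIN, validate_pairwise
from .errors import ConfigurationError, DomainError
from .types import DecisionMatrix, PairwiseMatrix, Scenario, WeightVector

#: Admissible Saaty judgment values: 1/9..1/2 and 1..9.
SAATY_VALUES = np.array(
    [1.0 / k for k in range(9, 1, -1)] + [float(k) for k in range(1, 10)]
)
_LOG_SAATY = np.log(SAATY_VALUES)


def _snap(value: float) -> float:
    return float(SAATY_VALUES[np.argmin(np.abs(np.log(value) - _LOG_SAATY))])


def generate_consistent_pairwise(
    true_weights,
    seed: int = 0,
    inconsistency_level: float = 0.0,
    snap_to_saaty: bool = False,
) -> PairwiseMatrix:
    """Pairwise matrix around a ground-truth weight vector.

    inconsistency_level is the standard deviation of the jitter on the log
    scale; 0 gives an exactly consistent matrix.  Ratios outside [1/9, 9] are
    clamped (with a warning) before snapping.
    """
    w = np.asarray(true_weights, dtype=float)
    if np.any(w <= 0):
        raise DomainError("true weights must be strictly positive")
    if abs(w.sum() - 1.0) > 1e-8:
        raise DomainError("true weights must sum to 1")
    if inconsistency_level < 0:
        raise DomainError("inconsistency_level must be >= 0")
    n = len(w)
    rng = np.random.default_rng(seed)
    a = np.ones((n, n))
    warnings: list[str] = []
    for i in range(n):
        for j in range(i + 1, n):
            v = w[i] / w[j]
            if inconsistency_level > 0:
                v *= float(np.exp(rng.normal(0.0, inconsistency_level)))
            if snap_to_saaty:
                if v > SAATY_MAX or v < SAATY_MIN:
                    warnings.append(
                        f"ratio {v:.3g} at ({i + 1}, {j + 1}) outside the Saaty "
                        "range; clamped"
                    )
                    v = min(max(v, SAATY_MIN), SAATY_MAX)
                v = _snap(v)
            a[i, j] = v
            a[j, i] = 1.0 / v
    m = validate_pairwise(a, reciprocity_tol=1e-9, scale_action="warn")
    if warnings:
        m = PairwiseMatrix(m.criteria, m.entries, m.warnings + tuple(warnings))
    return m


def generate_decision_scenario(
    m: int,
    n: int,
    directions: Sequence[str] | None = None,
    score_range: tuple[int, int] = (1, 9),
    seed: int = 0,
) -> DecisionMatrix:
    """Uniform integer expert scores on [lo, hi], optimal row derived."""
    lo, hi = score_range
    if lo > hi:
        raise ConfigurationError(f"empty score range {score_range}")
    if lo <= 0:
        raise DomainError("scores must be strictly positive; score_range low end must be >= 1")
    rng = np.random.default_rng(seed)
    scores = rng.integers(lo, hi + 1, size=(m, n)).astype(float)
    criteria = None
    if directions is not None:
        from .types import CriterionSpec

        criteria = [CriterionSpec(f"C{j + 1}", direction=d) for j, d in enumerate(directions)]
    return build_decision_matrix(scores, criteria=criteria)


def perturb_decision(d: DecisionMatrix, noise_sd: float, seed: int = 0) -> DecisionMatrix:
    """Additive Gaussian noise on raw scores, truncated to stay positive.

    Integer inputs stay integers (rounded, floored at 1); the optimal row is
    re-derived from the perturbed scores.
    """
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    noisy = d.scores + rng.normal(0.0, noise_sd, size=d.scores.shape)
    if np.allclose(d.scores, np.round(d.scores)):
        noisy = np.maximum(np.round(noisy), 1.0)
    else:
        noisy = np.maximum(noisy, d.scores.min() * 1e-3)
    return build_decision_matrix(noisy, alternatives=d.alternatives, criteria=d.criteria)


def generate_scenario(
    n_criteria: int,
    n_alternatives: int,
    seed: int = 0,
    inconsistency_level: float = 0.0,
    snap_to_saaty: bool = False,
    true_weights=None,
) -> Scenario:
    """A complete synthetic study with independent sub-streams per stage.

    Default ground-truth weights are Dirichlet(3) draws: moderately uneven,
    with weight ratios that usually stay inside the Saaty range.
    """
    ss = np.random.SeedSequence(seed)
    s_weights, s_pairwise, s_decision = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))
    if true_weights is None:
        rng = np.random.default_rng(s_weights)
        true_weights = rng.dirichlet(np.full(n_criteria, 3.0))
    w = np.asarray(true_weights, dtype=float)
    pairwise = generate_consistent_pairwise(
        w, seed=s_pairwise, inconsistency_level=inconsistency_level, snap_to_saaty=snap_to_saaty
    )
    decision = generate_decision_scenario(n_alternatives, n_criteria, seed=s_decision)
    return Scenario(
        true_weights=WeightVector(pairwise.labels, w),
        pairwise=pairwise,
        decision=decision,
        seed=seed,
        inconsistency_level=inconsistency_level,
        snap_to_saaty=snap_to_saaty,
    )
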