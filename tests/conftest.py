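"""Shared fixtures and independent naive oracles.

The oracles re-implement the weighting and ranking arithmetic with explicit
Python loops and no shared code, so agreement with the vectorized library is
a genuine cross-check rather than a tautology.
"""

import numpy as np
import pytest

import mcda


@pytest.fixture(scope="session")
def study():
    """The bundled health-monitoring case study (pairwise, decision)."""
    return mcda.load_health_apps_study()


@pytest.fixture(scope="session")
def pairwise(study):
    return study[0]


@pytest.fixture(scope="session")
def decision(study):
    return study[1]


@pytest.fixture(scope="session")
def study_weights(pairwise):
    w, _ = mcda.ahp_full(pairwise)
    return w


# --------------------------------------------------------------------------
# naive oracles (explicit loops, no numpy vectorization, no library calls)

def naive_ahp_weights(grid):
    """Column-normalize and row-average with plain loops."""
    n = len(grid)
    colsums = [sum(grid[i][j] for i in range(n)) for j in range(n)]
    weights = []
    for i in range(n):
        rowsum = 0.0
        for j in range(n):
            rowsum += grid[i][j] / colsums[j]
        weights.append(rowsum / n)
    return weights


def naive_weighted_sums(grid, weights):
    n = len(grid)
    return [sum(grid[i][j] * weights[j] for j in range(n)) for i in range(n)]


def naive_aras(scores, directions, weights):
    """Full additive-ratio pipeline with plain loops.

    Returns (S0, S list, K list) with the optimal row derived from the
    scores per direction.
    """
    m, n = len(scores), len(scores[0])
    optimal = []
    for j in range(n):
        col = [scores[i][j] for i in range(m)]
        optimal.append(min(col) if directions[j] == "cost" else max(col))
    stack = [optimal] + [list(r) for r in scores]
    for j in range(n):
        if directions[j] == "cost":
            for i in range(m + 1):
                stack[i][j] = 1.0 / stack[i][j]
    s = [0.0] * (m + 1)
    for j in range(n):
        colsum = sum(stack[i][j] for i in range(m + 1))
        for i in range(m + 1):
            s[i] += stack[i][j] / colsum * weights[j]
    k = [s[i] / s[0] for i in range(1, m + 1)]
    return s[0], s[1:], k


@pytest.fixture(scope="session")
def naive():
    class Oracles:
        ahp_weights = staticmethod(naive_ahp_weights)
        weighted_sums = staticmethod(naive_weighted_sums)
        aras = staticmethod(naive_aras)

    return Oracles


def random_reciprocal(rng, n):
    """Random Saaty-scale reciprocal matrix (independent of the generator)."""
    a = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = float(rng.choice(mcda.SAATY_VALUES))
            a[i, j] = v
            a[j, i] = 1.0 / v
    return a


@pytest.fixture(scope="session")
def make_reciprocal():
    return random_reciprocal
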