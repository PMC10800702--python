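# Methods

## Model and procedure

The package implements a two-stage multi-criteria decision analysis. Stage
one (AHP) turns a panel's pairwise criterion comparisons into weights; stage
two (ARAS) ranks alternatives by how close their weighted normalized
performance comes to an ideal alternative. The stages are coupled only
through the weight vector, which is passed at full floating-point precision —
rounding is purely a display concern.

**Weighting.** The judgment matrix `A` is positive and reciprocal
(`a_ji = 1/a_ij`, unit diagonal), with entries on the Saaty 1–9 scale.
Weights are the row means of the column-normalized matrix. This arithmetic
"column-mean" method is the package's primary route; Saaty's
principal-eigenvector method is provided as an alternative and as a
cross-check, and the two coincide exactly on consistent matrices. The
column-mean route was chosen as primary because it is the method the bundled
case study uses and its arithmetic is transparent enough to audit by hand.

**Consistency.** `λmax` is estimated as the mean over criteria of
`(Aw)_i / w_i`. For any positive reciprocal matrix this estimate is ≥ n
(each symmetric pair contributes `x + 1/x ≥ 2`), so `CI = (λmax − n)/(n − 1)`
is nonnegative. `CR = CI/RI(n)` uses Saaty's random-index table
(0, 0, 0.58, 0.90, 1.12, 1.24, 1.32, 1.41, 1.45, 1.49, 1.51, 1.48, 1.56,
1.57, 1.59 for n = 1…15), overridable for other orders. For n ≤ 2, RI = 0
and CR is defined as 0 — a 2×2 reciprocal matrix is always consistent. A CR
above the threshold (default 0.10) sets a *warning* status and is carried in
the report's warning list; it never aborts, because inconsistency is a
property of the judgments the analyst must weigh, not a computational
failure. The ratio-mean `λmax` tracks the principal eigenvalue closely in
the moderate-inconsistency regime typical of expert panels (within ~2% at
jitter levels around 0.25 on the log scale) but can deviate more for wildly
inconsistent matrices; in that regime CR will be far above threshold anyway.

**Ranking.** The decision matrix rows are indexed 0…m with row 0 the optimal
row. The optimal row is included in every column's normalization
denominator; this matters (many ARAS write-ups are ambiguous) and makes the
normalized columns of m+1 rows sum to one. Cost criteria are inverted
(`x → 1/x`, optimal row included) before share normalization, which makes a
cost criterion with scores `x` exactly equivalent to a benefit criterion
with scores `1/x`. Because each weighted column sums to its weight and
weights sum to one, the optimality values of all rows sum to one — a useful
conservation check. With a derived optimal row its share is the column-wise
maximum, so `K_i = S_i/S_0 ∈ (0, 1]`; a user-supplied optimal row that is
beaten by an alternative breaks the bound and is flagged with a warning at
construction.

**Ranking convention.** Rank 1 goes to the largest utility degree. Ties take
the minimum (competition) rank and report order follows input order, so the
output is deterministic; the tie convention is the package's own choice
since panel data rarely ties exactly.

## Tunable parameters

| Parameter | Default | Meaning |
|---|---|---|
| `cr_threshold` | 0.10 | CR above this sets status `warning` (conventional AHP cutoff) |
| `reciprocity_tol` | 0.05 | relative tolerance on `a_ij·a_ji = 1`; admits 2-dp printed reciprocals (0.33 for 1/3, 0.13 for 1/8, product up to 1.04) |
| `scale_tol` / `scale_action` | 0.05 / `warn` | slack around the Saaty range `[1/9, 9]`; out-of-range entries warn by default, can error or be ignored |
| `weight_decimals`, `table_decimals` | 2, 3 | display rounding in reports only |
| sensitivity `epsilon` | 0.05 | *relative* weight jitter: weights span an order of magnitude, so absolute jitter would swamp small weights |

All quantities are dimensionless: judgments are ratios of importance, scores
are panel ratings, weights and utility degrees are normalized shares.

## What the scenario generator emulates

The generator mimics the two artifacts an expert panel produces. Pairwise
matrices are built from a ground-truth weight vector as
`a_ij = (w_i/w_j)·ε_ij` with log-symmetric multiplicative jitter mirrored
across the diagonal (`ε_ji = 1/ε_ij`), so reciprocity is exact at every
inconsistency level and level 0 gives a perfectly consistent matrix. The
jitter is Gaussian on the log scale with standard deviation equal to the
`inconsistency_level`; mean CR grows monotonically with it, which the tests
verify by Monte Carlo. Optional snapping discretizes each upper-triangle
entry to the nearest admissible Saaty value *in log space* — so `x` and
`1/x` snap symmetrically, the natural metric for a reciprocal scale — and
mirrors the reciprocal; ratios outside `[1/9, 9]` are clamped with a
warning. Decision matrices are uniform integer scores on 1–9, matching the
observed range of panel ratings; default ground-truth weights are
Dirichlet(3) draws, uneven enough to be interesting while usually keeping
weight ratios within the representable Saaty range. Score perturbation adds
truncated Gaussian noise (integer inputs are re-rounded and floored at 1)
and re-derives the optimal row.

What the generator does **not** model: correlation between criteria scores,
systematic expert bias, panel aggregation (the tool ingests one finished
judgment matrix), or non-uniform score distributions. Passing tests
therefore demonstrate correctness of the arithmetic and robustness under
idealized noise, not validity of any particular panel's judgments.

## Numerical choices

- Chained computations stay at full precision; the published tables the
  fixtures reproduce were rounded at 2–3 decimals, so tests compare at the
  printed precision (±0.005 / ±0.0015 cell-wise) and allow ±0.02/±0.05 on
  weighted-sum and ratio columns whose source rounded intermediates.
- Conservation invariants (column sums, ΣS = 1) are asserted at 1e-12;
  consistent-matrix weight recovery at 1e-10; `λmax ≥ n` at 1e-9.
- A zero or negative judgment or score is a hard error, never clamped; a
  zero weight is allowed in a `WeightVector` (a criterion can be worthless)
  but is rejected where a ratio would divide by it.
- Sensitivity draws one uniform noise panel per seed and scales it by
  epsilon, so stability at different epsilons is compared draw-by-draw
  (coupled Monte Carlo), making the degradation-with-epsilon comparison
  noise-free.
- Report JSON is serialized with sorted keys; identical inputs and config
  produce byte-identical output apart from the timestamp, and
  serialize→deserialize→serialize is byte-stable.

## Problem sizes used in tests

The bundled study is 8 criteria × 8 alternatives and runs in milliseconds.
Property sweeps use 200 recovery scenarios (n = 3…8), 1000 random reciprocal
matrices (n = 3…9), 1000 random decision instances, and a few hundred
Monte-Carlo replicates for the stability comparisons; the full suite runs in
a few seconds on one CPU.

## Known limitations

- Single-level criterion hierarchy only; no group-judgment aggregation,
  fuzzy extensions, or incomplete-matrix completion.
- The ratio-mean `λmax` is an estimate; for severely inconsistent matrices
  it can differ from the principal eigenvalue by more than a few percent
  (both still flag such matrices as inconsistent).
- The CR threshold, RI table and Saaty scale are conventions; the tool
  reports against them but cannot decide whether a warning-level CR is
  acceptable for a given study.
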