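# mcda-hybrid

Hybrid AHP–ARAS multi-criteria decision analysis for technology assessment:
derive criterion weights from expert pairwise comparisons (with consistency
diagnostics), then rank alternatives by additive-ratio utility degrees
against an ideal alternative. Built for evaluations like prioritizing
computer-based health-monitoring applications, where a panel scores a handful
of candidate systems against weighted criteria such as real-time ability,
data security, disease monitoring and usability.

## Method

**Weighting (Analytic Hierarchy Process).** Experts compare criteria pairwise
on the Saaty 1–9 scale, giving a positive reciprocal matrix
`A` with `a_ji = 1/a_ij`. Weights come from column normalization followed by
row averaging:

```
w_i = (1/n) Σ_j  a_ij / Σ_k a_kj
```

Judgment coherence is quantified by `λmax = mean_i (Aw)_i / w_i`,
`CI = (λmax − n)/(n − 1)` and `CR = CI / RI(n)` with Saaty's random index
(RI(8) = 1.41). `CR ≤ 0.10` is the conventional acceptance threshold; a
larger CR yields a *warning* status and annotates the report, it never aborts
the run. Saaty's principal-eigenvector weights are available as a
cross-check (`ahp_full(..., eigenvector_check=True)`) or as an alternative
method (`method="eigenvector"`).

**Ranking (Additive Ratio Assessment).** The m×n decision matrix of raw
performance scores is extended by an optimal-value row (column maximum for
benefit criteria, minimum for cost criteria). Every column — optimal row
included — is share-normalized to sum to one (cost criteria are first
inverted, `x → 1/x`), multiplied by the weights, and summed per row into the
optimality function `S_i`. The utility degree

```
K_i = S_i / S_0
```

measures each alternative against the ideal; rank 1 goes to the largest
`K_i`, and with a derived optimal row every `K_i ∈ (0, 1]`.

The package also ships a seeded scenario generator (consistent or
controllably inconsistent pairwise matrices with known ground-truth weights,
integer 1–9 score matrices, score perturbation) and a sensitivity suite
(rank stability under relative weight jitter, per-criterion knockout
rankings).

## Worked example

The bundled case study evaluates eight health-monitoring applications
(Ap1…Ap8) against eight benefit criteria (C1…C8):

```python
import mcda

pairwise, decision = mcda.load_health_apps_study()
weights, consistency = mcda.ahp_full(pairwise)
print({c: round(w, 2) for c, w in weights.as_dict().items()})
print(f"lambda_max={consistency.lambda_max:.2f}  CI={consistency.ci:.2f}  "
      f"CR={consistency.cr:.3f}  status={consistency.status}")

result = mcda.aras_full(decision, weights)
print(f"S0={result.s0:.3f}")
print({a: round(float(k), 3) for a, k in zip(result.alternatives, result.k_values)})
print(" > ".join(result.ordering()))
```

prints

```
{'C1': 0.12, 'C2': 0.03, 'C3': 0.08, 'C4': 0.14, 'C5': 0.1, 'C6': 0.17, 'C7': 0.35, 'C8': 0.02}
lambda_max=9.41  CI=0.20  CR=0.143  status=warning
S0=0.169
{'Ap1': 0.545, 'Ap2': 0.769, 'Ap3': 0.691, 'Ap4': 0.581, 'Ap5': 0.618, 'Ap6': 0.568, 'Ap7': 0.509, 'Ap8': 0.637}
Ap2 > Ap3 > Ap8 > Ap5 > Ap4 > Ap6 > Ap1 > Ap7
```

Usability (C7, weight 0.35) dominates the weighting; the judgments are
somewhat inconsistent (CR ≈ 0.14 > 0.10, hence the warning), which the
analysis reports and proceeds with. Ap2 is the best application (utility
degree 0.769 relative to the ideal), Ap7 the worst (0.509).

The same pipeline is available from a shell:

```
mcda run --pairwise pairwise.csv --decision decision.csv \
         --report report.json --markdown report.md
mcda sensitivity --report report.json --epsilon 0.05 --samples 1000 --seed 1 \
         --out sensitivity.json
```

plus `mcda ahp weights`, `mcda aras rank` and `mcda simulate` for the
individual stages; all input is labeled CSV (UTF-8, comma-delimited, dot
decimals), an optional `OV` row supplies user-chosen optimal values.

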