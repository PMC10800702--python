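"""End-to-end pipeline: pairwise judgments -> weights -> ranking, one report.

The three-level evaluation runs AHP on the criterion judgments, feeds the
full-precision weights into ARAS, and collects every intermediate with
provenance (input digests, configuration echo, tool version, timestamp) into
a single serializable report.  Criterion sets of the two input matrices are
reconciled by id - never silently by position - and the decision matrix is
reordered to the pairwise criterion order when needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import datetime, timezone

import numpy as np

from ._version import __version__
from .ahp import ahp_full, validate_pairwise
from .aras import aras_full
from .errors import ReconciliationError
from .io import matrix_digest
from .types import (
    ArasResult,
    ConsistencyReport,
    CriterionSpec,
    DecisionMatrix,
    PairwiseMatrix,
    StudyConfig,
    WeightVector,
)


@dataclass(frozen=True)
class HybridReport:
    """Everything one evaluation run produced, at full precision."""

    weights: WeightVector
    consistency: ConsistencyReport
    ranking: ArasResult
    pairwise: PairwiseMatrix
    decision: DecisionMatrix
    config: StudyConfig
    provenance: dict

    def to_dict(self) -> dict:
        d = self.decision
        return {
            "provenance": dict(self.provenance),
            "config": self.config.to_dict(),
            "inputs": {
                "pairwise": {
                    "criteria": list(self.pairwise.labels),
                    "entries": [[float(v) for v in row] for row in self.pairwise.entries],
                    "warnings": list(self.pairwise.warnings),
                },
                "decision": {
                    "alternatives": list(d.alternatives),
                    "criteria": list(d.criterion_labels),
                    "directions": [c.direction for c in d.criteria],
                    "scores": [[float(v) for v in row] for row in d.scores],
                    "optimal_row": [float(v) for v in d.optimal_row],
                    "optimal_source": d.optimal_source,
                },
            },
            "weights": {
                "criteria": list(self.weights.criteria),
                "weights": [float(v) for v in self.weights.weights],
            },
            "consistency": self.consistency.to_dict(),
            "ranking": self.ranking.to_dict(),
            "warnings": sorted(
                set(self.pairwise.warnings)
                | set(d.warnings)
                | ({f"consistency ratio {self.consistency.cr:.4f} exceeds "
                    f"threshold {self.consistency.threshold}"}
                   if self.consistency.status == "warning" else set())
            ),
        }

    def to_json(self, include_timestamp: bool = True) -> str:
        d = self.to_dict()
        if not include_timestamp:
            d["provenance"].pop("timestamp", None)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "HybridReport":
        cfg = StudyConfig(**data["config"])
        pw_in = data["inputs"]["pairwise"]
        pairwise = validate_pairwise(
            np.asarray(pw_in["entries"], float),
            pw_in["criteria"],
            reciprocity_tol=cfg.reciprocity_tol,
            scale_tol=cfg.scale_tol,
            scale_action=cfg.scale_action,
        )
        de = data["inputs"]["decision"]
        criteria = tuple(
            CriterionSpec(c, direction=dr) for c, dr in zip(de["criteria"], de["directions"])
        )
        decision = DecisionMatrix(
            alternatives=tuple(de["alternatives"]),
            criteria=criteria,
            scores=np.asarray(de["scores"], float),
            optimal_row=np.asarray(de["optimal_row"], float),
            optimal_source=de["optimal_source"],
        )
        weights = WeightVector(
            tuple(data["weights"]["criteria"]), np.asarray(data["weights"]["weights"], float)
        )
        cons = data["consistency"]
        consistency = ConsistencyReport(
            lambda_max=cons["lambda_max"],
            ci=cons["ci"],
            ri=cons["ri"],
            cr=cons["cr"],
            n=cons["n"],
            threshold=cons["threshold"],
            status=cons["status"],
            row_ratios=np.asarray(cons["row_ratios"], float),
            weighted_sum_values=np.asarray(cons["weighted_sum_values"], float),
            eigenvector_delta=cons.get("eigenvector_delta"),
        )
        rk = data["ranking"]
        ranking = ArasResult(
            alternatives=tuple(rk["alternatives"]),
            s0=rk["S0"],
            s_values=np.asarray(rk["S"], float),
            k_values=np.asarray(rk["K"], float),
            ranks=np.asarray(rk["ranks"], int),
            warnings=tuple(rk["warnings"]),
        )
        return cls(
            weights=weights,
            consistency=consistency,
            ranking=ranking,
            pairwise=pairwise,
            decision=decision,
            config=cfg,
            provenance=dict(data["provenance"]),
        )

    @classmethod
    def from_json(cls, text: str) -> "HybridReport":
        return cls.from_dict(json.loads(text))

    def to_markdown(self) -> str:
        """Human-readable rendering of the weight and ranking sections."""
        wd, td = self.config.weight_decimals, self.config.table_decimals
        lines = ["# Hybrid AHP-ARAS evaluation report", ""]
        lines += ["## Criterion weights and consistency", ""]
        lines += ["| Criterion | Weighted sum value | Weight | Ratio |",
                  "|---|---|---|---|"]
        for c, wsv, w, r in zip(
            self.weights.criteria,
            self.consistency.weighted_sum_values,
            self.weights.weights,
            self.consistency.row_ratios,
        ):
            lines.append(f"| {c} | {wsv:.{wd}f} | {w:.{wd}f} | {r:.{wd}f} |")
        cons = self.consistency
        lines += [
            "",
            f"lambda_max = {cons.lambda_max:.4f}, CI = {cons.ci:.4f}, "
            f"RI = {cons.ri}, CR = {cons.cr:.4f} ({cons.status})",
            "",
            "## Ranking",
            "",
            "| Alternative | S | K | Rank |",
            "|---|---|---|---|",
            f"| (optimal) | {self.ranking.s0:.{td}f} | 1 | |",
        ]
        for a, s, k, r in zip(
            self.ranking.alternatives,
            self.ranking.s_values,
            self.ranking.k_values,
            self.ranking.ranks,
        ):
            lines.append(f"| {a} | {s:.{td}f} | {k:.{td}f} | {r} |")
        return "\n".join(lines) + "\n"


def reconcile_decision(pairwise: PairwiseMatrix, decision: DecisionMatrix) -> DecisionMatrix:
    """Reorder decision columns to the pairwise criterion order, matching by id."""
    pw_ids = list(pairwise.labels)
    de_ids = list(decision.criterion_labels)
    if pw_ids == de_ids:
        return decision
    missing = sorted(set(pw_ids) ^ set(de_ids))
    if missing:
        raise ReconciliationError(
            f"criterion sets of pairwise and decision matrices differ; "
            f"unmatched ids: {missing}"
        )
    order = [de_ids.index(c) for c in pw_ids]
    return DecisionMatrix(
        alternatives=decision.alternatives,
        criteria=tuple(decision.criteria[j] for j in order),
        scores=decision.scores[:, order],
        optimal_row=decision.optimal_row[order],
        optimal_source=decision.optimal_source,
        warnings=decision.warnings,
    )


def run_hybrid(
    pairwise: PairwiseMatrix,
    decision: DecisionMatrix,
    config: StudyConfig | None = None,
) -> HybridReport:
    """AHP weights feed ARAS at full precision; one auditable report out."""
    config = config or StudyConfig()
    decision = reconcile_decision(pairwise, decision)
    weights, consistency = ahp_full(
        pairwise,
        cr_threshold=config.cr_threshold,
        eigenvector_check=config.eigenvector_check,
    )
    ranking = aras_full(decision, weights)
    provenance = {
        "tool": "mcda-hybrid",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "pairwise_digest": matrix_digest(pairwise.entries, pairwise.labels, pairwise.labels),
        "decision_digest": matrix_digest(
            np.vstack([decision.scores, decision.optimal_row]),
            list(decision.alternatives) + ["OV"],
            decision.criterion_labels,
        ),
    }
    return HybridReport(
        weights=weights,
        consistency=consistency,
        ranking=ranking,
        pairwise=pairwise,
        decision=decision,
        config=config,
        provenance=provenance,
    )
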