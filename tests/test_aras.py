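"""Unit tests for the additive-ratio ranking engine."""

import numpy as np
import pytest

import mcda
from mcda.errors import DomainError, ReconciliationError, StructuralError
from mcda.types import CriterionSpec


class TestBuildDecisionMatrix:
    def test_study_optimal_row_is_column_maxima(self, decision):
        assert tuple(decision.optimal_row) == (9, 8, 9, 7, 6, 8, 9, 9)
        assert decision.optimal_source == "derived"

    def test_single_benefit_criterion_takes_max(self):
        d = mcda.build_decision_matrix([[2.0], [5.0], [3.0]])
        assert d.optimal_row[0] == 5.0

    def test_single_cost_criterion_takes_min(self):
        d = mcda.build_decision_matrix(
            [[2.0], [5.0], [3.0]], criteria=[CriterionSpec("C1", direction="cost")]
        )
        assert d.optimal_row[0] == 2.0

    def test_rejects_nonpositive_score(self):
        with pytest.raises(DomainError, match="Ap2"):
            mcda.build_decision_matrix([[1.0, 2.0], [0.0, 3.0]])

    def test_rejects_label_mismatch(self):
        with pytest.raises(StructuralError):
            mcda.build_decision_matrix([[1.0, 2.0]], alternatives=["A", "B"])

    def test_user_optimal_below_column_max_warns(self):
        d = mcda.build_decision_matrix(
            [[2.0, 4.0], [6.0, 3.0]], optimal_row=[4.0, 4.0]
        )
        assert d.optimal_source == "user"
        assert any("exceed 1" in w for w in d.warnings)
        res = mcda.aras_full(d, mcda.WeightVector(("C1", "C2"), np.array([0.5, 0.5])))
        assert res.k_values.max() > 1.0  # the beaten ideal lets K pass 1


class TestNormalizeDecision:
    def test_study_cells(self, decision):
        nd = mcda.normalize_decision(decision)
        assert round(nd.values[0, 0], 2) == 0.19  # optimal row, C1: 9/47
        assert round(nd.values[1, 2], 2) == 0.18  # Ap1, C3: 9/49

    def test_columns_sum_to_one(self, decision):
        nd = mcda.normalize_decision(decision)
        colsums = nd.values.sum(axis=0)
        assert np.max(np.abs(colsums - 1.0)) <= 1e-12
        assert np.all((nd.values > 0) & (nd.values < 1))

    def test_equal_scores_give_uniform_shares(self):
        d = mcda.build_decision_matrix([[4.0], [4.0], [4.0]], optimal_row=[4.0])
        nd = mcda.normalize_decision(d)
        assert np.allclose(nd.values, 0.25)

    def test_column_scale_invariance(self, decision, study_weights):
        scaled = decision.scores.copy()
        scaled[:, 3] *= 10.0
        d2 = mcda.build_decision_matrix(
            scaled, alternatives=decision.alternatives, criteria=decision.criteria
        )
        r1 = mcda.aras_full(decision, study_weights)
        r2 = mcda.aras_full(d2, study_weights)
        assert np.max(np.abs(r1.k_values - r2.k_values)) <= 1e-12
        assert np.array_equal(r1.ranks, r2.ranks)

    def test_cost_benefit_duality(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(1, 9, size=(4, 1))
        cost = mcda.build_decision_matrix(
            x, criteria=[CriterionSpec("C1", direction="cost")]
        )
        benefit = mcda.build_decision_matrix(1.0 / x)
        assert np.allclose(
            mcda.normalize_decision(cost).values,
            mcda.normalize_decision(benefit).values,
        )


class TestWeightingAndOptimality:
    def test_study_weighted_cells(self, decision, study_weights):
        wd = mcda.apply_weights(mcda.normalize_decision(decision), study_weights)
        assert round(wd.values[0, 6], 3) == 0.061  # optimal row, C7
        assert round(wd.values[0, 7], 3) == 0.003
        assert round(wd.values[2, 6], 3) == 0.061  # Ap2, C7

    def test_column_sums_equal_weights(self, decision, study_weights):
        wd = mcda.apply_weights(mcda.normalize_decision(decision), study_weights)
        assert np.max(np.abs(wd.values.sum(axis=0) - study_weights.weights)) <= 1e-12

    def test_uniform_weights_scale_by_one_over_n(self, decision):
        nd = mcda.normalize_decision(decision)
        w = mcda.WeightVector(nd.criteria, np.full(8, 1 / 8))
        wd = mcda.apply_weights(nd, w)
        assert np.allclose(wd.values, nd.values / 8)

    def test_criterion_id_mismatch_raises(self, decision):
        w = mcda.WeightVector(tuple(f"X{i}" for i in range(8)), np.full(8, 1 / 8))
        with pytest.raises(ReconciliationError):
            mcda.apply_weights(mcda.normalize_decision(decision), w)

    def test_study_optimality_values(self, decision, study_weights):
        wd = mcda.apply_weights(mcda.normalize_decision(decision), study_weights)
        s = mcda.optimality_function(wd)
        assert round(s[0], 3) == 0.169  # ideal row
        assert round(s[2], 3) == 0.130  # Ap2
        assert s.sum() == pytest.approx(1.0, abs=1e-12)


class TestUtilityAndRanks:
    def test_study_utility_degrees(self, decision, study_weights):
        res = mcda.aras_full(decision, study_weights)
        k = dict(zip(res.alternatives, np.round(res.k_values, 3)))
        assert k["Ap2"] == 0.769
        assert k["Ap7"] == 0.509

    def test_alternative_equal_to_ideal_has_k_one(self):
        scores = np.array([[9.0, 8.0], [3.0, 2.0], [9.0, 8.0]])
        d = mcda.build_decision_matrix(scores)
        res = mcda.aras_full(d, mcda.WeightVector(("C1", "C2"), np.array([0.4, 0.6])))
        assert res.k_values[0] == pytest.approx(1.0, abs=1e-12)
        assert res.k_values[2] == pytest.approx(1.0, abs=1e-12)

    def test_rank_conventions(self):
        assert list(mcda.rank_alternatives(np.array([0.9, 0.5, 0.7]))) == [1, 3, 2]
        assert list(mcda.rank_alternatives(np.array([0.5, 0.5, 0.5]))) == [1, 1, 1]
        assert list(mcda.rank_alternatives(np.array([0.9, 0.7, 0.5]))) == [1, 2, 3]
        # ties share the minimum rank; the next distinct value skips ranks
        assert list(mcda.rank_alternatives(np.array([0.5, 0.9, 0.9]))) == [3, 1, 1]

    def test_study_ordering(self, decision, study_weights):
        res = mcda.aras_full(decision, study_weights)
        assert res.ordering() == ("Ap2", "Ap3", "Ap8", "Ap5", "Ap4", "Ap6", "Ap1", "Ap7")

    def test_single_alternative_equal_to_own_ideal(self):
        d = mcda.build_decision_matrix([[5.0, 3.0]])
        res = mcda.aras_full(d, mcda.WeightVector(("C1", "C2"), np.array([0.5, 0.5])))
        assert res.k_values[0] == pytest.approx(1.0)
        assert res.ranks[0] == 1


class TestArasFull:
    def test_matches_naive_loop_oracle(self, naive):
        rng = np.random.default_rng(11)
        scores = rng.uniform(1, 9, size=(5, 4))
        directions = ["benefit", "cost", "benefit", "cost"]
        weights = rng.dirichlet(np.ones(4))
        d = mcda.build_decision_matrix(
            scores,
            criteria=[CriterionSpec(f"C{j+1}", direction=dr) for j, dr in enumerate(directions)],
        )
        wv = mcda.WeightVector(d.criterion_labels, weights)
        res = mcda.aras_full(d, wv)
        s0, s, k = naive.aras(scores.tolist(), directions, weights.tolist())
        assert abs(res.s0 - s0) < 1e-12
        assert np.max(np.abs(res.s_values - s)) < 1e-12
        assert np.max(np.abs(res.k_values - k)) < 1e-12

    def test_pairwise_monotonicity_in_benefit_score(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(1, 9, size=(5, 3))
        w = mcda.WeightVector(("C1", "C2", "C3"), rng.dirichlet(np.ones(3)))
        base = mcda.aras_full(mcda.build_decision_matrix(scores), w)
        bumped = scores.copy()
        bumped[2, 1] += 1.0
        res = mcda.aras_full(mcda.build_decision_matrix(bumped), w)
        for j in range(5):
            if j == 2:
                continue
            assert (res.s_values[2] / res.s_values[j]
                    > base.s_values[2] / base.s_values[j])

    def test_permutation_equivariance(self, decision, study_weights):
        rng = np.random.default_rng(9)
        perm = rng.permutation(decision.m)
        d2 = mcda.build_decision_matrix(
            decision.scores[perm],
            alternatives=[decision.alternatives[i] for i in perm],
            criteria=decision.criteria,
        )
        r1 = mcda.aras_full(decision, study_weights)
        r2 = mcda.aras_full(d2, study_weights)
        assert np.max(np.abs(r2.k_values - r1.k_values[perm])) <= 1e-12
        assert np.array_equal(r2.ranks, r1.ranks[perm])
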