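"""ROC-AUC, Mann-Whitney, permutation nulls, and proportional rank."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from ratecov.rank_stats import (
    binomial_tail,
    complex_prop_rank_test,
    global_average_auc_test,
    mann_whitney_one_tailed,
    permute_complex_auc,
    proportional_rank,
    protein_pair_prop_rank,
    roc_auc,
)

from conftest import make_edges


def brute_force_auc(scores, labels):
    """Pair-counting oracle: P(pos > neg) + 0.5 * P(tie)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_positives_on_top(self):
        edges = make_edges([4, 3, 2, 1], [1, 1, 0, 0])
        assert roc_auc(edges).auc == 1.0

    def test_positives_on_bottom(self):
        edges = make_edges([4, 3, 2, 1], [0, 0, 1, 1])
        assert roc_auc(edges).auc == 0.0

    def test_tie_midpoint_oracle(self):
        # pos scores {3,1}, neg {3,0}: AUC = (2 + 0.5)/4
        edges = make_edges([3, 1, 3, 0], [1, 1, 0, 0])
        assert roc_auc(edges).auc == pytest.approx(0.625)

    def test_auc_u_identity_random_lists(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 30))
            scores = rng.integers(0, 8, size=n).astype(float)  # many ties
            labels = np.zeros(n, dtype=int)
            labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            edges = make_edges(scores, labels)
            res = roc_auc(edges)
            assert res.auc == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )
            assert res.auc == pytest.approx(
                res.u_stat / (res.n_pos * res.n_neg), abs=1e-12
            )

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.standard_normal(50)
        labels = (rng.random(50) < 0.3).astype(int)
        labels[0] = 1
        labels[1] = 0
        edges = make_edges(scores, labels)
        assert roc_auc(edges).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_curve_monotone_and_anchored(self, rng):
        scores = rng.integers(0, 5, size=30).astype(float)
        labels = (rng.random(30) < 0.4).astype(int)
        labels[0], labels[1] = 1, 0
        curve = roc_auc(make_edges(scores, labels)).curve
        assert curve[0] == (0.0, 0.0) and curve[-1] == (1.0, 1.0)
        fprs = [p[0] for p in curve]
        tprs = [p[1] for p in curve]
        assert fprs == sorted(fprs) and tprs == sorted(tprs)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.standard_normal(25)
        labels = (rng.random(25) < 0.4).astype(int)
        labels[0], labels[1] = 1, 0
        a1 = roc_auc(make_edges(scores, labels)).auc
        a2 = roc_auc(make_edges(np.exp(2 * scores) + 7, labels)).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both"):
            roc_auc(make_edges([3, 2, 1], [1, 1, 1]))


class TestMannWhitney:
    def test_exact_small_sample(self):
        # n1=2, n0=2, positives on top: p = 1/C(4,2) = 1/6
        edges = make_edges([4, 3, 2, 1], [1, 1, 0, 0])
        assert mann_whitney_one_tailed(edges) == pytest.approx(1 / 6)

    def test_single_vs_single(self):
        edges = make_edges([2, 1], [1, 0])
        assert mann_whitney_one_tailed(edges) == pytest.approx(0.5)

    def test_null_center_large_n(self, rng):
        scores = np.arange(200, dtype=float)
        labels = np.zeros(200, dtype=int)
        labels[::2] = 1  # perfectly interleaved: AUC ~ 0.5
        p = mann_whitney_one_tailed(make_edges(scores, labels))
        assert 0.4 < p < 0.6

    def test_exact_vs_asymptotic_agreement(self, rng):
        # tie-free, n0 = n1 = 8: the two p-values should be within 10%
        scores = rng.standard_normal(16)
        labels = np.array([1] * 8 + [0] * 8)
        pos, neg = scores[labels == 1], scores[labels == 0]
        p_exact = stats.mannwhitneyu(pos, neg, alternative="greater",
                                     method="exact").pvalue
        p_asym = stats.mannwhitneyu(pos, neg, alternative="greater",
                                    method="asymptotic").pvalue
        assert p_asym == pytest.approx(p_exact, rel=0.10)


class TestPermuteComplexAuc:
    def test_seed_determinism(self, rng):
        edges = make_edges(rng.standard_normal(12), [1, 1, 0, 0, 1, 0] * 2)
        r1 = permute_complex_auc(edges, B=100, seed=5)
        r2 = permute_complex_auc(edges, B=100, seed=5)
        assert np.array_equal(r1.null, r2.null)

    def test_converges_to_exhaustive_enumeration(self, rng):
        # 10 edges, 5 positives: C(10,5) = 252 label placements
        scores = rng.standard_normal(10)
        labels = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        edges = make_edges(scores, labels)
        obs = roc_auc(edges).auc
        ranks = stats.rankdata(scores)
        null_exact = [
            (ranks[list(pos)].sum() - 15) / 25
            for pos in combinations(range(10), 5)
        ]
        p_exact = np.mean([a >= obs for a in null_exact])
        B = 1000
        res = permute_complex_auc(edges, B=B, seed=11)
        p_mc = np.sum(res.null >= obs) / B
        se = np.sqrt(p_exact * (1 - p_exact) / B)
        assert abs(p_mc - p_exact) <= 2 * se + 1e-9

    def test_null_mean_half(self, rng):
        edges = make_edges(rng.standard_normal(20),
                           [1] * 6 + [0] * 14)
        res = permute_complex_auc(edges, B=1000, seed=3)
        se = res.null.std() / np.sqrt(len(res.null))
        assert abs(res.null.mean() - 0.5) < 3 * se

    def test_all_positive_rejected(self):
        with pytest.raises(ValueError, match="both"):
            permute_complex_auc(make_edges([3, 2, 1], [1, 1, 1]), B=10, seed=0)


class TestGlobalAverageAuc:
    def test_symmetric_null_gives_p_near_half(self, rng):
        complexes = []
        for _ in range(6):
            scores = rng.standard_normal(16)
            labels = np.zeros(16, dtype=int)
            labels[rng.choice(16, 5, replace=False)] = 1
            complexes.append(make_edges(scores, labels))
        # relabel each complex so observed AUC is itself a random draw
        res = global_average_auc_test(complexes, B=500, seed=7)
        assert 0.001 < res.p <= 1.0
        assert abs(res.null.mean() - 0.5) < 0.05

    def test_two_tiny_complexes_match_joint_enumeration(self):
        # complex 1: 3 edges 1 positive; complex 2: 4 edges 1 positive
        e1 = make_edges([3.0, 2.0, 1.0], [1, 0, 0])
        e2 = make_edges([4.0, 3.0, 2.0, 1.0], [0, 1, 0, 0])
        obs = np.mean([roc_auc(e1).auc, roc_auc(e2).auc])
        auc1 = [(2 - r) / 2 for r in range(3)]  # AUC per position (no ties)
        auc2 = [(3 - r) / 3 for r in range(4)]
        joint = [np.mean([a1, a2]) for a1 in auc1 for a2 in auc2]
        p_exact = np.mean([a >= obs - 1e-12 for a in joint])
        res = global_average_auc_test([e1, e2], B=4000, seed=13)
        p_mc = np.sum(res.null >= obs - 1e-12) / 4000
        se = np.sqrt(p_exact * (1 - p_exact) / 4000)
        assert abs(p_mc - p_exact) <= 3 * se + 1e-9

    def test_needs_two_complexes(self):
        with pytest.raises(ValueError, match=">= 2"):
            global_average_auc_test([make_edges([2, 1], [1, 0])], B=10, seed=0)


class TestProportionalRank:
    def test_anchors(self):
        assert proportional_rank(1, 11) == 1.0
        assert proportional_rank(11, 11) == 0.0

    def test_interior_value(self):
        assert proportional_rank(3, 11) == pytest.approx(0.8)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="T=1"):
            proportional_rank(1, 1)
        with pytest.raises(ValueError, match="outside"):
            proportional_rank(5, 4)

    def test_single_physical_on_top(self):
        edges = make_edges([2.0, 1.0], [1, 0])
        res = protein_pair_prop_rank(edges, {frozenset(("pA_d0", "pB_d0"))})
        assert res.score == 1.0

    def test_two_physical_at_extremes(self):
        edges = make_edges([4.0, 3.0, 2.0, 1.0], [1, 0, 0, 1])
        phys = {frozenset(("pA_d0", "pB_d0")), frozenset(("pA_d3", "pB_d3"))}
        res = protein_pair_prop_rank(edges, phys)
        assert res.score == pytest.approx(0.5)

    def test_tie_aware_average_rank_oracle(self):
        # 6 domain pairs (3x2 domains), one physical, with an ftERC tie
        # involving the physical pair: it shares ranks 2 and 3 -> rank 2.5
        scores = [5.0, 4.0, 4.0, 2.0, 1.0, 0.5]
        labels = [0, 1, 0, 0, 0, 0]
        edges = make_edges(scores, labels)
        res = protein_pair_prop_rank(edges, {frozenset(("pA_d1", "pB_d1"))})
        assert res.physical_ranks == [2.5]
        assert res.score == pytest.approx((6 - 2.5) / 5)

    def test_no_physical_pair_not_evaluated(self):
        edges = make_edges([2.0, 1.0], [0, 0])
        assert protein_pair_prop_rank(edges, set()) is None

    def test_all_physical_not_evaluated(self):
        edges = make_edges([2.0, 1.0], [1, 1])
        phys = {frozenset(("pA_d0", "pB_d0")), frozenset(("pA_d1", "pB_d1"))}
        assert protein_pair_prop_rank(edges, phys) is None


class TestComplexPropRank:
    def pair(self, t, rank):
        ranks = [float(rank)]
        score = (t - rank) / (t - 1)
        from ratecov.rank_stats import PropRankResult

        return PropRankResult("pa", "pb", t, ranks, score)

    def test_null_expectation_half(self):
        res = complex_prop_rank_test([self.pair(11, 1)], B=1000, seed=1)
        se = res.null.std() / np.sqrt(len(res.null))
        assert abs(res.null.mean() - 0.5) < 3 * se

    def test_add_one_bound_when_observed_is_max(self):
        # T=40: a null draw hits rank 1 with p=1/40 per replicate
        res = complex_prop_rank_test([self.pair(40, 1)], B=1000, seed=2)
        n_hits = int(np.sum(res.null >= 1.0))
        assert res.p == pytest.approx((1 + n_hits) / 1001)

    def test_two_pairs_exhaustive_joint_null(self):
        # 2 pairs with T=3 each: joint null is the 3x3 grid of rank pairs
        pairs = [self.pair(3, 1), self.pair(3, 2)]
        obs = np.mean([p.score for p in pairs])
        grid = [(3 - r1) / 2 / 2 + (3 - r2) / 2 / 2
                for r1 in (1, 2, 3) for r2 in (1, 2, 3)]
        p_exact = np.mean([g >= obs - 1e-12 for g in grid])
        B = 4000
        res = complex_prop_rank_test(pairs, B=B, seed=3)
        p_mc = np.sum(res.null >= obs - 1e-12) / B
        se = np.sqrt(p_exact * (1 - p_exact) / B)
        assert abs(p_mc - p_exact) <= 3 * se + 1e-9

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no evaluated"):
            complex_prop_rank_test([], B=10, seed=0)


def test_binomial_tail_closed_form():
    # P(X >= 2), X ~ Bin(3, 0.5): (3 + 1)/8
    assert binomial_tail(2, 3, 0.5) == pytest.approx(0.5)
    assert binomial_tail(0, 5, 0.5) == 1.0
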