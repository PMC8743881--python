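"""Rank-order search, rank distances, dendrogram and tier assignment."""

import itertools

import numpy as np
import pytest

import domcert as dc
from domcert.conductance import DPMatrix
from domcert.errors import InvalidParameterError

from .conftest import block_dp, random_dp


def two_id_dp(p=0.7):
    dp = np.array([[np.nan, p], [1 - p, np.nan]])
    return DPMatrix(("A", "B"), dp)


class TestOrderScore:
    def test_two_ids(self):
        dp = two_id_dp(0.7)
        assert dc.order_score(dp, ("A", "B")) == pytest.approx(0.7)
        assert dc.order_score(dp, ("B", "A")) == pytest.approx(0.3)

    def test_matches_manual_upper_triangle_sum(self, rng):
        dp = random_dp(rng, 5)
        order = list(dp.ids)
        rng.shuffle(order)
        manual = sum(
            dp.value(order[a], order[b])
            for a in range(5)
            for b in range(a + 1, 5)
        )
        assert dc.order_score(dp, order) == pytest.approx(manual, abs=1e-12)

    def test_invalid_permutation_rejected(self):
        dp = two_id_dp()
        with pytest.raises(InvalidParameterError):
            dc.order_score(dp, ("A", "A"))

    def test_score_plus_reverse_score_is_pair_count(self, rng):
        # dp normalization makes score(order) + score(reverse) = n(n-1)/2
        dp = random_dp(rng, 6)
        order = list(dp.ids)
        total = dc.order_score(dp, order) + dc.order_score(dp, order[::-1])
        assert total == pytest.approx(6 * 5 / 2, abs=1e-9)


class TestExactSearch:
    def test_consistent_matrix_returns_identity_order(self):
        n = 5
        dp = np.full((n, n), 0.1)
        dp[np.triu_indices(n, 1)] = 0.9
        np.fill_diagonal(dp, np.nan)
        m = DPMatrix(tuple("ABCDE"), dp)
        assert dc.best_order_exact(m).order == tuple("ABCDE")

    def test_all_ties_returns_id_sorted_order(self):
        n = 4
        dp = np.full((n, n), 0.5)
        np.fill_diagonal(dp, np.nan)
        m = DPMatrix(("D", "B", "A", "C"), dp)
        assert dc.best_order_exact(m).order == ("A", "B", "C", "D")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_scan(self, seed):
        dp = random_dp(np.random.default_rng(seed), 6)
        best = dc.best_order_exact(dp)
        brute = max(
            itertools.permutations(dp.ids),
            key=lambda p: dc.order_score(dp, p),
        )
        assert best.score == pytest.approx(dc.order_score(dp, brute), abs=1e-9)

    def test_size_limit_enforced(self, rng):
        dp = random_dp(rng, 9)
        with pytest.raises(InvalidParameterError):
            dc.best_order_exact(dp, max_n=8)


class TestAnnealedSearch:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exact_optimum(self, seed):
        dp = random_dp(np.random.default_rng(seed), 7)
        exact = dc.best_order_exact(dp)
        ensemble = dc.best_order_annealed(dp, seed=seed)
        assert ensemble.best.score == pytest.approx(exact.score, abs=1e-9)

    def test_same_seed_identical_ensemble(self, rng):
        dp = random_dp(rng, 9)
        e1 = dc.best_order_annealed(dp, restarts=10, seed=3)
        e2 = dc.best_order_annealed(dp, restarts=10, seed=3)
        assert e1 == e2

    def test_best_dominates_start_and_members(self, rng):
        dp = random_dp(rng, 10)
        ensemble = dc.best_order_annealed(dp, restarts=10, seed=1)
        rowsum_order = sorted(
            dp.ids, key=lambda i: (-np.nansum(dp.dp[dp.index_of(i)]), i)
        )
        assert ensemble.best.score >= dc.order_score(dp, rowsum_order) - 1e-9
        assert all(ensemble.best.score >= o.score - 1e-9 for o in ensemble.orders)

    def test_best_beats_random_permutations(self, rng):
        dp = random_dp(rng, 9)
        best = dc.best_order_annealed(dp, restarts=10, seed=2).best
        order = list(dp.ids)
        for _ in range(1000):
            rng.shuffle(order)
            assert best.score >= dc.order_score(dp, order) - 1e-9


class TestRankDistance:
    @pytest.mark.parametrize("p, expected", [(0.5, 0.0), (1.0, 1.0), (0.7, 0.4)])
    def test_values(self, p, expected):
        dp = two_id_dp(p)
        assert dc.rank_distance(dp, "A", "B") == pytest.approx(expected, abs=1e-12)
        assert dc.rank_distance(dp, "B", "A") == pytest.approx(expected, abs=1e-12)

    def test_matrix_is_symmetric_zero_diagonal(self, rng):
        d = dc.rank_distance_matrix(random_dp(rng, 6))
        assert np.allclose(d, d.T, atol=1e-12)
        assert np.all(np.diagonal(d) == 0)


class TestRankTree:
    def test_fully_ambiguous_pair_merges_at_zero(self):
        tree = dc.build_rank_tree(two_id_dp(0.5))
        assert tree.linkage_matrix[0, 2] == 0.0
        assert len(set(tree.cut(0.01).values())) == 1

    def test_block_matrix_cut_recovers_blocks(self):
        dp = block_dp(3, within=0.5, between=0.95)
        clusters = dc.build_rank_tree(dp).cut(0.4)
        assert len(set(clusters.values())) == 2
        assert clusters["A"] == clusters["B"] == clusters["C"]
        assert clusters["D"] == clusters["E"] == clusters["F"]
        assert clusters["A"] != clusters["D"]

    def test_fully_decided_group_no_merge_below_one(self):
        n = 4
        dp = np.zeros((n, n))
        dp[np.triu_indices(n, 1)] = 1.0
        np.fill_diagonal(dp, np.nan)
        tree = dc.build_rank_tree(DPMatrix(tuple("ABCD"), dp))
        assert np.all(tree.linkage_matrix[:, 2] >= 1.0 - 1e-12)


class TestRankTiers:
    def test_decided_neighbours_yield_singletons(self):
        n = 5
        dp = np.full((n, n), 0.01)
        dp[np.triu_indices(n, 1)] = 0.99
        np.fill_diagonal(dp, np.nan)
        m = DPMatrix(tuple("ABCDE"), dp)
        tiers = dc.rank_tiers(m, dc.best_order_exact(m))
        assert sorted(tiers.tiers.values()) == [1, 2, 3, 4, 5]

    def test_all_ambiguous_single_tier(self):
        n = 4
        dp = np.full((n, n), 0.5)
        np.fill_diagonal(dp, np.nan)
        m = DPMatrix(tuple("ABCD"), dp)
        tiers = dc.rank_tiers(m, dc.best_order_exact(m))
        assert set(tiers.tiers.values()) == {1}

    def test_two_block_matrix_two_tiers(self):
        dp = block_dp(3, within=0.5, between=0.95)
        best = dc.best_order_exact(dp)
        tiers = dc.rank_tiers(dp, best, threshold=0.70)
        assert max(tiers.tiers.values()) == 2
        assert {tiers.tiers[i] for i in "ABC"} == {1}
        assert {tiers.tiers[i] for i in "DEF"} == {2}

    def test_threshold_range_enforced(self):
        dp = two_id_dp()
        with pytest.raises(InvalidParameterError):
            dc.rank_tiers(dp, dc.best_order_exact(dp), threshold=0.5)

    def test_threshold_limits(self, rng):
        # just above 0.5: every strictly decided adjacency splits;
        # at 1.0: single tier unless some dp is exactly 1
        dp = random_dp(rng, 6)
        best = dc.best_order_exact(dp)
        strict = dc.rank_tiers(dp, best, threshold=0.5 + 1e-9)
        adjacent_decided = all(
            dp.value(a, b) > 0.5 + 1e-9
            for a, b in zip(best.order[:-1], best.order[1:])
        )
        if adjacent_decided:
            assert max(strict.tiers.values()) == 6
        loose = dc.rank_tiers(dp, best, threshold=1.0)
        if not np.any(dp.dp == 1.0):
            assert max(loose.tiers.values()) == 1
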