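import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from recombnet import prioritize
from recombnet.motif_scan import GenomicInterval
from recombnet.prioritize import (
    HBProfile,
    Ranking,
    build_hb_network,
    build_hb_profile,
    footrule_distance,
    km_aggregate,
    odds_ratio,
    rank_by_or,
    relevance_from_clusters,
    select_seeds,
)


def brute_force_km(sigma_o, sigma_h):
    """Exhaustive minimum of the summed footrule objective (oracle)."""
    genes = sigma_o.order
    n = len(genes)
    best = math.inf
    for perm in itertools.permutations(range(1, n + 1)):
        cost = sum(
            abs(sigma_o.position(g) - p) + abs(sigma_h.position(g) - p)
            for g, p in zip(genes, perm)
        )
        best = min(best, cost)
    return best


class TestOddsRatio:
    def test_worked_example(self):
        r = odds_ratio("M", 30, 100, 10, 100)
        assert r.odds_ratio == pytest.approx(27 / 7)
        assert (r.hm, r.hn, r.cm, r.cn) == (30, 70, 10, 90)

    def test_symmetric_counts_give_one(self):
        assert odds_ratio("M", 25, 80, 25, 80).odds_ratio == pytest.approx(1.0)

    def test_no_coldspot_hits_is_infinite(self):
        assert odds_ratio("M", 5, 10, 0, 10).odds_ratio == math.inf

    def test_all_hotspots_hit_is_infinite(self):
        assert odds_ratio("M", 10, 10, 3, 10).odds_ratio == math.inf

    def test_no_hits_anywhere_flagged_undefined(self):
        with pytest.warns(UserWarning):
            r = odds_ratio("M", 0, 10, 0, 10)
        assert r.odds_ratio == 0.0 and r.undefined

    def test_count_overflow_is_hard_error(self):
        with pytest.raises(ValueError):
            odds_ratio("M", 11, 10, 0, 10)

    def test_haldane_correction(self):
        r = odds_ratio("M", 5, 10, 0, 10, haldane=True)
        assert r.odds_ratio == pytest.approx((5.5 / 5.5) / (0.5 / 10.5))

    def test_ranking_order_and_ties(self):
        recs = [
            odds_ratio("a", 30, 100, 10, 100),   # 27/7
            odds_ratio("b", 10, 100, 10, 100),   # 1
            odds_ratio("c", 20, 100, 10, 100),   # 9/4
            odds_ratio("d", 5, 100, 0, 100),     # inf, ranked first
            odds_ratio("e", 10, 100, 10, 100),   # tie with b -> lexicographic
        ]
        assert rank_by_or(recs).order == ["d", "a", "c", "b", "e"]


class TestHBProfiles:
    LENGTHS = {"c1": 10_000_000}

    def bound(self, *midpoints):
        return [GenomicInterval("c1", m - 50, m + 50, "hotspot") for m in midpoints]

    def test_midpoint_binning(self):
        p = build_hb_profile("M", self.bound(1_000_000, 7_000_000), self.LENGTHS, 5_000_000)
        assert p.b.tolist() == [1, 1]

    def test_empty_profile(self):
        p = build_hb_profile("M", [], self.LENGTHS, 5_000_000)
        assert p.b.tolist() == [0, 0]

    def test_all_in_first_bin(self):
        p = build_hb_profile("M", self.bound(100, 200, 300), self.LENGTHS, 5_000_000)
        assert p.b.tolist() == [3, 0]

    def test_bins_concatenate_across_chromosomes(self):
        lengths = {"c1": 6_000_000, "c2": 4_000_000}
        p = build_hb_profile("M", self.bound(5_500_000), lengths, 5_000_000)
        assert p.b.tolist() == [0, 1, 0]  # c1 gets 2 bins, c2 gets 1

    def test_network_edges(self):
        ps = [
            HBProfile("x", np.array([1, 2, 3]), 1),
            HBProfile("y", np.array([2, 4, 6]), 1),
            HBProfile("z", np.array([3, 2, 1]), 1),
            HBProfile("w", np.array([2, 2, 2]), 1),
        ]
        g = build_hb_network(ps, threshold=0.7)
        assert g.has_edge("x", "y")          # r = 1
        assert not g.has_edge("x", "z")      # r = -1
        assert g.degree("w") == 0            # zero variance -> no edges

    def test_network_scale_invariance(self, rng):
        base = [HBProfile(f"m{i}", rng.integers(0, 9, 8), 1) for i in range(5)]
        scaled = [HBProfile(p.motif_id, p.b * 7, 1) for p in base]
        g1, g2 = build_hb_network(base), build_hb_network(scaled)
        assert set(g1.edges()) == set(g2.edges())


class TestRelevance:
    def test_frequency_normalization(self):
        r = relevance_from_clusters(
            [frozenset({"g1", "g2"}), frozenset({"g1", "g3"})], ["g1", "g2", "g3", "g4"]
        )
        assert r["g1"] == 1.0 and r["g2"] == 0.5 and r["g3"] == 0.5
        assert r["g4"] == 0.0

    def test_single_cluster_all_max(self):
        r = relevance_from_clusters([frozenset({"g1", "g2"})], ["g1", "g2"])
        assert r["g1"] == r["g2"] == 1.0

    def test_no_clusters_hard_error(self):
        with pytest.raises(ValueError):
            relevance_from_clusters([], ["g1"])


class TestFootruleAndKM:
    def test_identity_distance_zero(self):
        a = Ranking(["a", "b", "c"])
        assert footrule_distance(a, a) == 0

    def test_reversal(self):
        assert footrule_distance(Ranking(["a", "b", "c"]), Ranking(["c", "b", "a"])) == 4

    def test_swap(self):
        assert footrule_distance(Ranking(["a", "b"]), Ranking(["b", "a"])) == 2

    def test_universe_mismatch(self):
        with pytest.raises(ValueError):
            footrule_distance(Ranking(["a"]), Ranking(["b"]))

    @given(st.permutations(list("abcdef")), st.permutations(list("abcdef")),
           st.permutations(list("abcdef")))
    @settings(max_examples=50, deadline=None)
    def test_footrule_symmetry_and_triangle(self, p1, p2, p3):
        a, b, c = Ranking(list(p1)), Ranking(list(p2)), Ranking(list(p3))
        assert footrule_distance(a, b) == footrule_distance(b, a)
        assert footrule_distance(a, c) <= footrule_distance(a, b) + footrule_distance(b, c)

    def test_km_identity_optimum(self):
        a = Ranking(["a", "b", "c"])
        agg, cost = km_aggregate(a, a)
        assert cost == 0 and agg.order == a.order

    def test_km_worked_example(self):
        so = Ranking(["a", "b", "c"])
        sh = Ranking(["b", "a", "c"])
        _, cost = km_aggregate(so, sh)
        assert cost == 2  # multiple optima; only the cost is unique

    def test_km_singleton(self):
        agg, cost = km_aggregate(Ranking(["a"]), Ranking(["a"]))
        assert agg.order == ["a"] and cost == 0

    def test_km_matches_brute_force(self, rng):
        genes = list("abcdef")
        for n in range(2, 7):
            for _ in range(10):
                so = Ranking(list(rng.permutation(genes[:n])))
                sh = Ranking(list(rng.permutation(genes[:n])))
                _, cost = km_aggregate(so, sh)
                assert cost == brute_force_km(so, sh)

    def test_km_aggregation_is_deterministic(self, rng):
        so = Ranking(list(rng.permutation(list("abcdefgh"))))
        sh = Ranking(list(rng.permutation(list("abcdefgh"))))
        r1, c1 = km_aggregate(so, sh)
        r2, c2 = km_aggregate(so, sh)
        assert r1.order == r2.order and c1 == c2


class TestSeedSelection:
    @pytest.mark.parametrize("n,expected", [(177, 18), (158, 16), (148, 15)])
    def test_top_decile_counts(self, n, expected):
        ranking = Ranking([f"g{i:04d}" for i in range(n)])
        seeds = select_seeds(ranking, {g: 1.0 for g in ranking}, 0.10)
        assert len(seeds) == expected

    def test_seeds_are_top_ranked(self):
        ranking = Ranking(["a", "b", "c", "d", "e"])
        seeds = select_seeds(ranking, {g: 1.0 for g in ranking}, 0.4)
        assert seeds.genes == {"a", "b"}

    def test_infinite_scores_clamped(self):
        ranking = Ranking(["a", "b", "c"])
        seeds = select_seeds(ranking, {"a": math.inf, "b": 2.0, "c": 1.0}, 1.0)
        assert seeds.scores["a"] == 4.0  # 2 x largest finite

    def test_uniform_mode(self):
        ranking = Ranking(["a", "b"])
        seeds = select_seeds(ranking, None, 1.0, mode="uniform")
        assert set(seeds.scores.values()) == {1.0}

    def test_rank_score_fallback(self):
        ranking = Ranking(["a", "b"])
        seeds = select_seeds(ranking, None, 1.0)
        assert seeds.scores == {"a": 1.0, "b": 0.5}

    def test_empty_fraction_rejected(self):
        with pytest.raises(ValueError):
            select_seeds(Ranking(["a"]), {"a": 1.0}, 0.0)


class TestNaiveConservedClusters:
    def test_orthologous_edges_survive(self):
        a = nx.Graph([("x", "y"), ("y", "z"), ("p", "q")])
        b = nx.Graph([("X", "Y"), ("Y", "Z")])
        orth = {("x", "X"), ("y", "Y"), ("z", "Z"), ("p", "P")}
        clusters = prioritize.naive_conserved_clusters(a, b, orth)
        assert clusters == [frozenset({"x", "y", "z"})]
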