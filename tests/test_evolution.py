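"""Shortest paths and the stochastic evolutionary distance models."""

import numpy as np
import pytest

from evogeo import (EvoModelParams, MSTContext, all_pairs_shortest_path,
                    edge_probability, evolutionary_distance_matrix,
                    minimum_spanning_tree, sample_evolved_network)
from evogeo.evolution import probability_matrix
from evogeo.network import PPINetwork, subnetwork

from conftest import random_connected_network


def floyd_warshall(net: PPINetwork) -> np.ndarray:
    """Brute-force all-pairs shortest paths (triple loop oracle)."""
    n = net.n
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i, j in net.edges:
        d[i, j] = d[j, i] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def path_network(n: int) -> PPINetwork:
    ids = [f"n{i}" for i in range(n)]
    return PPINetwork.from_id_pairs([(ids[i], ids[i + 1])
                                     for i in range(n - 1)])


class TestShortestPath:
    def test_matches_floyd_warshall_on_random_graphs(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            net = random_connected_network(int(rng.integers(4, 13)), 0.35, rng)
            sp = all_pairs_shortest_path(net)
            assert np.array_equal(sp, floyd_warshall(net))

    def test_basic_identities(self):
        sp = all_pairs_shortest_path(path_network(3))
        assert sp[0, 0] == 0 and sp[0, 2] == 2

    def test_disconnected_raises(self):
        net = PPINetwork.from_id_pairs([("A", "B"), ("C", "D")])
        with pytest.raises(ValueError, match="disconnected"):
            all_pairs_shortest_path(net)


@pytest.fixture(scope="module")
def star_plus_path():
    # Hub H with leaves L1..L4, path H-a-b-c-d: varied degrees, Δ=5.
    pairs = [("H", f"L{i}") for i in range(1, 5)]
    pairs += [("H", "a"), ("a", "b"), ("b", "c"), ("c", "d")]
    net = PPINetwork.from_id_pairs(pairs)
    return net, MSTContext.from_mst(net)


class TestEdgeProbability:
    """Branch values of the three model definitions."""

    def test_toy_fixture_hand_computed_values(self, toy):
        comp_ids = toy["component_ids"]
        mst_net = PPINetwork(comp_ids, toy["mst"])
        ctx = MSTContext.from_mst(mst_net)
        assert ctx.max_deg == toy["max_deg"]
        assert np.array_equal(ctx.deg, toy["deg"])
        for model, table in toy["probabilities"].items():
            params = EvoModelParams(model=model)
            for (i, j), expected in table.items():
                assert edge_probability(i, j, ctx, params) == \
                    pytest.approx(expected)

    @pytest.mark.parametrize("model", ["daneosf", "lpa", "rm"])
    def test_adjacent_pairs_are_certain(self, star_plus_path, model):
        net, ctx = star_plus_path
        params = EvoModelParams(model=model)
        for i, j in net.edges:
            assert edge_probability(i, j, ctx, params) == 1.0

    def test_daneosf_neofunctionalization_band(self):
        # Chain with controlled degrees: deg(i)=2, deg(j)=3, Δ=4, SP=4
        # gives (2*3/16)^4, checked by independent arithmetic.
        ctx = MSTContext(sp=np.full((2, 2), 4.0) - 4 * np.eye(2),
                         deg=np.array([2, 3]), max_deg=4)
        p = edge_probability(0, 1, ctx, EvoModelParams(model="daneosf"))
        assert p == pytest.approx((6 / 16) ** 4)

    def test_daneosf_duplication_band_is_alpha(self, star_plus_path):
        net, ctx = star_plus_path
        params = EvoModelParams(model="daneosf", alpha=0.3)
        i, j = np.argwhere(ctx.sp == 2)[0]
        assert edge_probability(int(i), int(j), ctx, params) == 0.3
        i, j = np.argwhere(ctx.sp == 3)[0]
        assert edge_probability(int(i), int(j), ctx, params) == 0.3

    def test_lpa_max_degree_pair_is_half(self):
        ctx = MSTContext(sp=np.array([[0.0, 2.0], [2.0, 0.0]]),
                         deg=np.array([4, 4]), max_deg=4)
        assert edge_probability(0, 1, ctx, EvoModelParams(model="lpa")) == 0.5

    def test_rm_is_beta_everywhere_beyond_one(self, star_plus_path):
        net, ctx = star_plus_path
        params = EvoModelParams(model="rm", beta=0.15)
        for (i, j) in np.argwhere(ctx.sp > 1):
            assert edge_probability(int(i), int(j), ctx, params) == 0.15

    @pytest.mark.parametrize("model", ["daneosf", "lpa", "rm"])
    def test_probabilities_lie_in_unit_interval(self, model):
        rng = np.random.default_rng(2)
        for _ in range(5):
            net = random_connected_network(20, 0.15, rng)
            mst = minimum_spanning_tree(net, int(rng.integers(100)))
            ctx = MSTContext.from_mst(subnetwork(net, mst))
            p = probability_matrix(ctx, EvoModelParams(model=model))
            assert (p >= 0).all() and (p <= 1).all()

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            EvoModelParams(model="bogus")


class TestSampling:
    def test_rm_beta_zero_keeps_only_mst(self):
        net = path_network(8)
        ctx = MSTContext.from_mst(net)
        ev = sample_evolved_network(
            net, ctx, EvoModelParams(model="rm", beta=0.0, seed=1))
        assert ev.edges == net.edges

    def test_rm_beta_one_completes_graph(self):
        net = path_network(8)
        ctx = MSTContext.from_mst(net)
        ev = sample_evolved_network(
            net, ctx, EvoModelParams(model="rm", beta=1.0, seed=1))
        assert ev.m_edges == 8 * 7 // 2

    def test_acceptance_rate_tracks_alpha(self):
        # Aggregate Bernoulli draws over SP=2 pairs: within 3 binomial SE.
        net = path_network(40)
        ctx = MSTContext.from_mst(net)
        params_base = EvoModelParams(model="daneosf", alpha=0.3)
        sp2 = [(i, j) for i, j in zip(*np.triu_indices(40, 1))
               if ctx.sp[i, j] == 2]
        hits = draws = 0
        for seed in range(300):
            params = EvoModelParams(model="daneosf", alpha=0.3, seed=seed)
            ev = sample_evolved_network(net, ctx, params)
            for e in sp2:
                draws += 1
                hits += e in ev.edges
        assert draws >= 10_000
        se = np.sqrt(0.3 * 0.7 / draws)
        assert abs(hits / draws - 0.3) <= 3 * se

    def test_fixed_seed_is_bit_reproducible(self, geo_small):
        comp, _ = geo_small
        mst = minimum_spanning_tree(comp, 4)
        net = subnetwork(comp, mst)
        ctx = MSTContext.from_mst(net)
        params = EvoModelParams(model="daneosf", seed=99)
        a = sample_evolved_network(net, ctx, params)
        b = sample_evolved_network(net, ctx, params)
        assert a.edges == b.edges


class TestDistanceMatrix:
    def test_literal_rm_beta_zero_equals_sp(self):
        net = path_network(10)
        ctx = MSTContext.from_mst(net)
        params = EvoModelParams(model="rm", beta=0.0, mode="literal", seed=0)
        d, ev = evolutionary_distance_matrix(net, ctx, params)
        assert np.array_equal(d, ctx.sp)
        assert ev.edges == net.edges

    def test_evolved_graph_never_lengthens_paths(self, geo_small):
        comp, _ = geo_small
        mst = minimum_spanning_tree(comp, 2)
        net = subnetwork(comp, mst)
        ctx = MSTContext.from_mst(net)
        for model in ("daneosf", "lpa", "rm"):
            d, _ = evolutionary_distance_matrix(
                net, ctx, EvoModelParams(model=model, seed=5))
            assert (d <= ctx.sp + 1e-12).all()

    def test_evolved_graph_matches_materialized_oracle(self):
        # Distance matrix must equal Floyd-Warshall on the sampled edges.
        rng = np.random.default_rng(8)
        base = random_connected_network(10, 0.3, rng)
        mst = minimum_spanning_tree(base, 3)
        net = subnetwork(base, mst)
        ctx = MSTContext.from_mst(net)
        params = EvoModelParams(model="daneosf", seed=21)
        d, ev = evolutionary_distance_matrix(net, ctx, params)
        assert np.array_equal(d, floyd_warshall(ev))

    def test_literal_mode_sets_sampled_pairs_to_one(self):
        net = path_network(12)
        ctx = MSTContext.from_mst(net)
        params = EvoModelParams(model="rm", beta=0.5, mode="literal", seed=3)
        d, ev = evolutionary_distance_matrix(net, ctx, params)
        for i, j in zip(*np.triu_indices(12, 1)):
            expected = 1.0 if (i, j) in ev.edges else ctx.sp[i, j]
            assert d[i, j] == expected == d[j, i]
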