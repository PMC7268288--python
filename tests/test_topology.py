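import math
import random

import networkx as nx
import numpy as np
import pytest

import regnet as rn
from conftest import brute_force_betweenness


class TestDegree:
    def test_star_center_and_leaves(self, star5):
        deg = rn.degree_centrality(star5)
        assert deg["c"] == 4
        assert all(deg[f"l{i}"] == 1 for i in range(4))

    def test_triangle_all_two(self, triangle):
        assert set(rn.degree_centrality(triangle).values()) == {2}

    def test_handshake_identity_on_synthetic(self):
        ppi, _ = rn.gen_ppi_planted(200, 0.03, [], seed=8)
        deg = rn.degree_centrality(ppi)
        assert sum(deg.values()) == 2 * ppi.n_edges

    def test_directed_in_out_sum_to_edge_count(self, minimal_regnet):
        assert sum(rn.degree_centrality(minimal_regnet, "in").values()) == 2
        assert sum(rn.degree_centrality(minimal_regnet, "out").values()) == 2

    def test_empty_network_is_error(self):
        with pytest.raises(ValueError):
            rn.degree_centrality(rn.PPINetwork())


class TestBetweenness:
    def test_path_p3(self):
        p3 = rn.PPINetwork.from_pairs([("a", "b"), ("b", "c")])
        b = rn.betweenness(p3)
        assert b == {"a": 0.0, "b": 1.0, "c": 0.0}

    def test_star_center_is_leaf_pairs(self, star5):
        assert rn.betweenness(star5)["c"] == math.comb(4, 2)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_on_small_graphs(self, seed):
        rng = random.Random(seed)
        n = rng.randint(2, 8)
        g = nx.gnp_random_graph(n, rng.uniform(0.2, 0.9), seed=seed)
        net = rn.PPINetwork(graph=nx.relabel_nodes(g, str))
        net.graph.add_nodes_from(str(i) for i in range(n))
        got = rn.betweenness(net)
        want = brute_force_betweenness(net.graph)
        for v in want:
            assert got[v] == pytest.approx(want[v], abs=1e-9)


class TestHubBottleneck:
    def test_star_center_is_hub_bottleneck(self, star5):
        rep = rn.hub_bottleneck(star5, quantile=0.2)
        assert rep.hub_bottleneck_set == {"c"}

    def test_disjoint_rankings_give_empty_intersection(self):
        # two K4 cliques joined by a path: path interior nodes carry the
        # betweenness, clique members the degree
        pairs = []
        for base in ("a", "b"):
            for i in range(4):
                for j in range(i + 1, 4):
                    pairs.append((f"{base}{i}", f"{base}{j}"))
        pairs += [("a0", "x1"), ("x1", "x2"), ("x2", "x3"), ("x3", "b0")]
        net = rn.PPINetwork.from_pairs(pairs)
        rep = rn.hub_bottleneck(net, quantile=0.18)
        # hubs are the junction clique nodes by degree; the top betweenness
        # nodes are the path interior
        assert {"x1", "x2", "x3"} & rep.bottleneck_set
        deg_rank = sorted(rep.degree, key=rep.degree.get, reverse=True)
        btw_rank = sorted(rep.betweenness, key=rep.betweenness.get, reverse=True)
        assert deg_rank[0] != btw_rank[0]
        assert rep.hub_bottleneck_set == set()

    def test_planted_bridge_hub_is_recovered(self):
        # dense node bridging two communities: top degree and top betweenness
        pairs = [("hub", f"a{i}") for i in range(8)] + [("hub", f"b{i}") for i in range(8)]
        pairs += [(f"a{i}", f"a{j}") for i in range(8) for j in range(i + 1, 8) if (i + j) % 2]
        pairs += [(f"b{i}", f"b{j}") for i in range(8) for j in range(i + 1, 8) if (i + j) % 2]
        net = rn.PPINetwork.from_pairs(pairs)
        rep = rn.hub_bottleneck(net, quantile=0.1)
        assert "hub" in rep.hub_bottleneck_set

    def test_quantile_bounds_checked(self, star5):
        for q in (0.0, 1.0, -0.2, 2.0):
            with pytest.raises(ValueError):
                rn.hub_bottleneck(star5, quantile=q)

    def test_hub_set_monotone_in_quantile(self):
        ppi, _ = rn.gen_ppi_planted(60, 0.08, [6], 1.0, seed=4)
        reports = [rn.hub_bottleneck(ppi, q) for q in (0.05, 0.1, 0.2, 0.4)]
        for small, big in zip(reports, reports[1:]):
            assert small.hub_set <= big.hub_set
            assert small.bottleneck_set <= big.bottleneck_set

    def test_hub_set_size_at_least_quantile_fraction(self):
        ppi, _ = rn.gen_ppi_planted(50, 0.1, [], seed=6)
        rep = rn.hub_bottleneck(ppi, 0.2)
        assert len(rep.hub_set) >= math.ceil(0.2 * ppi.n_nodes)
        assert rep.hub_bottleneck_set == rep.hub_set & rep.bottleneck_set


class TestHubMirnas:
    def test_highest_degree_mirna_ranks_first(self):
        nodes = [rn.RegulatoryNode(f"T{i}", "TF") for i in range(9)] + [
            rn.RegulatoryNode("big", "miRNA"),
            rn.RegulatoryNode("small", "miRNA"),
        ]
        edges = [rn.RegulatoryEdge(f"T{i}", "big", "tf_mirna") for i in range(9)]
        edges += [rn.RegulatoryEdge(f"T{i}", "small", "tf_mirna") for i in range(3)]
        net = rn.assemble_network(nodes, edges)
        assert rn.rank_hub_mirnas(net, [], k=2) == ["big", "small"]

    def test_fixture_mir21_tops_ranking(self, loop_fixture):
        net, _ = loop_fixture
        top = rn.rank_hub_mirnas(net, [], k=10)
        assert top[0] == "hsa-miR-21-5p"
        assert "hsa-miR-155-5p" in top[:4]
        assert "hsa-miR-17-5p" in top[:2]

    def test_module_membership_breaks_degree_ties(self):
        nodes = [rn.RegulatoryNode(t, "TF") for t in ("T1", "T2")] + [
            rn.RegulatoryNode(m, "miRNA") for m in ("mA", "mB")
        ]
        edges = [
            rn.RegulatoryEdge("T1", "mA", "tf_mirna"),
            rn.RegulatoryEdge("T2", "mB", "tf_mirna"),
        ]
        net = rn.assemble_network(nodes, edges)
        # same degree; mB shares a module with its regulator, mA does not
        assert rn.rank_hub_mirnas(net, [{"T2", "mB"}], k=2) == ["mB", "mA"]

    def test_ranking_matches_independent_degree_sort(self):
        net, truth = rn.gen_regulatory_network(rn.SynthNetworkSpec(seed=13))
        deg = {}
        for s, t, _ in truth.extras["edge_list"]:
            deg[s] = deg.get(s, 0) + 1
            deg[t] = deg.get(t, 0) + 1
        mirnas = net.nodes_of_class("miRNA")
        want = sorted(mirnas, key=lambda m: (-deg.get(m, 0), m))
        assert rn.rank_hub_mirnas(net, [], k=len(mirnas)) == want

    def test_no_mirnas_returns_empty(self):
        net = rn.assemble_network(
            [rn.RegulatoryNode("A", "TF"), rn.RegulatoryNode("B", "target_gene")],
            [rn.RegulatoryEdge("A", "B", "tf_gene")],
        )
        assert rn.rank_hub_mirnas(net, [], k=3) == []


class TestPowerLaw:
    def test_exact_power_law_recovered(self):
        degrees = {}
        idx = 0
        for d, f in [(1, 1600), (2, 400), (4, 100), (8, 25)]:  # freq = 1600 d^-2
            for _ in range(f):
                degrees[f"n{idx}"] = d
                idx += 1
        fit = rn.fit_power_law(degrees)
        assert fit.slope == pytest.approx(-2.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.n_points == 4

    def test_uniform_histogram_slope_zero(self):
        degrees = {f"n{i}": d for i, d in enumerate([1] * 5 + [2] * 5 + [4] * 5)}
        assert rn.fit_power_law(degrees).slope == pytest.approx(0.0, abs=1e-12)

    def test_sampled_power_law_exponent_recovered(self):
        # support truncated so every histogram bin stays populated at n=2000;
        # raw log-log OLS is badly biased by frequency-1 tail bins otherwise
        rng = np.random.default_rng(17)
        ds = np.arange(1, 21)
        probs = ds ** -2.2
        probs /= probs.sum()
        sample = rng.choice(ds, size=2000, p=probs)
        fit = rn.fit_power_law({f"n{i}": int(d) for i, d in enumerate(sample)})
        assert fit.slope == pytest.approx(-2.2, abs=0.3)

    def test_single_degree_value_is_error(self):
        with pytest.raises(ValueError):
            rn.fit_power_law({"a": 3, "b": 3})

    def test_mle_variant_returns_negative_exponent(self):
        rng = np.random.default_rng(1)
        ds = np.arange(1, 100)
        probs = ds ** -2.5
        probs /= probs.sum()
        sample = rng.choice(ds, size=1000, p=probs)
        fit = rn.fit_power_law({f"n{i}": int(d) for i, d in enumerate(sample)}, method="mle")
        assert -3.2 < fit.slope < -1.8
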