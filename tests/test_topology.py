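import networkx as nx
import numpy as np
import pytest

from ceconet import (
    CoNetwork,
    degree_and_clustering,
    detect_modules,
    generate_benchmark_graph,
    modularity,
    null_ensemble_summary,
    partition_ari,
    path_metrics,
    positive_edge_fraction,
    randomize,
)


def two_k4():
    net, part, _ = generate_benchmark_graph("two-cliques", {"clique_size": 4})
    return net, part


class TestDegreeAndClustering:
    def test_triangle_fully_clustered(self):
        degree, clustering, acc = degree_and_clustering(nx.complete_graph(3))
        assert acc == 1.0
        assert (clustering == 1.0).all()

    def test_path_has_zero_clustering(self):
        _, _, acc = degree_and_clustering(nx.path_graph(3))
        assert acc == 0.0

    def test_k4_minus_one_edge(self):
        # by hand: triangles (0,2,3) and (1,2,3); degree-2 nodes sit in 1 of
        # their 1 possible triangle (c=1), degree-3 nodes in 2 of 3 (c=2/3)
        g = nx.complete_graph(4)
        g.remove_edge(0, 1)
        degree, clustering, acc = degree_and_clustering(g)
        assert sorted(degree) == [2, 2, 3, 3]
        assert acc == pytest.approx((1 + 1 + 2 / 3 + 2 / 3) / 4)


class TestPathMetrics:
    def test_path_graph(self):
        pm = path_metrics(nx.path_graph(3))
        assert pm.apl == pytest.approx(4 / 3)
        assert pm.diameter == 2

    def test_unreachable_pairs_excluded(self):
        g = nx.Graph([(0, 1), (2, 3)])
        pm = path_metrics(g)
        assert pm.apl == 1.0
        assert pm.diameter == 1
        assert pm.component_sizes == [2, 2]

    def test_cycle_c5_brute_force(self):
        g = nx.cycle_graph(5)
        pm = path_metrics(g)
        # oracle: all-pairs BFS by hand -> distances {1,1,2,2} per node
        assert pm.apl == pytest.approx(1.5)
        assert pm.diameter == 2

    def test_edgeless_graph_flagged_undefined(self):
        g = nx.empty_graph(4)
        pm = path_metrics(g)
        assert pm.apl is None and pm.diameter is None


class TestModularity:
    def test_two_disjoint_k4_analytic(self):
        net, part = two_k4()
        assert modularity(net, part) == pytest.approx(0.5, abs=1e-12)
        assert part.q == pytest.approx(0.5, abs=1e-12)

    def test_single_module_is_zero(self, rng):
        g = nx.gnm_random_graph(20, 50, seed=3)
        assert modularity(g, {n: 0 for n in g.nodes}) == pytest.approx(0.0, abs=1e-12)

    def test_matches_networkx_on_detected_partition(self):
        g = nx.gnm_random_graph(30, 60, seed=7)
        part = detect_modules(g, seed=1)
        communities = {}
        for node, mod in part.assignment.items():
            communities.setdefault(mod, set()).add(node)
        expected = nx.community.modularity(g, communities.values(), weight=None)
        assert part.q == pytest.approx(expected, abs=1e-12)

    def test_missing_node_is_an_error(self):
        g = nx.path_graph(3)
        with pytest.raises(ValueError):
            modularity(g, {0: 0, 1: 0})


class TestDetectModules:
    def test_disjoint_cliques_recovered(self):
        net, truth = two_k4()
        part = detect_modules(net, seed=0)
        assert part.n_modules == 2
        assert partition_ari(part, truth) == 1.0
        assert part.q >= 0.0  # at least the trivial all-in-one partition

    def test_planted_partition_recovered(self):
        net, truth, _ = generate_benchmark_graph(
            "planted-partition",
            {"n_groups": 4, "group_size": 20, "p_in": 0.9, "p_out": 0.01},
            seed=2,
        )
        part = detect_modules(net, seed=1)
        assert partition_ari(part, truth) > 0.9

    def test_singletons_count_as_modules(self):
        g = nx.Graph([(0, 1)])
        g.add_node(2)
        part = detect_modules(g, seed=0)
        assert part.n_modules == 2

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError):
            detect_modules(nx.Graph(), seed=0)

    def test_seeded_determinism(self):
        g = nx.gnm_random_graph(40, 90, seed=5)
        a = detect_modules(g, seed=11)
        b = detect_modules(g, seed=11)
        assert a.assignment == b.assignment


class TestRandomize:
    def test_rewire_preserves_degree_sequence(self, rng):
        for s in range(20):
            g = nx.gnp_random_graph(25, 0.2, seed=s)
            rep = randomize(CoNetwork(g), model="rewire", seed=s)
            assert sorted(d for _, d in rep.graph.degree()) == sorted(
                d for _, d in g.degree()
            )
            assert nx.number_of_selfloops(rep.graph) == 0

    def test_gnm_preserves_counts(self):
        g = nx.gnm_random_graph(100, 200, seed=1)
        rep = randomize(CoNetwork(g), model="gnm", seed=2)
        assert rep.graph.number_of_nodes() == 100
        assert rep.graph.number_of_edges() == 200
        assert set(rep.graph.nodes) == set(g.nodes)

    def test_rewired_cliques_lose_modularity(self):
        net, _ = two_k4()
        below = sum(
            detect_modules(randomize(net, "rewire", n_swaps_factor=100, seed=s),
                           seed=s).q < 0.5
            for s in range(100)
        )
        assert below >= 95

    def test_no_legal_swap_returns_input(self):
        g = nx.Graph([(0, 1)])
        rep = randomize(CoNetwork(g), model="rewire", seed=0)
        assert set(rep.graph.edges) == {(0, 1)}


class TestNullEnsemble:
    def test_self_consistent_null_replicate(self):
        g = nx.gnm_random_graph(40, 120, seed=8)
        summary = null_ensemble_summary(CoNetwork(g), model="gnm",
                                        n_replicates=50, seed=1)
        assert all(abs(z) < 3 for z in summary.z.values())

    def test_modular_graph_stands_out_from_rewired_nulls(self):
        net, _, _ = generate_benchmark_graph(
            "ring-of-cliques", {"n_cliques": 5, "clique_size": 6})
        summary = null_ensemble_summary(net, model="rewire", n_replicates=30, seed=2)
        assert summary.z["q"] > 3
        assert summary.modular_smallworld

    def test_null_mean_stability_across_replicate_counts(self):
        g = nx.gnm_random_graph(30, 80, seed=4)
        small = null_ensemble_summary(CoNetwork(g), "gnm", n_replicates=10, seed=5)
        large = null_ensemble_summary(CoNetwork(g), "gnm", n_replicates=100, seed=6)
        for k in ("acc", "q"):
            tol = 3 * large.null_sd[k] / np.sqrt(10)
            assert abs(small.null_mean[k] - large.null_mean[k]) <= tol

    def test_minimum_replicates_enforced(self):
        with pytest.raises(ValueError):
            null_ensemble_summary(CoNetwork(nx.path_graph(4)), n_replicates=5)


class TestPositiveEdgeFraction:
    def test_counting(self):
        g = nx.Graph()
        for i in range(3):
            g.add_edge(f"p{i}", f"q{i}", sign="+")
        g.add_edge("x", "y", sign="-")
        assert positive_edge_fraction(g) == 0.75

    def test_empty_is_nan(self):
        assert np.isnan(positive_edge_fraction(nx.Graph()))


class TestInvariants:
    def test_diameter_at_least_apl(self, rng):
        for s in range(10):
            g = nx.gnp_random_graph(20, 0.15, seed=s)
            pm = path_metrics(g)
            if pm.apl is not None:
                assert pm.diameter >= pm.apl

    def test_gnm_acc_matches_edge_density(self):
        """Expected clustering of G(n,m) is the edge density 2m/(n(n-1))."""
        accs = [
            degree_and_clustering(nx.gnm_random_graph(60, 300, seed=s))[2]
            for s in range(200)
        ]
        accs = np.asarray(accs)
        expected = 2 * 300 / (60 * 59)
        se = accs.std(ddof=1) / np.sqrt(len(accs))
        assert abs(accs.mean() - expected) <= 3 * se
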