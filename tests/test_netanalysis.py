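import itertools

import networkx as nx
import numpy as np
import pytest

from cacmir.errors import ParameterError
from cacmir.netanalysis import (
    CleaningAudit,
    InteractionData,
    Network,
    betweenness,
    bottleneck_scores,
    bridging,
    build_network,
    centrality_report,
    degree,
    eigenvector_centrality,
    er_degree_sample,
    radiality,
    randomize_and_test,
    rank_hubs,
    stress,
)
from cacmir.synthetic_data import gen_interactions


def net_from_edges(edges):
    g = nx.Graph()
    g.add_edges_from(edges)
    return Network(graph=g, audit=CleaningAudit(0, 0, 0))


PATH3 = [("A", "B"), ("B", "C")]
STAR4 = [("c", f"l{i}") for i in range(1, 5)]


class TestBuildNetwork:
    def test_complex_becomes_a_clique(self):
        net = build_network(InteractionData(binary_pairs=[], complexes=[{"A", "B", "C"}]))
        assert set(map(frozenset, net.graph.edges)) == {
            frozenset(p) for p in itertools.combinations("ABC", 2)
        }

    def test_cleaning_audit_counts(self):
        data = InteractionData(
            binary_pairs=[("A", "B"), ("A", "B"), ("B", "B")],
            complexes=[],
            nodes=["A", "B", "C"],
        )
        net = build_network(data)
        assert sorted(net.graph.nodes) == ["A", "B"]
        assert net.audit == CleaningAudit(1, 1, 1)

    def test_complex_size_k_adds_k_choose_2(self):
        net = build_network(InteractionData(binary_pairs=[], complexes=[set("WXYZ")]))
        assert net.graph.number_of_edges() == 6

    def test_audit_conserves_raw_candidate_count(self, rng):
        pairs = [tuple(rng.choice(list("ABCDEFG"), size=2)) for _ in range(40)]
        complexes = [set(rng.choice(list("ABCDEFG"), size=3, replace=False)) for _ in range(4)]
        raw = len(pairs) + sum(len(c) * (len(c) - 1) // 2 for c in complexes)
        net = build_network(InteractionData(pairs, complexes))
        assert (
            net.graph.number_of_edges()
            + net.audit.removed_multi_edges
            + net.audit.removed_self_loops
            == raw
        )


class TestSmallGraphValues:
    def test_path_betweenness_counts_ordered_pairs(self):
        bc = betweenness(net_from_edges(PATH3))
        assert bc["B"] == 2.0 and bc["A"] == 0.0 and bc["C"] == 0.0

    def test_path_stress(self):
        st = stress(net_from_edges(PATH3))
        assert st["B"] == 2.0 and st["A"] == 0.0

    def test_star_center_stress(self):
        st = stress(net_from_edges([("c", "a"), ("c", "b"), ("c", "d")]))
        assert st["c"] == 6.0

    def test_path_radiality(self):
        rad = radiality(net_from_edges(PATH3))
        assert rad["B"] == pytest.approx(2.0)
        assert rad["A"] == pytest.approx(1.5)

    def test_complete_graph_radiality_is_one(self):
        rad = radiality(net_from_edges(list(itertools.combinations("ABCDE", 2))))
        assert all(v == pytest.approx(1.0) for v in rad.values())

    def test_triangle_eigenvector_is_uniform(self):
        ev = eigenvector_centrality(net_from_edges([("A", "B"), ("B", "C"), ("A", "C")]))
        assert all(v == pytest.approx(1 / np.sqrt(3)) for v in ev.values())

    def test_star_eigenvector_ratio_is_sqrt3(self):
        ev = eigenvector_centrality(net_from_edges([("c", "a"), ("c", "b"), ("c", "d")]))
        assert ev["c"] / ev["a"] == pytest.approx(np.sqrt(3), abs=1e-6)

    def test_path_bridging(self):
        bcoeff, brg = bridging(net_from_edges(PATH3))
        assert bcoeff["B"] == pytest.approx(0.25)
        assert brg["B"] == pytest.approx(0.5)
        assert brg["A"] == 0.0  # leaves never bridge

    def test_star_bottleneck_center_scores_per_leaf_root(self):
        scores = bottleneck_scores(net_from_edges(STAR4))
        assert scores["c"] == 4
        assert all(scores[f"l{i}"] == 0 for i in range(1, 5))

    def test_k2_bottleneck_scores_one_each(self):
        scores = bottleneck_scores(net_from_edges([("A", "B")]))
        assert scores == {"A": 1, "B": 1}

    def test_degree_lookup(self):
        net = net_from_edges(PATH3)
        assert degree(net, "B") == 2
        with pytest.raises(KeyError):
            degree(net, "Z")


class TestCentralityOracles:
    """Brute-force cross-checks on seeded random graphs."""

    def _random_net(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 26))
        g = nx.gnp_random_graph(n, 0.3, seed=int(rng.integers(2**31)))
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
        return Network(graph=g, audit=CleaningAudit(0, 0, 0))

    @pytest.mark.parametrize("seed", range(20))
    def test_betweenness_matches_networkx(self, seed):
        net = self._random_net(seed)
        ours = betweenness(net)
        ref = nx.betweenness_centrality(net.graph, normalized=False)
        for v in net.graph:
            assert ours[v] == pytest.approx(2 * ref[v])  # ordered-pair convention

    @pytest.mark.parametrize("seed", range(10))
    def test_stress_matches_path_enumeration(self, seed):
        net = self._random_net(seed)
        g = net.graph
        expected = {v: 0 for v in g}
        for s in g:
            for t in g:
                if s == t or not nx.has_path(g, s, t):
                    continue
                for path in nx.all_shortest_paths(g, s, t):
                    for v in path[1:-1]:
                        expected[v] += 1
        assert stress(net) == expected

    @pytest.mark.parametrize("seed", range(10))
    def test_eigenvector_matches_dense_solver(self, seed):
        net = self._random_net(seed)
        ours = eigenvector_centrality(net)
        for comp in nx.connected_components(net.graph):
            comp = sorted(comp)
            if len(comp) == 1:
                continue
            A = nx.to_numpy_array(net.graph.subgraph(comp), nodelist=comp)
            w, V = np.linalg.eigh(A)
            principal = np.abs(V[:, np.argmax(w)])
            for v, x in zip(comp, principal):
                assert ours[v] == pytest.approx(x, abs=1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_radiality_matches_direct_formula(self, seed):
        net = self._random_net(seed)
        g = net.graph
        ours = radiality(net)
        n_total = g.number_of_nodes()
        for comp in nx.connected_components(g):
            sub = g.subgraph(comp)
            if len(comp) == 1:
                (v,) = comp
                assert ours[v] == 0.0
                continue
            diam = nx.diameter(sub)
            for v in comp:
                dists = nx.shortest_path_length(sub, v)
                expected = (
                    len(comp)
                    / n_total
                    * sum(diam + 1 - d for w, d in dists.items() if w != v)
                    / (len(comp) - 1)
                )
                assert ours[v] == pytest.approx(expected)


class TestRankHubs:
    def test_competition_ranking_with_ties(self):
        ranked = rank_hubs({"A": 5, "B": 5, "C": 3}, method="degree", top_k=10)
        assert [(r, n) for r, n, _ in ranked] == [(1, "A"), (1, "B"), (3, "C")]

    def test_single_node(self):
        assert rank_hubs({"X": 7.0}) == [(1, "X", 7.0)]

    def test_top_k_cuts_by_rank(self):
        scores = {c: 10 - i for i, c in enumerate("ABCDEFGHIJKL")}
        ranked = rank_hubs(scores, top_k=3)
        assert [n for _, n, _ in ranked] == ["A", "B", "C"]


class TestRandomization:
    def test_er_sample_matches_networkx_degrees(self):
        rng = np.random.default_rng(0)
        deg = er_degree_sample(30, 60, rng)
        assert deg.sum() == 120 and len(deg) == 30
        g = nx.gnm_random_graph(30, 60, seed=1)
        assert sorted(d for _, d in g.degree) != []  # networkx reference exists
        # marginal check: mean degree equals 2m/n exactly for every draw
        assert deg.mean() == pytest.approx(2 * 60 / 30)

    def test_er_capacity_error(self):
        with pytest.raises(ParameterError):
            er_degree_sample(4, 7, np.random.default_rng(0))

    def test_identical_distribution_is_not_rejected(self):
        data, _ = gen_interactions(40, model="ER", n_edges_or_attach=80, seed=5)
        net = build_network(data)
        res = randomize_and_test(net, n_reps=200, seed=6)
        assert 0 <= res.ks_statistic <= 1
        assert res.p_value > 0.01  # its own model: no evidence against the null

    def test_heavy_tailed_network_is_rejected(self):
        data, truth = gen_interactions(200, model="BA", n_edges_or_attach=3, seed=7)
        net = build_network(data)
        res = randomize_and_test(net, n_reps=200, seed=8)
        assert res.p_value < 0.05 and res.significant

    def test_ba_planted_hub_attains_max_degree(self):
        data, truth = gen_interactions(
            200, model="BA", n_edges_or_attach=3, n_complexes=3, seed=9
        )
        net = build_network(data)
        degrees = dict(net.graph.degree)
        assert degrees[truth.planted_hub_ids[0]] == max(degrees.values())

    def test_er_cleaned_graph_keeps_exact_edge_count(self):
        data, _ = gen_interactions(100, model="ER", n_edges_or_attach=300, seed=10)
        net = build_network(data)
        assert net.graph.number_of_edges() == 300
        assert net.audit.removed_multi_edges == 0


class TestReport:
    def test_report_is_consistent_with_components(self):
        data, _ = gen_interactions(30, model="ER", n_edges_or_attach=45, seed=11)
        net = build_network(data)
        rep = centrality_report(net)
        assert set(rep.table.columns) == {
            "rad", "bc", "deg", "stress", "ev", "bcoeff", "brg", "bottleneck"
        }
        # bridging is the product of its factors, everywhere
        assert np.allclose(rep.table["brg"], rep.table["bcoeff"] * rep.table["bc"])
        hubs = rank_hubs(rep, method="degree")
        assert hubs[0][2] == rep.table["deg"].max()
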