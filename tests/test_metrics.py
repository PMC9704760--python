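import random

import networkx as nx
import pytest

from pathmaps.core import Edge, Node, NodeClass, PathwayGraph
from pathmaps.metrics import (
    Measure,
    MetricsError,
    annotate_with_centrality,
    betweenness_centrality,
    closeness_centrality,
    compute,
    degree_centrality,
    pagerank,
)

from conftest import build_graph, make_random_flat_graph


def nx_undirected(g):
    u = nx.Graph()
    u.add_nodes_from(g.nodes)
    for e in g.edges.values():
        if e.source != e.target:
            u.add_edge(e.source, e.target)
    return u


class TestDegree:
    def test_single_node(self):
        rep = degree_centrality(build_graph(["A"]))
        assert rep.raw == {"A": 0.0} and rep.normalized == {"A": 0.0}

    def test_star(self, canon):
        rep = degree_centrality(canon["star4"])
        assert rep.raw["c"] == 4 and rep.normalized["c"] == 1.0
        assert all(rep.normalized[f"l{i}"] == 0.25 for i in range(4))

    def test_self_loop_counts_twice(self):
        rep = degree_centrality(build_graph(["A"], [("e0", "A", "A")]))
        assert rep.raw["A"] == 2

    def test_empty_graph_rejected(self):
        with pytest.raises(MetricsError):
            degree_centrality(PathwayGraph())


class TestCloseness:
    def test_two_nodes_one_edge(self):
        rep = closeness_centrality(build_graph("AB", [("e0", "A", "B")]))
        assert rep.raw == {"A": 1.0, "B": 1.0}
        assert rep.normalized == {"A": 1.0, "B": 1.0}

    def test_path3_hand_computed(self, canon):
        rep = closeness_centrality(canon["path3"])
        assert rep.raw["B"] == pytest.approx(2.0)
        assert rep.raw["A"] == pytest.approx(1.5)
        assert rep.normalized["B"] == pytest.approx(1.0)
        assert rep.normalized["A"] == pytest.approx(0.75)

    def test_disconnected_pairs_contribute_zero(self):
        g = build_graph("ABXY", [("e0", "A", "B"), ("e1", "X", "Y")])
        rep = closeness_centrality(g)
        # each node sees exactly one partner at distance 1 out of 3 others
        assert all(v == pytest.approx(1.0) for v in rep.raw.values())
        assert all(v == pytest.approx(1 / 3) for v in rep.normalized.values())

    def test_matches_networkx_harmonic(self):
        rng = random.Random(11)
        for _ in range(25):
            g = make_random_flat_graph(rng, n_max=10)
            rep = closeness_centrality(g)
            want = nx.harmonic_centrality(nx_undirected(g))
            for nid in g.nodes:
                assert rep.raw[nid] == pytest.approx(want[nid])

    def test_singleton_rejected(self):
        with pytest.raises(MetricsError):
            closeness_centrality(build_graph(["A"]))


class TestBetweenness:
    def test_path3_middle(self, canon):
        rep = betweenness_centrality(canon["path3"])
        assert rep.normalized == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_star_center(self, canon):
        rep = betweenness_centrality(canon["star4"])
        assert rep.normalized["c"] == pytest.approx(1.0)

    def test_k4_all_zero(self, canon):
        rep = betweenness_centrality(canon["k4"])
        assert all(v == 0.0 for v in rep.normalized.values())

    def test_matches_networkx_on_random_graphs(self):
        rng = random.Random(12)
        for _ in range(30):
            g = make_random_flat_graph(rng, n_max=10)
            if len(g.nodes) < 3:
                continue
            rep = betweenness_centrality(g)
            want = nx.betweenness_centrality(nx_undirected(g), normalized=False)
            for nid in g.nodes:
                assert rep.raw[nid] == pytest.approx(want[nid])

    def test_too_small_rejected(self):
        with pytest.raises(MetricsError):
            betweenness_centrality(build_graph("AB", [("e0", "A", "B")]))


class TestPagerank:
    def test_single_node(self):
        rep = pagerank(build_graph(["A"]))
        assert rep.raw == {"A": 1.0}

    def test_symmetric_two_cycle(self):
        g = build_graph("AB", [("e0", "A", "B"), ("e1", "B", "A")])
        rep = pagerank(g)
        assert rep.raw["A"] == pytest.approx(0.5, abs=1e-6)

    def test_three_cycle_uniform(self, canon):
        rep = pagerank(canon["cycle3"])
        for v in rep.raw.values():
            assert v == pytest.approx(1 / 3, abs=1e-6)

    def test_sums_to_one_and_matches_networkx(self):
        rng = random.Random(13)
        for _ in range(25):
            g = make_random_flat_graph(rng, n_max=10)
            rep = pagerank(g)
            assert sum(rep.raw.values()) == pytest.approx(1.0, abs=1e-6)
            dg = nx.DiGraph()
            dg.add_nodes_from(g.nodes)
            for e in g.edges.values():
                dg.add_edge(e.source, e.target)
            want = nx.pagerank(dg, alpha=0.85, tol=1e-10)
            for nid in g.nodes:
                assert rep.raw[nid] == pytest.approx(want[nid], abs=1e-5)

    def test_invariant_under_relabeling(self):
        g = build_graph("ABC", [("e0", "A", "B"), ("e1", "B", "C"), ("e2", "C", "A"),
                                ("e3", "A", "C")])
        relabel = {"A": "zz", "B": "aa", "C": "mm"}
        h = PathwayGraph()
        for nid in g.nodes:
            h.add_node(Node(relabel[nid]))
        for eid, e in g.edges.items():
            h.add_edge(Edge(eid, relabel[e.source], relabel[e.target]))
        rg, rh = pagerank(g), pagerank(h)
        for nid in g.nodes:
            assert rg.raw[nid] == pytest.approx(rh.raw[relabel[nid]], abs=1e-9)


class TestNormalizationInvariants:
    @pytest.mark.parametrize("measure", list(Measure))
    def test_normalized_in_unit_interval(self, measure):
        rng = random.Random(14)
        for _ in range(15):
            g = make_random_flat_graph(rng, n_max=10)
            if len(g.nodes) < 3:
                continue
            rep = compute(g, measure)
            assert set(rep.raw) == set(rep.normalized)
            for v in rep.normalized.values():
                assert 0.0 <= v <= 1.0 + 1e-12

    @pytest.mark.parametrize("measure", [Measure.DEGREE, Measure.PAGERANK])
    def test_max_normalized_is_one(self, measure):
        rng = random.Random(15)
        for _ in range(15):
            g = make_random_flat_graph(rng, n_max=10)
            rep = compute(g, measure)
            if any(v > 0 for v in rep.raw.values()):
                assert max(rep.normalized.values()) == pytest.approx(1.0)


class TestContainerExclusion:
    def test_pure_container_scores_zero(self):
        g = build_graph(
            [("comp", "compartment"), ("a", "macromolecule", "comp"),
             ("b", "macromolecule", "comp"), "c"],
            [("e0", "a", "b"), ("e1", "b", "c")],
        )
        for fn in (closeness_centrality, betweenness_centrality, pagerank):
            rep = fn(g)
            assert rep.raw["comp"] == 0.0

    def test_container_with_arcs_participates(self, nesting3):
        rep = pagerank(nesting3)
        assert rep.raw["cx"] > 0.0


class TestAnnotate:
    def test_label_suffix_rounding(self):
        g = build_graph(["A"])
        g.nodes["A"].label = "TP53"
        rep = degree_centrality(g)
        rep.normalized["A"] = 0.4567
        annotate_with_centrality(g, rep)
        assert g.nodes["A"].label == "TP53 (0.46)"
        assert g.nodes["A"].highlight_thickness == 0.4567

    def test_extremes(self):
        g = build_graph(["A", "B"], [("e0", "A", "B")])
        rep = degree_centrality(g)
        annotate_with_centrality(g, rep)
        assert g.nodes["A"].label.endswith("(1.00)")

    def test_zero_formats_and_min_thickness(self):
        g = build_graph(["A", "B"])
        rep = degree_centrality(g)
        annotate_with_centrality(g, rep)
        assert g.nodes["A"].label.endswith("(0.00)")
        assert g.nodes["A"].highlight_thickness == 0.0

    def test_key_mismatch_rejected(self):
        g = build_graph(["A", "B"])
        rep = degree_centrality(g)
        del rep.normalized["B"]
        with pytest.raises(MetricsError):
            annotate_with_centrality(g, rep)
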