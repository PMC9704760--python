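import random

import pytest

from pathmaps.core import Edge, Node, NodeClass, PathwayGraph
from pathmaps.queries import (
    Direction,
    PathExplosionError,
    QueryError,
    QueryOptions,
    common_stream,
    compound_bfs,
    neighborhood,
    paths_between,
    paths_from_to,
    shortest_path,
)
from pathmaps.core import UnknownNodeError

from conftest import build_graph, make_random_compound_graph, make_random_flat_graph
import oracles

N_RANDOM = 40  # random graphs per property check (acceptance runs 200)


class TestQueryOptions:
    def test_negative_k_rejected(self):
        with pytest.raises(QueryError):
            QueryOptions(limit_k=-1)

    def test_negative_d_rejected(self):
        with pytest.raises(QueryError):
            QueryOptions(additional_d=-1)

    def test_direction_coerced(self):
        assert QueryOptions(direction="upstream").direction is Direction.UPSTREAM


class TestCompoundBfs:
    def test_isolated_node(self):
        g = build_graph(["A"])
        assert compound_bfs(g, ["A"], limit_k=5) == {"A": 0}

    def test_limit_k_cuts_chain(self):
        g = build_graph("ABC", [("e0", "A", "B"), ("e1", "B", "C")])
        assert compound_bfs(g, ["A"], limit_k=1) == {"A": 0, "B": 1}

    def test_complex_member_reaches_through_container(self):
        # m in complex X; arc X->Z: m reaches X at 0 via closure, then Z at 1
        g = build_graph(
            [("X", "complex"), ("m", "macromolecule", "X"), "Z"],
            [("e0", "X", "Z")],
        )
        dist = compound_bfs(g, ["m"], limit_k=1)
        assert dist["Z"] == 1
        assert dist["X"] == 0

    def test_unknown_source_raises(self):
        g = build_graph(["A"])
        with pytest.raises(UnknownNodeError):
            compound_bfs(g, ["nope"])

    def test_sibling_reached_at_same_distance(self, nesting3):
        dist = compound_bfs(nesting3, ["m1"])
        assert dist["m2"] == 0  # via parent complex, zero cost

    @pytest.mark.parametrize("direction", ["downstream", "upstream", "both"])
    def test_matches_closure_expanded_dijkstra(self, direction):
        rng = random.Random(421)
        for _ in range(N_RANDOM):
            g = make_random_compound_graph(rng)
            src = [sorted(g.nodes)[0]]
            for k in (None, 2):
                got = compound_bfs(g, src, Direction(direction), k)
                want = oracles.oracle_compound_distances(g, src, direction, k)
                assert got == want


class TestNeighborhood:
    def test_star_downstream_one(self, canon):
        g = canon["star4"]
        res = neighborhood(g, ["c"], Direction.DOWNSTREAM, 1)
        assert res.result_nodes == {"c", "l0", "l1", "l2", "l3"}
        assert res.result_edges == set(g.edges)

    def test_chain_upstream_two(self):
        g = build_graph(
            "ABCD", [("ab", "A", "B"), ("bc", "B", "C"), ("cd", "C", "D")]
        )
        res = neighborhood(g, ["D"], Direction.UPSTREAM, 2)
        assert res.result_nodes == {"D", "C", "B"}
        assert res.result_edges == {"bc", "cd"}

    def test_two_sources_union(self):
        g = build_graph("ABXY", [("e0", "A", "B"), ("e1", "X", "Y")])
        res = neighborhood(g, ["A", "X"], Direction.DOWNSTREAM, 1)
        assert res.result_nodes == {"A", "B", "X", "Y"}

    def test_monotone_in_k(self):
        rng = random.Random(7)
        for _ in range(10):
            g = make_random_flat_graph(rng)
            src = [sorted(g.nodes)[0]]
            prev = set()
            for k in range(0, 5):
                cur = neighborhood(g, src, Direction.DOWNSTREAM, k).result_nodes
                assert prev <= cur
                prev = cur

    @pytest.mark.parametrize("direction", ["downstream", "upstream", "both"])
    def test_flat_matches_textbook_bfs(self, direction):
        rng = random.Random(99)
        for _ in range(N_RANDOM):
            g = make_random_flat_graph(rng)
            ids = sorted(g.nodes)
            src = ids[: rng.randint(1, 2)]
            k = rng.choice([1, 2, 3, None])
            res = neighborhood(g, src, Direction(direction), k)
            dist, edges = oracles.oracle_flat_bfs_edges(g, src, direction, k)
            assert res.distances == dist
            assert res.result_nodes == set(dist)
            assert res.result_edges == edges


class TestCommonStream:
    def test_simple_common_target(self):
        g = build_graph("ABX", [("ax", "A", "X"), ("bx", "B", "X")])
        res = common_stream(g, ["A", "B"], Direction.DOWNSTREAM, 1)
        assert res.focus_nodes == {"X"}
        assert res.result_edges == {"ax", "bx"}

    def test_roles_partition_disjoint(self):
        # seeds (green), common (red) and links (yellow) never overlap
        g = build_graph(
            "ABMX",
            [("am", "A", "M"), ("mx", "M", "X"), ("bx", "B", "X")],
        )
        res = common_stream(g, ["A", "B"], Direction.DOWNSTREAM, 2)
        seeds, common, links = res.seed_nodes, res.focus_nodes, res.link_nodes()
        assert seeds & common == set()
        assert seeds & links == set()
        assert common & links == set()
        assert common == {"X"}
        assert links == {"M"}
        assert seeds | common | links >= res.result_nodes | res.seed_nodes

    def test_k_dependence(self):
        g = build_graph(
            "ABXY", [("ax", "A", "X"), ("xy", "X", "Y"), ("by", "B", "Y")]
        )
        assert common_stream(g, ["A", "B"], limit_k=1).focus_nodes == set()
        assert common_stream(g, ["A", "B"], limit_k=2).focus_nodes == {"Y"}

    def test_requires_two_sources(self):
        g = build_graph("AB", [("e0", "A", "B")])
        with pytest.raises(QueryError):
            common_stream(g, ["A"])

    def test_distance_is_max_over_sources(self):
        g = build_graph(
            "ABMX", [("am", "A", "M"), ("mx", "M", "X"), ("bx", "B", "X")]
        )
        res = common_stream(g, ["A", "B"], Direction.DOWNSTREAM, 3)
        assert res.distances["X"] == 2  # 2 from A, 1 from B

    def test_both_is_union_of_streams(self):
        g = build_graph(
            "ABXR", [("ax", "A", "X"), ("bx", "B", "X"), ("ra", "R", "A"), ("rb", "R", "B")]
        )
        both = common_stream(g, ["A", "B"], Direction.BOTH, 2)
        assert both.focus_nodes == {"X", "R"}

    def test_common_nodes_match_intersection_oracle(self):
        rng = random.Random(1234)
        for _ in range(N_RANDOM):
            g = make_random_flat_graph(rng)
            ids = sorted(g.nodes)
            sources = ids[:2]
            k = rng.choice([1, 2, 3, None])
            for direction in ("downstream", "upstream"):
                res = common_stream(g, sources, Direction(direction), k)
                want = oracles.oracle_common_stream_nodes(g, sources, direction, k)
                assert res.focus_nodes == want

    def test_subset_of_single_source_neighborhood(self):
        rng = random.Random(5)
        for _ in range(20):
            g = make_random_flat_graph(rng)
            ids = sorted(g.nodes)
            res = common_stream(g, ids[:2], Direction.DOWNSTREAM, 3)
            for s in ids[:2]:
                nb = neighborhood(g, [s], Direction.DOWNSTREAM, 3).result_nodes
                assert res.focus_nodes <= nb


class TestPathsBetween:
    def test_single_arc(self):
        g = build_graph("AB", [("e0", "A", "B")])
        res = paths_between(g, ["A", "B"], 1)
        assert res.paths == [("A", "B")]

    def test_two_routes_and_k_cutoff(self):
        g = build_graph(
            "ABXY",
            [("e0", "A", "X"), ("e1", "X", "B"), ("e2", "A", "Y"), ("e3", "Y", "B")],
        )
        res = paths_between(g, ["A", "B"], 2)
        assert sorted(res.paths) == [("A", "X", "B"), ("A", "Y", "B")]
        res1 = paths_between(g, ["A", "B"], 1)
        assert res1.paths == []
        assert {"A", "B"} <= res1.result_nodes  # seeds stay even when unlinked

    def test_no_seed_intermediates(self):
        g = build_graph(
            "ABC", [("e0", "A", "B"), ("e1", "B", "C")]
        )
        res = paths_between(g, ["A", "B", "C"], 3)
        assert ("A", "B", "C") not in res.paths
        assert ("A", "B") in res.paths and ("B", "C") in res.paths

    def test_fig5_like_two_route_fixture(self, canon):
        res = paths_between(canon["two_route"], ["s", "t"], 7)
        assert len(res.paths) == 2
        assert sorted(len(p) - 1 for p in res.paths) == [4, 6]

    def test_requires_two_seeds(self):
        g = build_graph("AB", [("e0", "A", "B")])
        with pytest.raises(QueryError):
            paths_between(g, ["A"], 3)

    def test_matches_exhaustive_enumeration(self):
        rng = random.Random(31)
        for _ in range(N_RANDOM):
            g = make_random_flat_graph(rng, n_max=9)
            ids = sorted(g.nodes)
            seeds = ids[: rng.randint(2, 3)]
            k = rng.randint(1, 4)
            res = paths_between(g, seeds, k)
            assert set(res.paths) == oracles.oracle_paths_between(g, seeds, k)

    def test_explosion_guard(self):
        # dense bidirectional clique: enumeration must abort, not hang
        ids = [f"n{i}" for i in range(9)]
        g = PathwayGraph()
        for nid in ids:
            g.add_node(Node(nid))
        c = 0
        for u in ids:
            for v in ids:
                if u != v:
                    g.add_edge(Edge(f"e{c}", u, v))
                    c += 1
        with pytest.raises(PathExplosionError):
            paths_between(g, [ids[0], ids[-1]], 8, max_paths=100)

    def test_terminates_on_cycles(self):
        g = build_graph(
            "ABC", [("e0", "A", "B"), ("e1", "B", "A"), ("e2", "B", "C")]
        )
        res = paths_between(g, ["A", "C"], 5)
        assert res.paths == [("A", "B", "C")]


class TestPathsFromTo:
    def test_worked_example_lengths(self, canon):
        # shortest 3 plus relaxation 2 -> lengths exactly {3, 4, 5}
        res = paths_from_to(canon["worked_example"], ["s"], ["t"], additional_d=2)
        lengths = sorted(len(p) - 1 for p in res.paths)
        assert lengths == [3, 4, 5]

    def test_unreachable_pair_empty(self):
        g = build_graph("AB")
        res = paths_from_to(g, ["A"], ["B"])
        assert res.paths == []
        assert res.result_edges == set()

    def test_d_zero_is_all_shortest(self):
        rng = random.Random(77)
        for _ in range(N_RANDOM):
            g = make_random_flat_graph(rng, n_max=10)
            ids = sorted(g.nodes)
            s, t = ids[0], ids[-1]
            res = paths_from_to(g, [s], [t], additional_d=0)
            want = oracles.oracle_paths_from_to(g, [s], [t], None, 0)
            assert set(res.paths) == want

    def test_matches_enumeration_with_k_and_d(self):
        rng = random.Random(78)
        for _ in range(N_RANDOM):
            g = make_random_flat_graph(rng, n_max=9)
            ids = sorted(g.nodes)
            sources, targets = ids[:2], ids[-2:]
            k = rng.choice([2, 3, None])
            d = rng.randint(0, 2)
            res = paths_from_to(g, sources, targets, k, d)
            want = oracles.oracle_paths_from_to(g, sources, targets, k, d)
            assert set(res.paths) == want

    def test_monotone_in_d(self):
        rng = random.Random(79)
        for _ in range(15):
            g = make_random_flat_graph(rng, n_max=9)
            ids = sorted(g.nodes)
            prev = set()
            for d in range(0, 3):
                cur = set(paths_from_to(g, [ids[0]], [ids[-1]], None, d).paths)
                assert prev <= cur
                prev = cur

    def test_relaxation_is_per_pair(self):
        # (s1,t) shortest 1, (s2,t) shortest 3: d=0 must still return the
        # 3-long path for s2 even though the global minimum is 1
        g = build_graph(
            ["s1", "s2", "x", "y", "t"],
            [("a", "s1", "t"), ("b", "s2", "x"), ("c", "x", "y"), ("d", "y", "t")],
        )
        res = paths_from_to(g, ["s1", "s2"], ["t"], additional_d=0)
        assert set(res.paths) == {("s1", "t"), ("s2", "x", "y", "t")}

    def test_empty_source_set_rejected(self):
        g = build_graph("AB", [("e0", "A", "B")])
        with pytest.raises(QueryError):
            paths_from_to(g, [], ["B"])


class TestShortestPath:
    def test_direct_arc(self):
        g = build_graph("AB", [("e0", "A", "B")])
        res = shortest_path(g, "A", "B")
        assert res.paths == [("A", "B")]
        assert res.result_edges == {"e0"}

    def test_lexicographic_tie_break(self):
        g = build_graph(
            "ABCD",
            [("e0", "A", "B"), ("e1", "B", "D"), ("e2", "A", "C"), ("e3", "C", "D")],
        )
        res = shortest_path(g, "A", "D")
        assert res.paths == [("A", "B", "D")]

    def test_unreachable_is_empty_not_error(self):
        g = build_graph("AB")
        res = shortest_path(g, "A", "B")
        assert res.paths == []
        assert res.result_nodes == set()

    def test_same_node_rejected(self):
        g = build_graph("AB", [("e0", "A", "B")])
        with pytest.raises(QueryError):
            shortest_path(g, "A", "A")

    def test_matches_networkx_tie_rule(self):
        rng = random.Random(55)
        for _ in range(N_RANDOM):
            g = make_random_flat_graph(rng, n_max=10)
            ids = sorted(g.nodes)
            s, t = ids[0], ids[-1]
            want = oracles.oracle_shortest_path(g, s, t)
            got = shortest_path(g, s, t)
            if want is None:
                assert got.paths == []
            else:
                assert got.paths == [want]


class TestCompoundSemantics:
    def test_path_through_closure(self, nesting3):
        # m1 -> (closure: cx) -> Z costs one arc
        res = paths_from_to(nesting3, ["m1"], ["Z"])
        assert len(res.paths) == 1
        assert res.paths[0][-1] == "Z"
        assert len([1 for u, v in zip(res.paths[0], res.paths[0][1:])]) >= 1

    def test_result_invariants_on_random_graphs(self):
        rng = random.Random(8)
        for _ in range(20):
            g = make_random_compound_graph(rng, n_max=8)
            ids = sorted(g.nodes)
            res = paths_between(g, ids[:2], 3, max_paths=5000)
            for path in res.paths:
                assert len(set(path)) == len(path)  # simple
            for eid in res.result_edges:
                e = g.edges[eid]
                assert {e.source, e.target} <= res.result_nodes | res.seed_nodes
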