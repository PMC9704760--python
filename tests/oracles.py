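"""Independent brute-force oracles used to cross-check the query engine.

Flat-graph oracles lean on networkx (textbook BFS / exhaustive
``all_simple_paths``); compound behavior is checked against the
closure-expanded reduction: containment links become zero-weight edges
in both directions and distances come from Dijkstra.
"""

from __future__ import annotations

from collections import deque
from typing import Dict, Iterable, List, Optional, Set, Tuple

import networkx as nx

from pathmaps.core import PathwayGraph


def to_nx(graph: PathwayGraph, direction: str = "downstream") -> nx.DiGraph:
    """Arc structure only (no containment), orientation applied."""
    g = nx.DiGraph()
    g.add_nodes_from(graph.nodes)
    for e in graph.edges.values():
        if direction in ("downstream", "both"):
            g.add_edge(e.source, e.target)
        if direction in ("upstream", "both"):
            g.add_edge(e.target, e.source)
    return g


def closure_expanded_nx(graph: PathwayGraph, direction: str = "downstream") -> nx.DiGraph:
    """The reduction: arcs weight 1, containment links weight 0 both ways."""
    g = nx.DiGraph()
    g.add_nodes_from(graph.nodes)
    for e in graph.edges.values():
        pairs = []
        if direction in ("downstream", "both"):
            pairs.append((e.source, e.target))
        if direction in ("upstream", "both"):
            pairs.append((e.target, e.source))
        for u, v in pairs:
            if g.has_edge(u, v):
                g[u][v]["weight"] = min(g[u][v]["weight"], 1)
            else:
                g.add_edge(u, v, weight=1)
    for nid, node in graph.nodes.items():
        if node.parent is not None:
            g.add_edge(nid, node.parent, weight=0)
            g.add_edge(node.parent, nid, weight=0)
    return g


def oracle_compound_distances(
    graph: PathwayGraph,
    sources: Iterable[str],
    direction: str = "downstream",
    limit_k: Optional[int] = None,
) -> Dict[str, int]:
    g = closure_expanded_nx(graph, direction)
    dist = nx.multi_source_dijkstra_path_length(g, set(sources), weight="weight")
    if limit_k is not None:
        dist = {n: d for n, d in dist.items() if d <= limit_k}
    return {n: int(d) for n, d in dist.items()}


def oracle_flat_bfs_edges(
    graph: PathwayGraph,
    sources: Iterable[str],
    direction: str,
    limit_k: Optional[int],
) -> Tuple[Dict[str, int], Set[str]]:
    """Textbook multi-source BFS on a flat graph, recording traversed edges.

    Returns (distances, traversed edge ids); an edge is traversed when BFS
    expands one of its direction-respecting endpoints within the bound.
    """
    cap = float("inf") if limit_k is None else limit_k
    dist: Dict[str, int] = {s: 0 for s in set(sources)}
    dq = deque(sorted(dist))
    while dq:
        u = dq.popleft()
        if dist[u] + 1 > cap:
            continue
        steps = []
        if direction in ("downstream", "both"):
            steps += [(e.target,) for e in graph.out_edges(u)]
        if direction in ("upstream", "both"):
            steps += [(e.source,) for e in graph.in_edges(u)]
        for (v,) in steps:
            if v not in dist:
                dist[v] = dist[u] + 1
                dq.append(v)
    traversed: Set[str] = set()
    for eid, e in graph.edges.items():
        if e.source in dist and e.target in dist:
            if direction in ("downstream", "both") and dist[e.source] + 1 <= cap:
                traversed.add(eid)
            if direction in ("upstream", "both") and dist[e.target] + 1 <= cap:
                traversed.add(eid)
    return dist, traversed


def oracle_paths_between(
    graph: PathwayGraph, seeds: List[str], limit_k: int, direction: str = "downstream"
) -> Set[Tuple[str, ...]]:
    g = to_nx(graph, direction)
    seed_set = set(seeds)
    out: Set[Tuple[str, ...]] = set()
    for s in seeds:
        for t in seeds:
            if s == t:
                continue
            for path in nx.all_simple_paths(g, s, t, cutoff=limit_k):
                if not (set(path[1:-1]) & seed_set):
                    out.add(tuple(path))
    return out


def oracle_paths_from_to(
    graph: PathwayGraph,
    sources: List[str],
    targets: List[str],
    limit_k: Optional[int],
    additional_d: int,
    direction: str = "downstream",
) -> Set[Tuple[str, ...]]:
    g = to_nx(graph, direction)
    k_cap = float("inf") if limit_k is None else limit_k
    out: Set[Tuple[str, ...]] = set()
    for s in set(sources):
        for t in set(targets):
            if s == t or not nx.has_path(g, s, t):
                continue
            shortest = nx.shortest_path_length(g, s, t)
            cap = min(shortest + additional_d, k_cap)
            if shortest > cap:
                continue
            for path in nx.all_simple_paths(g, s, t, cutoff=int(cap)):
                out.add(tuple(path))
    return out


def oracle_shortest_path(
    graph: PathwayGraph, source: str, target: str, direction: str = "downstream"
) -> Optional[Tuple[str, ...]]:
    g = to_nx(graph, direction)
    if not nx.has_path(g, source, target):
        return None
    return min(tuple(p) for p in nx.all_shortest_paths(g, source, target))


def oracle_common_stream_nodes(
    graph: PathwayGraph,
    sources: List[str],
    direction: str,
    limit_k: Optional[int],
) -> Set[str]:
    sets = []
    for s in sources:
        dist, _ = oracle_flat_bfs_edges(graph, [s], direction, limit_k)
        sets.append(set(dist))
    return set.intersection(*sets) - set(sources)
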