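"""Compound-aware graph mining queries.

All queries share one traversal convention: following an arc costs one
unit of distance, while moving along a containment link (child to parent
or parent to child) is free.  Reaching any node therefore implicitly
reaches its whole containment tree at the same distance.  This is
realized either as a 0-1 breadth-first search (distances) or as a
depth-first enumeration over the closure-expanded move relation (path
listing queries).

Arc direction is configurable: ``downstream`` follows arcs source to
target, ``upstream`` reverses them and ``both`` ignores orientation.
Path enumeration is exponential in the worst case, so a configurable cap
(default 10,000 paths) aborts runaway queries with an explicit error.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .core import PathwayGraph, UnknownNodeError

__all__ = [
    "Direction",
    "QueryOptions",
    "QueryResult",
    "QueryError",
    "PathExplosionError",
    "compound_bfs",
    "neighborhood",
    "common_stream",
    "paths_between",
    "paths_from_to",
    "shortest_path",
    "MAX_PATHS_DEFAULT",
]

MAX_PATHS_DEFAULT = 10_000

INF = float("inf")


class QueryError(ValueError):
    """Invalid query parameters."""


class PathExplosionError(RuntimeError):
    """Raised when a path enumeration exceeds its configured cap."""


class Direction(str, Enum):
    DOWNSTREAM = "downstream"
    UPSTREAM = "upstream"
    BOTH = "both"


@dataclass
class QueryOptions:
    """Parameter block shared by the query API and the service facade.

    ``limit_k`` bounds path/link length in *edges* (``None`` = unbounded);
    ``additional_d`` relaxes the shortest-path requirement of the
    from-to query.
    """

    direction: Direction = Direction.DOWNSTREAM
    limit_k: Optional[int] = None
    additional_d: int = 0
    sources: Tuple[str, ...] = ()
    targets: Tuple[str, ...] = ()
    max_paths: int = MAX_PATHS_DEFAULT

    def __post_init__(self) -> None:
        if self.limit_k is not None and self.limit_k < 0:
            raise QueryError("limit_k must be >= 0")
        if self.additional_d < 0:
            raise QueryError("additional_d must be >= 0")
        if not isinstance(self.direction, Direction):
            self.direction = Direction(self.direction)


@dataclass
class QueryResult:
    """Highlighted subsets produced by a query.

    ``focus_nodes`` singles out the distinguished hits (e.g. the common
    nodes of a common-stream query); the remaining non-seed members of
    ``result_nodes`` are connecting-link nodes.
    """

    seed_nodes: Set[str] = field(default_factory=set)
    result_nodes: Set[str] = field(default_factory=set)
    result_edges: Set[str] = field(default_factory=set)
    focus_nodes: Set[str] = field(default_factory=set)
    distances: Dict[str, int] = field(default_factory=dict)
    paths: List[Tuple[str, ...]] = field(default_factory=list)

    def link_nodes(self) -> Set[str]:
        return self.result_nodes - self.focus_nodes - self.seed_nodes


# ---------------------------------------------------------------------------
# traversal primitives
# ---------------------------------------------------------------------------


def _check_seeds(graph: PathwayGraph, seeds: Iterable[str], minimum: int = 1) -> List[str]:
    seeds = list(seeds)
    if len(set(seeds)) < minimum:
        raise QueryError(f"query requires at least {minimum} distinct seed node(s)")
    for s in seeds:
        if s not in graph:
            raise UnknownNodeError(f"unknown seed node {s!r}")
    return seeds


def _arc_moves(
    graph: PathwayGraph, node_id: str, direction: Direction
) -> Iterable[Tuple[str, str]]:
    """Direction-respecting arc steps from ``node_id`` as (neighbor, edge id)."""
    if direction in (Direction.DOWNSTREAM, Direction.BOTH):
        for e in graph.out_edges(node_id):
            yield e.target, e.id
    if direction in (Direction.UPSTREAM, Direction.BOTH):
        for e in graph.in_edges(node_id):
            yield e.source, e.id


def _containment_moves(graph: PathwayGraph, node_id: str) -> Iterable[str]:
    node = graph.nodes[node_id]
    if node.parent is not None:
        yield node.parent
    yield from graph._children[node_id]


def compound_bfs(
    graph: PathwayGraph,
    sources: Iterable[str],
    direction: Direction = Direction.DOWNSTREAM,
    limit_k: Optional[int] = None,
) -> Dict[str, int]:
    """Minimum arc counts from any source, with free containment hops.

    Implemented as a 0-1 BFS on the move relation where containment links
    (both ways) have weight 0 and arcs weight 1.  Nodes farther than
    ``limit_k`` arcs are absent from the returned map.
    """
    sources = _check_seeds(graph, sources)
    cap = INF if limit_k is None else limit_k
    dist: Dict[str, int] = {}
    dq: deque = deque()
    for s in dict.fromkeys(sources):
        dist[s] = 0
        dq.appendleft((0, s))
    while dq:
        d, u = dq.popleft()
        if d > dist.get(u, INF):
            continue  # stale entry
        for v in _containment_moves(graph, u):
            if d < dist.get(v, INF):
                dist[v] = d
                dq.appendleft((d, v))
        if d + 1 > cap:
            continue
        for v, _eid in _arc_moves(graph, u, direction):
            if d + 1 < dist.get(v, INF):
                dist[v] = d + 1
                dq.append((d + 1, v))
    return dist


def _traversed_edges(
    graph: PathwayGraph,
    dist: Dict[str, int],
    direction: Direction,
    limit_k: Optional[int],
) -> Set[str]:
    """Edges lying on some direction-respecting step of a bounded BFS."""
    cap = INF if limit_k is None else limit_k
    out: Set[str] = set()
    for eid, edge in graph.edges.items():
        du = dist.get(edge.source)
        dv = dist.get(edge.target)
        if du is None or dv is None:
            continue
        forward_ok = direction in (Direction.DOWNSTREAM, Direction.BOTH) and du + 1 <= cap
        backward_ok = direction in (Direction.UPSTREAM, Direction.BOTH) and dv + 1 <= cap
        if forward_ok or backward_ok:
            out.add(eid)
    return out


# ---------------------------------------------------------------------------
# queries
# ---------------------------------------------------------------------------


def neighborhood(
    graph: PathwayGraph,
    sources: Iterable[str],
    direction: Direction = Direction.DOWNSTREAM,
    limit_k: Optional[int] = None,
) -> QueryResult:
    """Every node within ``limit_k`` arcs of any source, plus the arcs walked."""
    sources = _check_seeds(graph, sources)
    dist = compound_bfs(graph, sources, direction, limit_k)
    seed_set = set(sources)
    return QueryResult(
        seed_nodes=seed_set,
        result_nodes=set(dist),
        result_edges=_traversed_edges(graph, dist, direction, limit_k),
        focus_nodes=set(dist) - seed_set,
        distances=dist,
    )


def _opposite(direction: Direction) -> Direction:
    return Direction.UPSTREAM if direction is Direction.DOWNSTREAM else Direction.DOWNSTREAM


def _common_stream_oriented(
    graph: PathwayGraph,
    sources: Sequence[str],
    direction: Direction,
    limit_k: Optional[int],
) -> QueryResult:
    cap = INF if limit_k is None else limit_k
    per_source = {s: compound_bfs(graph, [s], direction, limit_k) for s in sources}
    common: Set[str] = set.intersection(*(set(d) for d in per_source.values()))
    common -= set(sources)
    distances = {c: max(per_source[s][c] for s in sources) for c in common}

    result_nodes: Set[str] = set(common)
    result_edges: Set[str] = set()
    if common:
        # Distance from each node to the nearest common node, following the
        # same orientation (so measured against the reverse traversal).
        to_common = compound_bfs(graph, common, _opposite(direction), limit_k)
        for s in sources:
            fwd = per_source[s]
            for nid, d_fwd in fwd.items():
                d_back = to_common.get(nid)
                if d_back is not None and d_fwd + d_back <= cap:
                    result_nodes.add(nid)
            for eid, edge in graph.edges.items():
                if direction is Direction.DOWNSTREAM:
                    du, dv = fwd.get(edge.source), to_common.get(edge.target)
                else:
                    du, dv = fwd.get(edge.target), to_common.get(edge.source)
                if du is not None and dv is not None and du + 1 + dv <= cap:
                    result_edges.add(eid)
    result_nodes -= set(sources)
    return QueryResult(
        seed_nodes=set(sources),
        result_nodes=result_nodes,
        result_edges=result_edges,
        focus_nodes=set(common),
        distances=distances,
    )


def common_stream(
    graph: PathwayGraph,
    sources: Iterable[str],
    direction: Direction = Direction.DOWNSTREAM,
    limit_k: Optional[int] = None,
) -> QueryResult:
    """Nodes reachable within ``limit_k`` from *every* source.

    Downstream finds common targets, upstream common regulators; ``both``
    runs the two oriented queries and unions them.  ``focus_nodes`` holds
    the common nodes; ``result_nodes`` additionally includes the nodes on
    the connecting paths so the highlight is self-contained.
    """
    sources = _check_seeds(graph, sources, minimum=2)
    if direction is Direction.BOTH:
        down = _common_stream_oriented(graph, sources, Direction.DOWNSTREAM, limit_k)
        up = _common_stream_oriented(graph, sources, Direction.UPSTREAM, limit_k)
        merged = {**up.distances}
        for nid, d in down.distances.items():
            merged[nid] = min(d, merged.get(nid, d))
        return QueryResult(
            seed_nodes=set(sources),
            result_nodes=down.result_nodes | up.result_nodes,
            result_edges=down.result_edges | up.result_edges,
            focus_nodes=down.focus_nodes | up.focus_nodes,
            distances=merged,
        )
    return _common_stream_oriented(graph, sources, direction, limit_k)


# ---------------------------------------------------------------------------
# path enumeration
# ---------------------------------------------------------------------------


def _expanded_moves(
    graph: PathwayGraph, node_id: str, direction: Direction
) -> List[Tuple[str, int, Optional[str]]]:
    """(neighbor, arc cost, edge id) moves of the closure-expanded graph."""
    moves: List[Tuple[str, int, Optional[str]]] = [
        (v, 0, None) for v in _containment_moves(graph, node_id)
    ]
    moves.extend((v, 1, eid) for v, eid in _arc_moves(graph, node_id, direction))
    return moves


def _enumerate_paths(
    graph: PathwayGraph,
    start: str,
    direction: Direction,
    cost_cap: float,
    is_goal,
    forbidden: Set[str],
    max_paths: int,
    collected: List[Tuple[Tuple[str, ...], Tuple[str, ...]]],
    lower_bound: Optional[Dict[str, int]] = None,
) -> None:
    """DFS over the closure-expanded move relation collecting simple paths.

    A path is recorded when ``is_goal`` accepts the current node and at
    least one real arc has been traversed.  Goal nodes and ``forbidden``
    nodes are never expanded through.  ``lower_bound`` (remaining arcs to
    any goal) prunes branches that cannot finish within ``cost_cap``.
    """
    path: List[str] = [start]
    edge_trail: List[str] = []
    on_path: Set[str] = {start}

    def bound_ok(node: str, cost: int) -> bool:
        if lower_bound is None:
            return cost <= cost_cap
        rem = lower_bound.get(node)
        return rem is not None and cost + rem <= cost_cap

    def dfs(node: str, cost: int) -> None:
        if is_goal(node) and cost >= 1:
            if len(collected) >= max_paths:
                raise PathExplosionError(
                    f"path enumeration exceeded cap of {max_paths} paths"
                )
            collected.append((tuple(path), tuple(edge_trail)))
            return  # goals are endpoints, never intermediates
        if node != start and node in forbidden:
            return
        for nxt, step, eid in _expanded_moves(graph, node, direction):
            if nxt in on_path:
                continue
            if not bound_ok(nxt, cost + step):
                continue
            on_path.add(nxt)
            path.append(nxt)
            if eid is not None:
                edge_trail.append(eid)
            dfs(nxt, cost + step)
            if eid is not None:
                edge_trail.pop()
            path.pop()
            on_path.discard(nxt)

    dfs(start, 0)


def paths_between(
    graph: PathwayGraph,
    seeds: Iterable[str],
    limit_k: int,
    direction: Direction = Direction.DOWNSTREAM,
    max_paths: int = MAX_PATHS_DEFAULT,
) -> QueryResult:
    """All simple paths of <= ``limit_k`` arcs linking two distinct seeds.

    No other seed may appear as an intermediate: a path through a third
    seed is just the concatenation of two shorter links.  Seeds are always
    part of ``result_nodes`` even when no link is found.
    """
    seeds = _check_seeds(graph, seeds, minimum=2)
    if limit_k < 1:
        raise QueryError("paths_between requires limit_k >= 1")
    seed_set = set(seeds)
    collected: List[Tuple[Tuple[str, ...], Tuple[str, ...]]] = []
    for s in seeds:
        _enumerate_paths(
            graph,
            s,
            direction,
            cost_cap=limit_k,
            is_goal=lambda n, s=s: n in seed_set and n != s,
            forbidden=seed_set,
            max_paths=max_paths,
            collected=collected,
        )
    return _paths_result(seed_set, collected)


def _paths_result(
    seed_set: Set[str],
    collected: List[Tuple[Tuple[str, ...], Tuple[str, ...]]],
    distances: Optional[Dict[str, int]] = None,
) -> QueryResult:
    result_nodes: Set[str] = set(seed_set)
    result_edges: Set[str] = set()
    unique_paths: Dict[Tuple[str, ...], None] = {}
    for node_seq, edge_seq in collected:
        unique_paths.setdefault(node_seq)
        result_nodes.update(node_seq)
        result_edges.update(edge_seq)
    return QueryResult(
        seed_nodes=set(seed_set),
        result_nodes=result_nodes,
        result_edges=result_edges,
        distances=distances or {},
        paths=sorted(unique_paths),
    )


def paths_from_to(
    graph: PathwayGraph,
    sources: Iterable[str],
    targets: Iterable[str],
    limit_k: Optional[int] = None,
    additional_d: int = 0,
    direction: Direction = Direction.DOWNSTREAM,
    max_paths: int = MAX_PATHS_DEFAULT,
) -> QueryResult:
    """Near-shortest simple paths from a source set to a target set.

    For each ordered pair ``(s, t)`` with shortest compound length ``L``,
    every simple path of length ``l`` with ``L <= l <= min(L +
    additional_d, limit_k)`` is returned; the relaxation applies per pair,
    not to the global minimum.
    """
    sources = _check_seeds(graph, sources)
    targets = _check_seeds(graph, targets)
    if additional_d < 0:
        raise QueryError("additional_d must be >= 0")
    k_cap = INF if limit_k is None else limit_k
    seed_set = set(sources) | set(targets)
    collected: List[Tuple[Tuple[str, ...], Tuple[str, ...]]] = []
    distances: Dict[str, int] = {}
    for t in dict.fromkeys(targets):
        # Remaining-arcs lower bound: compound distance to t against the flow.
        to_t = compound_bfs(graph, [t], _opposite(direction))
        for s in dict.fromkeys(sources):
            if s == t:
                continue
            shortest = to_t.get(s)
            if shortest is None:
                continue
            cap = min(shortest + additional_d, k_cap)
            if shortest > cap:
                continue
            distances[t] = min(shortest, distances.get(t, shortest))
            _enumerate_paths(
                graph,
                s,
                direction,
                cost_cap=cap,
                is_goal=lambda n, t=t: n == t,
                forbidden={t},
                max_paths=max_paths,
                collected=collected,
                lower_bound=to_t,
            )
    return _paths_result(seed_set, collected, distances)


def shortest_path(
    graph: PathwayGraph,
    source: str,
    target: str,
    direction: Direction = Direction.DOWNSTREAM,
    max_paths: int = MAX_PATHS_DEFAULT,
) -> QueryResult:
    """One shortest compound path; ties broken by smallest node-id sequence.

    Returns an empty result (no error) when the target is unreachable.
    """
    if source == target:
        raise QueryError("source and target must differ")
    _check_seeds(graph, [source, target])
    reach = compound_bfs(graph, [source], direction)
    if target not in reach:
        return QueryResult(seed_nodes={source, target})
    full = paths_from_to(
        graph, [source], [target], additional_d=0, direction=direction, max_paths=max_paths
    )
    best = min(full.paths)
    edge_ids = _edges_along(graph, best, direction)
    return QueryResult(
        seed_nodes={source, target},
        result_nodes=set(best),
        result_edges=edge_ids,
        distances={target: reach[target]},
        paths=[best],
    )


def _edges_along(
    graph: PathwayGraph, path: Sequence[str], direction: Direction
) -> Set[str]:
    """Edge ids realizing consecutive arc steps of a node sequence."""
    out: Set[str] = set()
    for u, v in zip(path, path[1:]):
        node_u = graph.nodes[u]
        if node_u.parent == v or graph.nodes[v].parent == u:
            continue  # containment hop
        for nbr, eid in _arc_moves(graph, u, direction):
            if nbr == v:
                out.add(eid)
                break
    return out
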