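"""Node centrality measures and label annotation.

Degree, closeness and betweenness are computed on the undirected view of
the arc structure; PageRank respects arc direction.  Compound container
nodes take part only when they carry arcs of their own — pure containers
are excluded from the distance graph and score 0, because containment is
not adjacency.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Set

from .core import Node, PathwayGraph

__all__ = [
    "Measure",
    "CentralityReport",
    "MetricsError",
    "degree_centrality",
    "closeness_centrality",
    "betweenness_centrality",
    "pagerank",
    "annotate_with_centrality",
    "compute",
]


class MetricsError(ValueError):
    pass


class Measure(str, Enum):
    DEGREE = "degree"
    CLOSENESS = "closeness"
    BETWEENNESS = "betweenness"
    PAGERANK = "pagerank"


@dataclass
class CentralityReport:
    measure: Measure
    raw: Dict[str, float]
    normalized: Dict[str, float]


def _participants(graph: PathwayGraph) -> List[str]:
    """Nodes of the distance graph: everything except arc-less containers."""
    out = []
    for nid, node in graph.nodes.items():
        if node.node_class.compound_capable and graph.degree(nid) == 0:
            continue
        out.append(nid)
    return out


def _undirected_adjacency(graph: PathwayGraph, nodes: List[str]) -> Dict[str, Set[str]]:
    """Simple undirected adjacency; parallel arcs collapse, self-loops drop."""
    keep = set(nodes)
    adj: Dict[str, Set[str]] = {nid: set() for nid in nodes}
    for edge in graph.edges.values():
        if edge.source == edge.target:
            continue
        if edge.source in keep and edge.target in keep:
            adj[edge.source].add(edge.target)
            adj[edge.target].add(edge.source)
    return adj


def _zero_report(graph: PathwayGraph, measure: Measure) -> Dict[str, float]:
    return {nid: 0.0 for nid in graph.nodes}


def degree_centrality(graph: PathwayGraph) -> CentralityReport:
    """Incident edge endpoints per node (self-loop counts 2), max-normalized."""
    if not graph.nodes:
        raise MetricsError("degree centrality requires at least 1 node")
    raw = {nid: float(graph.degree(nid)) for nid in graph.nodes}
    top = max(raw.values())
    normalized = {nid: (v / top if top > 0 else 0.0) for nid, v in raw.items()}
    return CentralityReport(Measure.DEGREE, raw, normalized)


def closeness_centrality(graph: PathwayGraph) -> CentralityReport:
    """Harmonic closeness on the undirected view.

    raw(v) = sum over u != v of 1/dist(u, v), with unreachable pairs
    contributing 0 — finite even on the disconnected maps that are common
    in pathway data.  Normalized by (n - 1) over participating nodes.
    """
    if len(graph.nodes) < 2:
        raise MetricsError("closeness centrality requires at least 2 nodes")
    nodes = _participants(graph)
    adj = _undirected_adjacency(graph, nodes)
    raw = _zero_report(graph, Measure.CLOSENESS)
    n = len(nodes)
    for v in nodes:
        total = 0.0
        dist = _bfs_distances(adj, v)
        for u, d in dist.items():
            if u != v and d > 0:
                total += 1.0 / d
        raw[v] = total
    denom = max(n - 1, 1)
    normalized = {nid: v / denom for nid, v in raw.items()}
    return CentralityReport(Measure.CLOSENESS, raw, normalized)


def _bfs_distances(adj: Dict[str, Set[str]], source: str) -> Dict[str, int]:
    dist = {source: 0}
    dq = deque([source])
    while dq:
        u = dq.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                dq.append(w)
    return dist


def betweenness_centrality(graph: PathwayGraph) -> CentralityReport:
    """Brandes' algorithm on the undirected view, endpoints excluded.

    Normalization divides by (n - 1)(n - 2) / 2, the number of unordered
    pairs a node could possibly sit between.
    """
    if len(graph.nodes) < 3:
        raise MetricsError("betweenness centrality requires at least 3 nodes")
    nodes = _participants(graph)
    adj = _undirected_adjacency(graph, nodes)
    raw = _zero_report(graph, Measure.BETWEENNESS)

    for s in nodes:
        # single-source shortest-path DAG with path counts
        stack: List[str] = []
        preds: Dict[str, List[str]] = {v: [] for v in nodes}
        sigma: Dict[str, float] = {v: 0.0 for v in nodes}
        sigma[s] = 1.0
        dist: Dict[str, int] = {s: 0}
        dq = deque([s])
        while dq:
            u = dq.popleft()
            stack.append(u)
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    dq.append(w)
                if dist[w] == dist[u] + 1:
                    sigma[w] += sigma[u]
                    preds[w].append(u)
        delta: Dict[str, float] = {v: 0.0 for v in nodes}
        while stack:
            w = stack.pop()
            for u in preds[w]:
                delta[u] += sigma[u] / sigma[w] * (1.0 + delta[w])
            if w != s:
                raw[w] += delta[w]

    n = len(nodes)
    for nid in raw:
        raw[nid] /= 2.0  # each unordered pair visited from both endpoints
    denom = (n - 1) * (n - 2) / 2.0
    normalized = {nid: (v / denom if denom > 0 else 0.0) for nid, v in raw.items()}
    return CentralityReport(Measure.BETWEENNESS, raw, normalized)


def pagerank(
    graph: PathwayGraph,
    damping: float = 0.85,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CentralityReport:
    """Power iteration on the directed multigraph.

    Parallel arcs add weight; dangling nodes redistribute their mass
    uniformly.  Iteration stops when the L1 change drops below ``tol``.
    """
    if not graph.nodes:
        raise MetricsError("pagerank requires at least 1 node")
    nodes = _participants(graph)
    n = len(nodes)
    raw = _zero_report(graph, Measure.PAGERANK)
    if n == 0:
        return CentralityReport(Measure.PAGERANK, raw, dict(raw))

    keep = set(nodes)
    out_weights: Dict[str, Dict[str, float]] = {v: {} for v in nodes}
    for edge in graph.edges.values():
        if edge.source in keep and edge.target in keep:
            tbl = out_weights[edge.source]
            tbl[edge.target] = tbl.get(edge.target, 0.0) + 1.0

    rank = {v: 1.0 / n for v in nodes}
    for _ in range(max_iter):
        dangling = sum(rank[v] for v in nodes if not out_weights[v])
        nxt = {v: (1.0 - damping) / n + damping * dangling / n for v in nodes}
        for v in nodes:
            tbl = out_weights[v]
            if not tbl:
                continue
            total = sum(tbl.values())
            share = damping * rank[v]
            for w, wt in tbl.items():
                nxt[w] += share * wt / total
        change = sum(abs(nxt[v] - rank[v]) for v in nodes)
        rank = nxt
        if change < tol:
            break

    raw.update(rank)
    top = max(rank.values())
    normalized = {nid: (v / top if top > 0 else 0.0) for nid, v in raw.items()}
    return CentralityReport(Measure.PAGERANK, raw, normalized)


_MEASURE_FNS = {
    Measure.DEGREE: degree_centrality,
    Measure.CLOSENESS: closeness_centrality,
    Measure.BETWEENNESS: betweenness_centrality,
    Measure.PAGERANK: pagerank,
}


def compute(graph: PathwayGraph, measure: Measure) -> CentralityReport:
    """Dispatch a measure by name."""
    return _MEASURE_FNS[Measure(measure)](graph)


def annotate_with_centrality(
    graph: PathwayGraph, report: CentralityReport, decimals: int = 2
) -> PathwayGraph:
    """Append normalized scores to node labels and set highlight thickness.

    Labels become ``"<label> (<score>)"`` with the score rounded to
    ``decimals`` places; the normalized value is also stored as the node's
    highlight thickness for the renderer.
    """
    if set(report.normalized) != set(graph.nodes):
        raise MetricsError("centrality report does not cover the graph's nodes")
    for nid, node in graph.nodes.items():
        score = report.normalized[nid]
        suffix = f"({score:.{decimals}f})"
        node.label = f"{node.label} {suffix}".strip()
        node.highlight_thickness = score
    return graph
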