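"""Compound-aware force-directed layout.

A two-stage scheme: a seeded draft placement (random scatter plus one
BFS-tree pass that rings unplaced neighbors around placed ones) followed
by an iterative spring-embedder refinement.  Compound nodes never move on
their own — their rectangles are recomputed from their children every
iteration (children bounding box grown by ``compound_padding``), which
makes the containment invariant hold by construction.

Forces act on leaf nodes only:

* a spring per arc pulling its endpoints toward ``ideal_edge_length``
  (arcs incident to a compound move the compound's whole leaf set),
* short-range rectangle repulsion between leaf pairs and between sibling
  compound rectangles (active only below a small separation cutoff, so a
  lone connected pair settles exactly at the ideal length),
* weak gravity toward the parent's center (component centroid for roots).

Displacements are capped by a linearly decaying cooling schedule starting
at the ideal edge length and ending at 1 px.
"""

from __future__ import annotations

import math
import random
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .core import NodeGeometry, PathwayGraph

__all__ = ["LayoutOptions", "LayoutError", "draft_placement", "refine", "layout"]

DEFAULT_NODE_SIZE = 40.0

GeometryMap = Dict[str, NodeGeometry]


class LayoutError(RuntimeError):
    """Numerical failure (NaN/overflow) during refinement."""


class LayoutOptions(BaseModel):
    """Layout tuning knobs; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    ideal_edge_length: float = Field(default=50.0, gt=0)
    randomize: bool = True
    max_iterations: int = Field(default=2500, ge=1)
    convergence_threshold: float = Field(default=1.0, ge=0)
    gravity_strength: float = Field(default=0.25, ge=0)
    compound_padding: float = Field(default=10.0, ge=0)
    seed: int = 0


# ---------------------------------------------------------------------------
# structural helpers
# ---------------------------------------------------------------------------


def _leaves(graph: PathwayGraph) -> List[str]:
    return [nid for nid in graph.nodes_in_document_order() if not graph._children[nid]]


def _leaf_set(graph: PathwayGraph, nid: str) -> List[str]:
    """The leaves a node stands on: itself if childless, else its leaf descendants."""
    if not graph._children[nid]:
        return [nid]
    return [d for d in graph.descendants(nid) if not graph._children[d]]


def _node_size(graph: PathwayGraph, nid: str) -> Tuple[float, float]:
    g = graph.nodes[nid].geometry
    if g is not None:
        return g.w, g.h
    return DEFAULT_NODE_SIZE, DEFAULT_NODE_SIZE


def _compound_rects(
    graph: PathwayGraph,
    pos: Dict[str, Tuple[float, float]],
    size: Dict[str, Tuple[float, float]],
    padding: float,
) -> Dict[str, Tuple[float, float, float, float]]:
    """(left, top, right, bottom) for every node; compounds from children."""
    rects: Dict[str, Tuple[float, float, float, float]] = {}
    order = graph.nodes_in_document_order()
    for nid in reversed(order):  # children always handled before their parent
        kids = graph._children[nid]
        if not kids:
            (x, y), (w, h) = pos[nid], size[nid]
            rects[nid] = (x - w / 2, y - h / 2, x + w / 2, y + h / 2)
        else:
            ls = [rects[k] for k in kids]
            rects[nid] = (
                min(r[0] for r in ls) - padding,
                min(r[1] for r in ls) - padding,
                max(r[2] for r in ls) + padding,
                max(r[3] for r in ls) + padding,
            )
    return rects


def _is_ancestor(graph: PathwayGraph, a: str, b: str) -> bool:
    return a in graph.ancestors(b)


# ---------------------------------------------------------------------------
# draft placement
# ---------------------------------------------------------------------------


def draft_placement(graph: PathwayGraph, options: Optional[LayoutOptions] = None) -> GeometryMap:
    """Quick initial placement; deterministic for a given seed.

    With ``randomize=False``, nodes that already carry coordinates keep
    them and only coordinate-less nodes are placed.
    """
    options = options or LayoutOptions()
    if not graph.nodes:
        return {}
    rng = random.Random(options.seed)
    leaves = _leaves(graph)
    side = options.ideal_edge_length * max(1.0, math.sqrt(len(leaves))) * 1.5

    pos: Dict[str, Tuple[float, float]] = {}
    size: Dict[str, Tuple[float, float]] = {nid: _node_size(graph, nid) for nid in leaves}
    fixed: Set[str] = set()
    for nid in leaves:
        node = graph.nodes[nid]
        if not options.randomize and node.geometry is not None:
            pos[nid] = (node.geometry.x, node.geometry.y)
            fixed.add(nid)
        else:
            pos[nid] = (rng.uniform(0, side), rng.uniform(0, side))

    # One BFS-tree pass over the arc structure: ring newly discovered
    # (non-fixed) leaves around the leaf that discovered them.
    undirected: Dict[str, List[str]] = {nid: [] for nid in leaves}
    leaf_of = {nid: _leaf_set(graph, nid) for nid in graph.nodes}
    for edge in graph.edges.values():
        for u in leaf_of[edge.source]:
            for v in leaf_of[edge.target]:
                if u != v:
                    undirected[u].append(v)
                    undirected[v].append(u)
    golden = math.pi * (3.0 - math.sqrt(5.0))
    seen: Set[str] = set()
    for start in leaves:
        if start in seen:
            continue
        queue = [start]
        seen.add(start)
        while queue:
            u = queue.pop(0)
            fan = 0
            for v in undirected[u]:
                if v in seen:
                    continue
                seen.add(v)
                if v not in fixed:
                    angle = golden * (fan + 1) + 0.61 * hash_angle(u)
                    r = options.ideal_edge_length
                    pos[v] = (pos[u][0] + r * math.cos(angle), pos[u][1] + r * math.sin(angle))
                fan += 1
                queue.append(v)

    return _geometry_from_leaves(graph, pos, size, options.compound_padding)


def hash_angle(nid: str) -> float:
    """Deterministic per-id angle jitter (independent of PYTHONHASHSEED)."""
    acc = 0
    for ch in nid:
        acc = (acc * 131 + ord(ch)) % 997
    return acc / 997.0 * 2 * math.pi


def _geometry_from_leaves(
    graph: PathwayGraph,
    pos: Dict[str, Tuple[float, float]],
    size: Dict[str, Tuple[float, float]],
    padding: float,
) -> GeometryMap:
    rects = _compound_rects(graph, pos, size, padding)
    out: GeometryMap = {}
    for nid in graph.nodes:
        l, t, r, b = (float(v) for v in rects[nid])
        if r - l <= 0 or b - t <= 0:  # childless compound fallback
            w, h = DEFAULT_NODE_SIZE, DEFAULT_NODE_SIZE
            cx, cy = (l + r) / 2, (t + b) / 2
            out[nid] = NodeGeometry(cx, cy, w, h)
        else:
            out[nid] = NodeGeometry((l + r) / 2, (t + b) / 2, r - l, b - t)
    return out


# ---------------------------------------------------------------------------
# refinement
# ---------------------------------------------------------------------------


def refine(
    graph: PathwayGraph, geometry: GeometryMap, options: Optional[LayoutOptions] = None
) -> GeometryMap:
    """Spring-embedder polish of a draft placement."""
    options = options or LayoutOptions()
    if not graph.nodes:
        return {}
    leaves = _leaves(graph)
    index = {nid: i for i, nid in enumerate(leaves)}
    n = len(leaves)
    P = np.array([[geometry[nid].x, geometry[nid].y] for nid in leaves], dtype=float)
    S = np.array([[geometry[nid].w, geometry[nid].h] for nid in leaves], dtype=float)
    half = S / 2.0

    # Springs: per arc, the two endpoint leaf groups.  The common
    # leaf-to-leaf case is vectorized; arcs touching compounds keep a
    # (rarely long) per-arc path.
    leaf_springs: List[Tuple[int, int]] = []
    group_springs: List[Tuple[np.ndarray, np.ndarray]] = []
    for edge in graph.edges.values():
        u, v = edge.source, edge.target
        if u == v or _is_ancestor(graph, u, v) or _is_ancestor(graph, v, u):
            continue
        if u in index and v in index:
            leaf_springs.append((index[u], index[v]))
        else:
            group_springs.append(
                (
                    np.array([index[x] for x in _leaf_set(graph, u)], dtype=int),
                    np.array([index[x] for x in _leaf_set(graph, v)], dtype=int),
                )
            )
    spring_src = np.array([p[0] for p in leaf_springs], dtype=int)
    spring_dst = np.array([p[1] for p in leaf_springs], dtype=int)

    # Sibling compound pairs for rectangle repulsion.
    compound_pairs: List[Tuple[np.ndarray, np.ndarray]] = []
    by_parent: Dict[Optional[str], List[str]] = {}
    for nid, node in graph.nodes.items():
        by_parent.setdefault(node.parent, []).append(nid)
    for siblings in by_parent.values():
        for i, a in enumerate(siblings):
            for b in siblings[i + 1 :]:
                if graph._children[a] or graph._children[b]:
                    compound_pairs.append(
                        (
                            np.array([index[x] for x in _leaf_set(graph, a)], dtype=int),
                            np.array([index[x] for x in _leaf_set(graph, b)], dtype=int),
                        )
                    )

    parent_of = {nid: graph.nodes[nid].parent for nid in leaves}
    parent_leaves = {
        p: np.array([index[x] for x in _leaf_set(graph, p)], dtype=int)
        for p in {parent for parent in parent_of.values() if parent is not None}
    }
    jitter = np.array(
        [[math.cos(hash_angle(nid)), math.sin(hash_angle(nid))] for nid in leaves]
    )

    ideal = options.ideal_edge_length
    cutoff = 5.0  # separation below which repulsion switches on
    # half-diagonal footprint: orientation-free, so no equilibrium can
    # retain a rectangle overlap for default-size nodes
    radius = np.hypot(S[:, 0], S[:, 1]) / 2.0
    pos_d: Dict[str, Tuple[float, float]] = {}
    size_d = {nid: (float(S[i, 0]), float(S[i, 1])) for nid, i in index.items()}

    for it in range(options.max_iterations):
        disp = np.zeros_like(P)

        # --- springs -------------------------------------------------
        if len(spring_src):
            delta = P[spring_dst] - P[spring_src]
            d = np.hypot(delta[:, 0], delta[:, 1])
            degenerate = d < 1e-9
            if degenerate.any():
                delta[degenerate] = jitter[spring_src[degenerate]]
                d = np.hypot(delta[:, 0], delta[:, 1])
            f = (0.35 * (d - ideal) / d)[:, None] * delta
            np.add.at(disp, spring_src, f)
            np.add.at(disp, spring_dst, -f)
        for gu, gv in group_springs:
            cu = P[gu].mean(axis=0)
            cv = P[gv].mean(axis=0)
            delta = cv - cu
            d = float(np.hypot(*delta))
            if d < 1e-9:
                delta = jitter[gu[0]]
                d = 1.0
            f = 0.35 * (d - ideal) / d
            disp[gu] += f * delta / len(gu)
            disp[gv] -= f * delta / len(gv)

        # --- leaf-leaf repulsion (vectorized, short range) -----------
        if n > 1:
            dx = P[:, 0][:, None] - P[:, 0][None, :]
            dy = P[:, 1][:, None] - P[:, 1][None, :]
            dist = np.hypot(dx, dy)
            gap = dist - (radius[:, None] + radius[None, :])
            active = gap < cutoff
            np.fill_diagonal(active, False)
            if active.any():
                push = 0.5 * (cutoff - gap)
                with np.errstate(invalid="ignore", divide="ignore"):
                    ux = np.where(dist > 1e-9, dx / dist, 0.0)
                    uy = np.where(dist > 1e-9, dy / dist, 0.0)
                coincident = (dist <= 1e-9) & active
                if coincident.any():
                    ux = np.where(coincident, jitter[:, 0][:, None], ux)
                    uy = np.where(coincident, jitter[:, 1][:, None], uy)
                fx = np.where(active, push * ux, 0.0)
                fy = np.where(active, push * uy, 0.0)
                disp[:, 0] += fx.sum(axis=1)
                disp[:, 1] += fy.sum(axis=1)
            # rectangle-overlap penalty: rotates configurations out of the
            # diagonal orientations the circle model cannot see
            ox = (half[:, 0][:, None] + half[:, 0][None, :]) - np.abs(dx)
            oy = (half[:, 1][:, None] + half[:, 1][None, :]) - np.abs(dy)
            rect_overlap = (ox > 0) & (oy > 0)
            np.fill_diagonal(rect_overlap, False)
            if rect_overlap.any():
                # separate along the axis of least overlap; the tangential
                # component lets configurations rotate free of the overlap
                along_x = ox <= oy
                sx = np.where(dx != 0, np.sign(dx), jitter[:, 0][:, None])
                sy = np.where(dy != 0, np.sign(dy), jitter[:, 1][:, None])
                push = 0.4 * np.minimum(ox, oy)
                fx = np.where(rect_overlap & along_x, push * sx, 0.0)
                fy = np.where(rect_overlap & ~along_x, push * sy, 0.0)
                disp[:, 0] += fx.sum(axis=1)
                disp[:, 1] += fy.sum(axis=1)

        # --- compound rectangle repulsion ----------------------------
        if compound_pairs:
            for ga, gb in compound_pairs:
                ra = _group_rect(P, half, ga)
                rb = _group_rect(P, half, gb)
                gapx = max(rb[0] - ra[2], ra[0] - rb[2])
                gapy = max(rb[1] - ra[3], ra[1] - rb[3])
                gap = max(gapx, gapy)
                if gap >= cutoff + options.compound_padding:
                    continue
                ca = np.array([(ra[0] + ra[2]) / 2, (ra[1] + ra[3]) / 2])
                cb = np.array([(rb[0] + rb[2]) / 2, (rb[1] + rb[3]) / 2])
                delta = cb - ca
                d = float(np.hypot(*delta))
                unit = delta / d if d > 1e-9 else jitter[ga[0]]
                mag = 0.5 * (cutoff + options.compound_padding - gap)
                disp[ga] -= mag * unit / len(ga)
                disp[gb] += mag * unit / len(gb)

        # --- gravity -------------------------------------------------
        centroid = P.mean(axis=0)
        for i, nid in enumerate(leaves):
            parent = parent_of[nid]
            if parent is None:
                target = centroid
                g = 0.002 * options.gravity_strength
            else:
                pr = _group_rect(P, half, parent_leaves[parent])
                target = np.array([(pr[0] + pr[2]) / 2, (pr[1] + pr[3]) / 2])
                g = 0.02 * options.gravity_strength
            disp[i] += g * (target - P[i])

        # --- cooling + integration -----------------------------------
        cap = max(1.0, ideal * (1.0 - it / options.max_iterations))
        norms = np.hypot(disp[:, 0], disp[:, 1])
        scale = np.where(norms > cap, cap / np.maximum(norms, 1e-12), 1.0)
        step = disp * scale[:, None]
        P += step
        if not np.isfinite(P).all():
            raise LayoutError(f"non-finite positions at iteration {it}")
        if float(np.abs(step).sum()) < options.convergence_threshold:
            break

    for i, nid in enumerate(leaves):
        pos_d[nid] = (float(P[i, 0]), float(P[i, 1]))
    _resolve_sibling_overlaps(graph, pos_d, size_d, jitter={nid: jitter[i] for nid, i in index.items()})
    _pack_components(graph, pos_d, size_d, options)
    return _geometry_from_leaves(graph, pos_d, size_d, options.compound_padding)


def _group_rect(P: np.ndarray, half: np.ndarray, idx: np.ndarray) -> Tuple[float, float, float, float]:
    return (
        float((P[idx, 0] - half[idx, 0]).min()),
        float((P[idx, 1] - half[idx, 1]).min()),
        float((P[idx, 0] + half[idx, 0]).max()),
        float((P[idx, 1] + half[idx, 1]).max()),
    )


def _resolve_sibling_overlaps(
    graph: PathwayGraph,
    pos: Dict[str, Tuple[float, float]],
    size: Dict[str, Tuple[float, float]],
    jitter: Dict[str, np.ndarray],
) -> None:
    """Deterministically push apart overlapping same-parent leaf pairs."""
    by_parent: Dict[Optional[str], List[str]] = {}
    for nid in pos:
        by_parent.setdefault(graph.nodes[nid].parent, []).append(nid)
    for siblings in by_parent.values():
        for _ in range(400):
            moved = False
            for i, a in enumerate(siblings):
                for b in siblings[i + 1 :]:
                    ax, ay = pos[a]
                    bx, by = pos[b]
                    ox = (size[a][0] + size[b][0]) / 2 - abs(ax - bx)
                    oy = (size[a][1] + size[b][1]) / 2 - abs(ay - by)
                    if ox <= 0 or oy <= 0:
                        continue
                    shift = (min(ox, oy) / 2.0) + 0.5
                    if ox <= oy:  # separate along the least-overlap axis
                        s = 1.0 if bx >= ax else -1.0
                        if abs(bx - ax) < 1e-9:
                            s = 1.0 if jitter[a][0] >= 0 else -1.0
                        pos[a] = (ax - s * shift, ay)
                        pos[b] = (bx + s * shift, by)
                    else:
                        s = 1.0 if by >= ay else -1.0
                        if abs(by - ay) < 1e-9:
                            s = 1.0 if jitter[a][1] >= 0 else -1.0
                        pos[a] = (ax, ay - s * shift)
                        pos[b] = (bx, by + s * shift)
                    moved = True
            if not moved:
                break


def _pack_components(
    graph: PathwayGraph,
    pos: Dict[str, Tuple[float, float]],
    size: Dict[str, Tuple[float, float]],
    options: LayoutOptions,
) -> None:
    """Place disconnected components side by side so they never overlap."""
    # Union containment trees and arc connectivity over root representatives.
    root_of = {nid: (graph.ancestors(nid)[-1] if graph.nodes[nid].parent else nid)
               for nid in graph.nodes}
    parent: Dict[str, str] = {r: r for r in set(root_of.values())}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for edge in graph.edges.values():
        a, b = find(root_of[edge.source]), find(root_of[edge.target])
        if a != b:
            parent[a] = b

    groups: Dict[str, List[str]] = {}
    for nid in pos:  # leaves only
        groups.setdefault(find(root_of[nid]), []).append(nid)
    if len(groups) <= 1:
        return
    gap = 2 * options.compound_padding + 20.0
    cursor = 0.0
    for rep in sorted(groups, key=lambda r: min(groups[r])):
        members = groups[rep]
        left = min(pos[m][0] - size[m][0] / 2 for m in members)
        top = min(pos[m][1] - size[m][1] / 2 for m in members)
        right = max(pos[m][0] + size[m][0] / 2 for m in members)
        shift_x = cursor - left
        shift_y = -top
        for m in members:
            pos[m] = (pos[m][0] + shift_x, pos[m][1] + shift_y)
        cursor += (right - left) + gap


def layout(graph: PathwayGraph, options: Optional[LayoutOptions] = None) -> GeometryMap:
    """Draft placement followed by refinement."""
    options = options or LayoutOptions()
    return refine(graph, draft_placement(graph, options), options)


def apply_geometry(graph: PathwayGraph, geometry: GeometryMap) -> PathwayGraph:
    """Write a geometry map back onto the graph's nodes."""
    for nid, geom in geometry.items():
        graph.nodes[nid].geometry = geom
    return graph
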