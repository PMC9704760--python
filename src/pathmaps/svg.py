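"""SVG construction for pathway maps.

Every node contributes exactly one shape element (``class="node-shape"``)
and every edge exactly one path element (``class="edge-path"``); labels,
markers and an optional background are separate.  Compound shapes always
precede their descendants in document order.  Edge endpoints are clipped
to the node borders so arrowheads touch the shapes.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from typing import Dict, Optional, Set, Tuple

from .core import EdgeClass, NodeGeometry, PathwayGraph
from .style import HighlightSpec, NodeStyle, StyleOptions, node_style

__all__ = ["render_svg", "RenderError"]

MARGIN = 20.0
FONT_SIZE = 11.0
CHAR_WIDTH = 0.62 * FONT_SIZE  # crude average glyph advance

#: transparent fill for containers so their contents stay visible
_CONTAINER_OPACITY = "0.35"


class RenderError(ValueError):
    pass


def render_svg(
    graph: PathwayGraph,
    highlight: Optional[HighlightSpec] = None,
    style: Optional[StyleOptions] = None,
) -> str:
    style = style or StyleOptions()
    highlight = highlight or HighlightSpec()

    for nid, node in graph.nodes.items():
        if node.geometry is None:
            raise RenderError(f"node {nid!r} has no geometry; run a layout first")

    vb = _view_box(graph, highlight, style)
    root = ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "version": "1.1",
            "width": str(style.width),
            "height": str(style.height),
            "viewBox": f"{vb[0]:.2f} {vb[1]:.2f} {vb[2]:.2f} {vb[3]:.2f}",
        },
    )
    defs = ET.SubElement(root, "defs")
    markers: Dict[Tuple[str, str], str] = {}

    if style.background is not None:
        ET.SubElement(
            root,
            "rect",
            {
                "class": "background",
                "x": f"{vb[0]:.2f}",
                "y": f"{vb[1]:.2f}",
                "width": f"{vb[2]:.2f}",
                "height": f"{vb[3]:.2f}",
                "fill": style.background,
            },
        )

    # node shapes, containers before their descendants
    for nid in graph.nodes_in_document_order():
        node = graph.nodes[nid]
        spec = node_style(node.node_class, style.scheme, style.base_color)
        attrs = _shape_attrs(spec, node.geometry)
        attrs["class"] = "node-shape"
        attrs["data-id"] = nid
        if graph._children[nid]:
            attrs["fill-opacity"] = _CONTAINER_OPACITY
        role = highlight.node_roles.get(nid)
        thickness = highlight.node_thickness.get(nid, node.highlight_thickness)
        if role is not None or thickness is not None:
            t = 0.5 if thickness is None else max(0.0, min(1.0, thickness))
            lo, hi = style.highlight_width_range
            attrs["stroke"] = style.role_color(role) if role else style.highlight_color
            attrs["stroke-width"] = f"{lo + t * (hi - lo):.2f}"
        tag = attrs.pop("_tag")
        ET.SubElement(root, tag, attrs)

    # edges
    for eid, edge in graph.edges.items():
        p1, p2 = _clip_endpoints(
            graph.nodes[edge.source].geometry, graph.nodes[edge.target].geometry
        )
        color = style.link_color if eid in highlight.edge_ids else "#555555"
        width = 2.5 if eid in highlight.edge_ids else 1.3
        attrs = {
            "class": "edge-path",
            "data-id": eid,
            "d": f"M {p1[0]:.2f} {p1[1]:.2f} L {p2[0]:.2f} {p2[1]:.2f}",
            "stroke": color,
            "stroke-width": f"{width:.2f}",
            "fill": "none",
        }
        marker = _marker_for(defs, markers, edge.edge_class, color)
        if marker is not None:
            attrs["marker-end"] = f"url(#{marker})"
        ET.SubElement(root, "path", attrs)

    # labels on top
    for nid in graph.nodes_in_document_order():
        node = graph.nodes[nid]
        if not node.label:
            continue
        g = node.geometry
        text = _truncate(node.label, g.w)
        x, y = g.x, g.y
        if graph._children[nid]:  # container labels go to the top edge
            y = g.top + FONT_SIZE
        el = ET.SubElement(
            root,
            "text",
            {
                "class": "node-label",
                "x": f"{x:.2f}",
                "y": f"{y + FONT_SIZE * 0.35:.2f}",
                "font-size": str(FONT_SIZE),
                "font-family": "Helvetica, Arial, sans-serif",
                "text-anchor": "middle",
                "fill": "#1A1A1A",
            },
        )
        el.text = text
    return ET.tostring(root, encoding="unicode")


# ---------------------------------------------------------------------------


def _view_box(
    graph: PathwayGraph, highlight: HighlightSpec, style: StyleOptions
) -> Tuple[float, float, float, float]:
    if style.result_only and (highlight.node_roles or highlight.edge_ids):
        ids: Set[str] = set(highlight.node_roles)
        for eid in highlight.edge_ids:
            edge = graph.edges.get(eid)
            if edge is not None:
                ids.update((edge.source, edge.target))
        ids &= set(graph.nodes)
    else:
        ids = set(graph.nodes)
    if not ids:
        return (0.0, 0.0, float(style.width), float(style.height))
    geoms = [graph.nodes[nid].geometry for nid in ids]
    left = min(g.left for g in geoms) - MARGIN
    top = min(g.top for g in geoms) - MARGIN
    right = max(g.right for g in geoms) + MARGIN
    bottom = max(g.bottom for g in geoms) + MARGIN
    return (left, top, right - left, bottom - top)


def _shape_attrs(spec: NodeStyle, g: NodeGeometry) -> Dict[str, str]:
    base = {
        "fill": spec.fill,
        "stroke": spec.stroke,
        "stroke-width": f"{spec.stroke_width:.2f}",
    }
    if spec.shape in ("rounded_rect", "stadium", "rect", "square"):
        rx = {"rounded_rect": min(8.0, g.h / 4), "stadium": g.h / 2}.get(spec.shape, 0.0)
        base.update(
            _tag="rect",
            x=f"{g.left:.2f}",
            y=f"{g.top:.2f}",
            width=f"{g.w:.2f}",
            height=f"{g.h:.2f}",
        )
        if rx:
            base["rx"] = f"{rx:.2f}"
        return base
    if spec.shape in ("ellipse",):
        base.update(
            _tag="ellipse",
            cx=f"{g.x:.2f}",
            cy=f"{g.y:.2f}",
            rx=f"{g.w / 2:.2f}",
            ry=f"{g.h / 2:.2f}",
        )
        return base
    if spec.shape == "circle":
        base.update(
            _tag="circle", cx=f"{g.x:.2f}", cy=f"{g.y:.2f}", r=f"{min(g.w, g.h) / 2:.2f}"
        )
        return base
    if spec.shape == "cut_rect":
        c = min(10.0, g.w / 4, g.h / 4)
        pts = [
            (g.left + c, g.top), (g.right - c, g.top), (g.right, g.top + c),
            (g.right, g.bottom - c), (g.right - c, g.bottom), (g.left + c, g.bottom),
            (g.left, g.bottom - c), (g.left, g.top + c),
        ]
    else:  # hexagon
        pts = [
            (g.left + g.w * 0.25, g.top), (g.right - g.w * 0.25, g.top),
            (g.right, g.y), (g.right - g.w * 0.25, g.bottom),
            (g.left + g.w * 0.25, g.bottom), (g.left, g.y),
        ]
    base.update(_tag="polygon", points=" ".join(f"{x:.2f},{y:.2f}" for x, y in pts))
    return base


def _clip_endpoints(
    gs: NodeGeometry, gt: NodeGeometry
) -> Tuple[Tuple[float, float], Tuple[float, float]]:
    p1 = _border_point(gs, (gt.x, gt.y))
    p2 = _border_point(gt, (gs.x, gs.y))
    return p1, p2


def _border_point(g: NodeGeometry, toward: Tuple[float, float]) -> Tuple[float, float]:
    """Intersection of the center->toward ray with the node rectangle."""
    dx, dy = toward[0] - g.x, toward[1] - g.y
    if abs(dx) < 1e-9 and abs(dy) < 1e-9:
        return (g.x, g.y)
    tx = (g.w / 2) / abs(dx) if abs(dx) > 1e-9 else math.inf
    ty = (g.h / 2) / abs(dy) if abs(dy) > 1e-9 else math.inf
    t = min(tx, ty, 1.0)
    return (g.x + dx * t, g.y + dy * t)


def _truncate(label: str, width: float) -> str:
    max_chars = max(1, int((0.9 * width) / CHAR_WIDTH))
    if len(label) <= max_chars:
        return label
    return label[: max(1, max_chars - 1)] + "…"


def _marker_for(
    defs: ET.Element,
    cache: Dict[Tuple[str, str], str],
    edge_class: EdgeClass,
    color: str,
) -> Optional[str]:
    """Arrowhead marker definition for an edge class/color combination."""
    if edge_class is EdgeClass.CONSUMPTION:
        return None
    key = (edge_class.value, color)
    if key in cache:
        return cache[key]
    mid = f"mk-{edge_class.value}-{color.lstrip('#')}"
    marker = ET.SubElement(
        defs,
        "marker",
        {
            "id": mid,
            "markerUnits": "userSpaceOnUse",
            "markerWidth": "14",
            "markerHeight": "14",
            "refX": "10",
            "refY": "5",
            "orient": "auto",
        },
    )
    if edge_class is EdgeClass.PRODUCTION or edge_class is EdgeClass.GENERIC:
        ET.SubElement(
            marker, "polygon", {"points": "0,0 10,5 0,10", "fill": color, "stroke": "none"}
        )
    elif edge_class is EdgeClass.STIMULATION:
        ET.SubElement(
            marker,
            "polygon",
            {"points": "0,0 10,5 0,10", "fill": "#FFFFFF", "stroke": color,
             "stroke-width": "1.2"},
        )
    elif edge_class is EdgeClass.CATALYSIS:
        ET.SubElement(
            marker,
            "circle",
            {"cx": "5", "cy": "5", "r": "4", "fill": "#FFFFFF", "stroke": color,
             "stroke-width": "1.2"},
        )
    elif edge_class is EdgeClass.INHIBITION:
        ET.SubElement(
            marker,
            "line",
            {"x1": "9", "y1": "0", "x2": "9", "y2": "10", "stroke": color,
             "stroke-width": "2"},
        )
    else:  # modulation: diamond
        ET.SubElement(
            marker,
            "polygon",
            {"points": "0,5 5,0 10,5 5,10", "fill": "#FFFFFF", "stroke": color,
             "stroke-width": "1.2"},
        )
    cache[key] = mid
    return mid
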