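"""Elements-JSON dialect: the interchange format of the service.

A document is either a plain list of elements or an object with
``nodes`` and ``edges`` lists.  Node elements look like::

    {"data": {"id": "A", "label": "...", "class": "...", "parent": "...",
              "w": 40, "h": 40},
     "position": {"x": 10, "y": 20}}

and edge elements like ``{"data": {"id": "e0", "source": "A",
"target": "B", "class": "production"}}``.  Edge ids are optional and
auto-generated deterministically ("e0", "e1", ... in input order).
"""

from __future__ import annotations

import json
from typing import Any, Dict, List

from ..core import Edge, EdgeClass, Node, NodeClass, NodeGeometry, PathwayGraph
from . import ParseError, ParseReport, SourceFormat
from ._xml import add_nodes_with_parents

DEFAULT_NODE_SIZE = 40.0


def read_json(text: str) -> ParseReport:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"malformed JSON: {exc}") from exc

    if isinstance(doc, dict):
        elements = list(doc.get("nodes", [])) + list(doc.get("edges", []))
    elif isinstance(doc, list):
        elements = doc
    else:
        raise ParseError("elements JSON must be a list or a {nodes, edges} object")

    warnings: List[str] = []
    nodes: List[Node] = []
    edges: List[Edge] = []
    auto_edge = 0

    for i, element in enumerate(elements):
        if not isinstance(element, dict) or not isinstance(element.get("data"), dict):
            raise ParseError(f"element #{i} lacks a data object")
        data = element["data"]
        if "source" in data or "target" in data:
            if "source" not in data or "target" not in data:
                raise ParseError(f"element #{i}: edge with missing endpoints")
            eid = data.get("id")
            if eid is None:
                eid = f"e{auto_edge}"
                auto_edge += 1
            edge_class = EdgeClass.GENERIC
            if data.get("class"):
                try:
                    edge_class = EdgeClass(data["class"])
                except ValueError:
                    warnings.append(
                        f"unknown edge class {data['class']!r}; using generic"
                    )
            edges.append(Edge(id=str(eid), source=str(data["source"]),
                              target=str(data["target"]), edge_class=edge_class))
        else:
            nid = data.get("id")
            if nid is None:
                raise ParseError(f"element #{i}: node without id")
            node_class = NodeClass.GENERIC
            if data.get("class"):
                try:
                    node_class = NodeClass(data["class"])
                except ValueError:
                    warnings.append(
                        f"unknown node class {data['class']!r} on {nid!r}; "
                        "using generic"
                    )
            geometry = None
            position = element.get("position")
            if isinstance(position, dict):
                try:
                    geometry = NodeGeometry(
                        float(position["x"]),
                        float(position["y"]),
                        float(data.get("w", DEFAULT_NODE_SIZE)),
                        float(data.get("h", DEFAULT_NODE_SIZE)),
                    )
                except (KeyError, TypeError, ValueError) as exc:
                    raise ParseError(f"node {nid!r}: bad position") from exc
            parent = data.get("parent")
            nodes.append(
                Node(id=str(nid), label=str(data.get("label", "")),
                     node_class=node_class,
                     parent=str(parent) if parent is not None else None,
                     geometry=geometry)
            )

    graph = PathwayGraph()
    add_nodes_with_parents(graph, nodes)
    for edge in edges:
        graph.add_edge(edge)
    return ParseReport(graph=graph, warnings=warnings, source_format=SourceFormat.JSON)


def write_elements_json(graph: PathwayGraph, indent: int = 0) -> str:
    """Serialize so that ``read_json`` reproduces the graph exactly."""
    elements: List[Dict[str, Any]] = []
    # insertion order is safe: a parent is always inserted before its children
    for node in graph.nodes.values():
        data: Dict[str, Any] = {"id": node.id, "class": node.node_class.value}
        if node.label:
            data["label"] = node.label
        if node.parent is not None:
            data["parent"] = node.parent
        element: Dict[str, Any] = {"data": data}
        if node.geometry is not None:
            data["w"] = node.geometry.w
            data["h"] = node.geometry.h
            element["position"] = {"x": node.geometry.x, "y": node.geometry.y}
        elements.append(element)
    for edge in graph.edges.values():
        elements.append(
            {
                "data": {
                    "id": edge.id,
                    "source": edge.source,
                    "target": edge.target,
                    "class": edge.edge_class.value,
                }
            }
        )
    return json.dumps(elements, indent=indent or None)


def write_layout_json(graph: PathwayGraph) -> str:
    """Key-sorted ``{node-id: {x, y, w, h}}`` map of center coordinates."""
    out: Dict[str, Dict[str, float]] = {}
    for nid, node in graph.nodes.items():
        if node.geometry is None:
            raise ValueError(f"node {nid!r} has no geometry; run a layout first")
        g = node.geometry
        out[nid] = {"x": g.x, "y": g.y, "w": g.w, "h": g.h}
    return json.dumps(out, sort_keys=True)
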