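"""GraphML reader with nested-graph (compound) support.

A ``<graph>`` element inside a ``<node>`` declares that node's children.
Data keys named ``label``, ``class``, ``x``, ``y``, ``w`` and ``h`` are
honored when declared in the document's ``<key>`` table.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from typing import Dict, List, Optional

from ..core import Edge, EdgeClass, Node, NodeClass, NodeGeometry, PathwayGraph
from . import ParseError, ParseReport, SourceFormat
from ._xml import add_nodes_with_parents, find_child, find_children, local_name, parse_xml

#: Data key names recognized on nodes (remappable by callers if needed).
NODE_KEYS = ("label", "class", "x", "y", "w", "h")


def read_graphml(text: str) -> ParseReport:
    root = parse_xml(text)
    if local_name(root.tag) != "graphml":
        raise ParseError("not a GraphML document (expected <graphml> root)")

    # key id -> semantic name, for keys we understand
    key_names: Dict[str, str] = {}
    for key in find_children(root, "key"):
        name = key.get("attr.name")
        kid = key.get("id")
        if kid and name in NODE_KEYS + ("class",):
            key_names[kid] = name

    warnings: List[str] = []
    nodes: List[Node] = []
    edges: List[Edge] = []
    edge_counter = 0

    def data_of(element: ET.Element) -> Dict[str, str]:
        out: Dict[str, str] = {}
        for data in find_children(element, "data"):
            name = key_names.get(data.get("key", ""))
            if name is not None:
                out[name] = data.text or ""
        return out

    def walk_graph(graph_el: ET.Element, container: Optional[str]) -> None:
        nonlocal edge_counter
        for node_el in find_children(graph_el, "node"):
            nid = node_el.get("id")
            if nid is None:
                raise ParseError("GraphML node without id")
            data = data_of(node_el)
            cls_name = data.get("class")
            node_class = NodeClass.GENERIC
            if cls_name:
                try:
                    node_class = NodeClass(cls_name)
                except ValueError:
                    warnings.append(
                        f"unknown node class {cls_name!r} on {nid!r}; using generic"
                    )
            geometry = _geometry_from(data, nid)
            nodes.append(
                Node(id=nid, label=data.get("label", ""), node_class=node_class,
                     parent=container, geometry=geometry)
            )
            sub = find_child(node_el, "graph")
            if sub is not None:
                walk_graph(sub, nid)
        for edge_el in find_children(graph_el, "edge"):
            source = edge_el.get("source")
            target = edge_el.get("target")
            if source is None or target is None:
                raise ParseError("GraphML edge without source/target")
            data = data_of(edge_el)
            cls_name = data.get("class")
            edge_class = EdgeClass.GENERIC
            if cls_name:
                try:
                    edge_class = EdgeClass(cls_name)
                except ValueError:
                    warnings.append(f"unknown edge class {cls_name!r}; using generic")
            eid = edge_el.get("id") or f"e{edge_counter}"
            edge_counter += 1
            edges.append(Edge(id=eid, source=source, target=target,
                              edge_class=edge_class))

    top = find_child(root, "graph")
    if top is not None:
        walk_graph(top, None)

    graph = PathwayGraph()
    add_nodes_with_parents(graph, nodes)
    for edge in edges:
        if edge.source not in graph or edge.target not in graph:
            raise ParseError(
                f"edge {edge.id!r} references undeclared node "
                f"{edge.source!r} or {edge.target!r}"
            )
        graph.add_edge(edge)
    return ParseReport(graph=graph, warnings=warnings,
                       source_format=SourceFormat.GRAPHML)


def _geometry_from(data: Dict[str, str], nid: str) -> Optional[NodeGeometry]:
    if not all(k in data for k in ("x", "y")):
        return None
    try:
        x, y = float(data["x"]), float(data["y"])
        w = float(data.get("w", 40.0))
        h = float(data.get("h", 40.0))
    except ValueError as exc:
        raise ParseError(f"node {nid!r}: bad geometry data") from exc
    if not all(math.isfinite(v) for v in (x, y, w, h)):
        raise ParseError(f"node {nid!r}: non-finite geometry")
    return NodeGeometry(x, y, w, h)
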