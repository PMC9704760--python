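"""Small XML helpers shared by the XML-based readers."""

from __future__ import annotations

import xml.etree.ElementTree as ET
from typing import Iterable, List, Optional, Tuple

from ..core import Node, PathwayGraph
from . import ParseError


def parse_xml(text: str) -> ET.Element:
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise ParseError(f"malformed XML: {exc}") from exc
    return root


def local_name(tag: str) -> str:
    """Tag name with any ``{namespace}`` prefix stripped."""
    return tag.rsplit("}", 1)[-1]


def find_children(element: ET.Element, name: str) -> List[ET.Element]:
    return [child for child in element if local_name(child.tag) == name]


def find_child(element: ET.Element, name: str) -> Optional[ET.Element]:
    matches = find_children(element, name)
    return matches[0] if matches else None


def iter_all(element: ET.Element, name: str) -> Iterable[ET.Element]:
    for child in element.iter():
        if local_name(child.tag) == name:
            yield child


def add_nodes_with_parents(
    graph: PathwayGraph, records: List[Node]
) -> None:
    """Insert nodes so that containers always precede their children."""
    pending = list(records)
    known = set(graph.nodes)
    declared = known | {n.id for n in pending}
    for node in pending:
        if node.parent is not None and node.parent not in declared:
            raise ParseError(
                f"node {node.id!r} references unknown parent {node.parent!r}"
            )
    while pending:
        progressed = False
        rest = []
        for node in pending:
            if node.parent is None or node.parent in known:
                graph.add_node(node)
                known.add(node.id)
                progressed = True
            else:
                rest.append(node)
        if not progressed:
            cyc = ", ".join(n.id for n in rest)
            raise ParseError(f"containment cycle among nodes: {cyc}")
        pending = rest


def parse_float_attr(element: ET.Element, attr: str, context: str) -> float:
    value = element.get(attr)
    if value is None:
        raise ParseError(f"{context}: missing attribute {attr!r}")
    try:
        return float(value)
    except ValueError as exc:
        raise ParseError(f"{context}: bad numeric attribute {attr}={value!r}") from exc


def bbox_to_center(
    x: float, y: float, w: float, h: float
) -> Tuple[float, float, float, float]:
    """Top-left corner box (the XML convention) to center coordinates."""
    return x + w / 2.0, y + h / 2.0, w, h
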