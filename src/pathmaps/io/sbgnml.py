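"""SBGNML (process description) reader."""

from __future__ import annotations

import xml.etree.ElementTree as ET
from typing import Dict, List, Optional

from ..core import Edge, EdgeClass, Node, NodeClass, NodeGeometry, PathwayGraph
from . import ParseError, ParseReport, SourceFormat
from ._xml import (
    add_nodes_with_parents,
    bbox_to_center,
    find_child,
    find_children,
    local_name,
    parse_float_attr,
    parse_xml,
)

#: SBGN PD glyph class -> internal node class.
GLYPH_CLASSES: Dict[str, NodeClass] = {
    "macromolecule": NodeClass.MACROMOLECULE,
    "simple chemical": NodeClass.SIMPLE_CHEMICAL,
    "nucleic acid feature": NodeClass.NUCLEIC_ACID_FEATURE,
    "unspecified entity": NodeClass.UNSPECIFIED_ENTITY,
    "complex": NodeClass.COMPLEX,
    "compartment": NodeClass.COMPARTMENT,
    "process": NodeClass.PROCESS,
    "association": NodeClass.ASSOCIATION,
    "dissociation": NodeClass.DISSOCIATION,
    "phenotype": NodeClass.PHENOTYPE,
    "source and sink": NodeClass.SOURCE_SINK,
    "empty set": NodeClass.SOURCE_SINK,
}

#: SBGN PD arc class -> internal edge class.
ARC_CLASSES: Dict[str, EdgeClass] = {
    "consumption": EdgeClass.CONSUMPTION,
    "production": EdgeClass.PRODUCTION,
    "catalysis": EdgeClass.CATALYSIS,
    "stimulation": EdgeClass.STIMULATION,
    "inhibition": EdgeClass.INHIBITION,
    "modulation": EdgeClass.MODULATION,
}

#: Sub-glyphs that decorate their owner instead of becoming nodes.
_AUXILIARY_GLYPHS = frozenset(
    {"state variable", "unit of information", "clone marker", "annotation"}
)

_PD_LANGUAGES = {"process description", "process_description", "PD"}


def read_sbgnml(text: str) -> ParseReport:
    """Parse an SBGNML process-description document.

    Glyph nesting and ``compartmentRef`` both become containment links;
    arcs that attach to ports are resolved to the port-owning glyph.
    Bounding boxes (top-left corner convention) are converted to center
    coordinates.
    """
    root = parse_xml(text)
    if local_name(root.tag) != "sbgn":
        raise ParseError("not an SBGNML document (expected <sbgn> root)")
    map_el = find_child(root, "map")
    if map_el is None:
        raise ParseError("SBGNML document has no <map>")
    language = map_el.get("language", "process description")
    if language not in _PD_LANGUAGES:
        raise ParseError(f"unsupported SBGN map language {language!r}")

    warnings: List[str] = []
    nodes: List[Node] = []
    port_owner: Dict[str, str] = {}

    def walk_glyph(glyph: ET.Element, container: Optional[str]) -> None:
        glyph_class = glyph.get("class", "")
        glyph_id = glyph.get("id")
        if glyph_class in _AUXILIARY_GLYPHS:
            warnings.append(f"auxiliary glyph {glyph_id or glyph_class!r} absorbed")
            return
        if glyph_id is None:
            raise ParseError("glyph without id")
        node_class = GLYPH_CLASSES.get(glyph_class)
        if node_class is None:
            warnings.append(
                f"unknown glyph class {glyph_class!r} on {glyph_id!r}; using generic"
            )
            node_class = NodeClass.GENERIC
        parent = glyph.get("compartmentRef") or container
        label_el = find_child(glyph, "label")
        label = label_el.get("text", "") if label_el is not None else ""
        geometry = None
        bbox = find_child(glyph, "bbox")
        if bbox is not None:
            x = parse_float_attr(bbox, "x", f"glyph {glyph_id}")
            y = parse_float_attr(bbox, "y", f"glyph {glyph_id}")
            w = parse_float_attr(bbox, "w", f"glyph {glyph_id}")
            h = parse_float_attr(bbox, "h", f"glyph {glyph_id}")
            geometry = NodeGeometry(*bbox_to_center(x, y, w, h))
        nodes.append(
            Node(id=glyph_id, label=label, node_class=node_class, parent=parent,
                 geometry=geometry)
        )
        for port in find_children(glyph, "port"):
            pid = port.get("id")
            if pid:
                port_owner[pid] = glyph_id
        for sub in find_children(glyph, "glyph"):
            walk_glyph(sub, glyph_id)

    for glyph in find_children(map_el, "glyph"):
        walk_glyph(glyph, None)

    graph = PathwayGraph()
    add_nodes_with_parents(graph, nodes)

    def resolve(ref: Optional[str], arc_id: str) -> str:
        if ref is None:
            raise ParseError(f"arc {arc_id!r} lacks an endpoint")
        if ref in graph:
            return ref
        if ref in port_owner:
            return port_owner[ref]
        raise ParseError(f"arc {arc_id!r} endpoint {ref!r} is unresolvable")

    counter = 0
    for arc in find_children(map_el, "arc"):
        arc_id = arc.get("id")
        if arc_id is None:
            arc_id = f"arc{counter}"
        counter += 1
        arc_class = arc.get("class", "")
        edge_class = ARC_CLASSES.get(arc_class)
        if edge_class is None:
            warnings.append(
                f"unknown arc class {arc_class!r} on {arc_id!r}; using generic"
            )
            edge_class = EdgeClass.GENERIC
        source = resolve(arc.get("source"), arc_id)
        target = resolve(arc.get("target"), arc_id)
        graph.add_edge(Edge(id=arc_id, source=source, target=target,
                            edge_class=edge_class))

    return ParseReport(graph=graph, warnings=warnings,
                       source_format=SourceFormat.SBGNML)
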