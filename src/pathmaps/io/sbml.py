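"""SBML (Level 2/3 core, optional layout package) reader.

Species become entity nodes, reactions become process nodes and the
species-reference lists become consumption/production/modulation arcs —
the usual bipartite expansion.  Compartments become compound nodes and
every species is parented by its compartment.  Reversible reactions are
flattened to their stated direction with a warning, since the query
direction semantics need a single orientation.
"""

from __future__ import annotations

from typing import Dict, List, Optional

from ..core import Edge, EdgeClass, Node, NodeClass, NodeGeometry, PathwayGraph
from . import ParseError, ParseReport, SourceFormat
from ._xml import (
    add_nodes_with_parents,
    bbox_to_center,
    find_child,
    find_children,
    iter_all,
    local_name,
    parse_float_attr,
    parse_xml,
)

#: Minimal SBO mappings; anything unrecognized falls back to the default.
SBO_SPECIES_CLASSES: Dict[str, NodeClass] = {
    "SBO:0000247": NodeClass.SIMPLE_CHEMICAL,  # simple chemical
    "SBO:0000245": NodeClass.MACROMOLECULE,  # macromolecule
    "SBO:0000250": NodeClass.NUCLEIC_ACID_FEATURE,  # ribonucleic acid
    "SBO:0000251": NodeClass.NUCLEIC_ACID_FEATURE,  # deoxyribonucleic acid
}

SBO_COMPARTMENT_CLASSES: Dict[str, NodeClass] = {
    "SBO:0000253": NodeClass.COMPLEX,  # non-covalent complex
}

#: Compartments tagged as implicit modelling artifacts produce no node.
_IMPLICIT_COMPARTMENT_SBO = "SBO:0000410"


def read_sbml(text: str) -> ParseReport:
    root = parse_xml(text)
    if local_name(root.tag) != "sbml":
        raise ParseError("not an SBML document (expected <sbml> root)")
    model = find_child(root, "model")
    if model is None:
        raise ParseError("SBML document has no <model>")

    warnings: List[str] = []
    nodes: List[Node] = []
    implicit: set = set()

    comp_list = find_child(model, "listOfCompartments")
    for comp in find_children(comp_list, "compartment") if comp_list is not None else []:
        cid = comp.get("id")
        if cid is None:
            raise ParseError("compartment without id")
        sbo = comp.get("sboTerm", "")
        if sbo == _IMPLICIT_COMPARTMENT_SBO:
            implicit.add(cid)
            warnings.append(f"implicit compartment {cid!r} skipped")
            continue
        nodes.append(
            Node(
                id=cid,
                label=comp.get("name", cid),
                node_class=SBO_COMPARTMENT_CLASSES.get(sbo, NodeClass.COMPARTMENT),
                parent=_visible(comp.get("outside"), implicit),
            )
        )

    species_ids = set()
    spec_list = find_child(model, "listOfSpecies")
    for sp in find_children(spec_list, "species") if spec_list is not None else []:
        sid = sp.get("id")
        if sid is None:
            raise ParseError("species without id")
        species_ids.add(sid)
        nodes.append(
            Node(
                id=sid,
                label=sp.get("name", sid),
                node_class=SBO_SPECIES_CLASSES.get(
                    sp.get("sboTerm", ""), NodeClass.MACROMOLECULE
                ),
                parent=_visible(sp.get("compartment"), implicit),
            )
        )

    edges: List[Edge] = []
    counter = 0

    def new_edge_id() -> str:
        nonlocal counter
        eid = f"e{counter}"
        counter += 1
        return eid

    rxn_list = find_child(model, "listOfReactions")
    for rxn in find_children(rxn_list, "reaction") if rxn_list is not None else []:
        rid = rxn.get("id")
        if rid is None:
            raise ParseError("reaction without id")
        if rxn.get("reversible", "false").lower() == "true":
            warnings.append(f"reaction {rid!r}: reversibility ignored")
        nodes.append(
            Node(
                id=rid,
                label=rxn.get("name", ""),
                node_class=NodeClass.PROCESS,
                parent=_visible(rxn.get("compartment"), implicit),
            )
        )

        def refs(list_name: str) -> List[str]:
            lst = find_child(rxn, list_name)
            if lst is None:
                return []
            out = []
            for ref in lst:
                species = ref.get("species")
                if species is None:
                    continue
                if species not in species_ids:
                    raise ParseError(
                        f"reaction {rid!r} references unknown species {species!r}"
                    )
                out.append(species)
            return out

        for species in refs("listOfReactants"):
            edges.append(Edge(new_edge_id(), species, rid, EdgeClass.CONSUMPTION))
        for species in refs("listOfProducts"):
            edges.append(Edge(new_edge_id(), rid, species, EdgeClass.PRODUCTION))
        for species in refs("listOfModifiers"):
            edges.append(Edge(new_edge_id(), species, rid, EdgeClass.MODULATION))

    graph = PathwayGraph()
    add_nodes_with_parents(graph, nodes)
    for edge in edges:
        graph.add_edge(edge)

    _adopt_layout(root, graph, warnings)
    return ParseReport(graph=graph, warnings=warnings, source_format=SourceFormat.SBML)


def _visible(ref: Optional[str], implicit: set) -> Optional[str]:
    return None if ref is None or ref in implicit else ref


def _adopt_layout(root, graph: PathwayGraph, warnings: List[str]) -> None:
    """Pick up layout-package bounding boxes when the document has any."""
    for glyph in iter_all(root, "compartmentGlyph"):
        _apply_bbox(glyph, glyph.get("compartment"), graph, warnings)
    for glyph in iter_all(root, "speciesGlyph"):
        _apply_bbox(glyph, glyph.get("species"), graph, warnings)
    for glyph in iter_all(root, "reactionGlyph"):
        _apply_bbox(glyph, glyph.get("reaction"), graph, warnings)


def _apply_bbox(glyph, ref: Optional[str], graph: PathwayGraph, warnings: List[str]) -> None:
    if ref is None or ref not in graph:
        if ref is not None:
            warnings.append(f"layout glyph for unknown element {ref!r} ignored")
        return
    bbox = find_child(glyph, "boundingBox")
    if bbox is None:
        return
    pos = find_child(bbox, "position")
    dim = find_child(bbox, "dimensions")
    if pos is None or dim is None:
        return
    x = parse_float_attr(pos, "x", f"layout of {ref}")
    y = parse_float_attr(pos, "y", f"layout of {ref}")
    w = parse_float_attr(dim, "width", f"layout of {ref}")
    h = parse_float_attr(dim, "height", f"layout of {ref}")
    graph.nodes[ref].geometry = NodeGeometry(*bbox_to_center(x, y, w, h))
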