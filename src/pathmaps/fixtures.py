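"""Deterministic synthetic pathway maps and canonical oracle graphs.

The generator produces process-description-like bipartite structures
(entities interact only through process nodes) distributed over
compartments and complexes, and can emit the same map in all four
supported formats such that each file re-parses to an isomorphic graph.
Topologies make no claim to biological realism.
"""

from __future__ import annotations

import os
import random
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from .core import Edge, EdgeClass, Node, NodeClass, PathwayGraph
from .io.elements import write_elements_json

__all__ = [
    "FixtureSpec",
    "generate_pathway",
    "emit_all_formats",
    "canonical_graphs",
    "write_sbgnml",
    "write_sbml",
    "write_graphml",
    "fingerprint",
]


@dataclass(frozen=True)
class FixtureSpec:
    n_entities: int = 6
    n_processes: int = 3
    n_compartments: int = 0
    n_complexes: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_entities", "n_processes", "n_compartments", "n_complexes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def generate_pathway(spec: FixtureSpec) -> PathwayGraph:
    """Deterministic pseudo-random pathway; a pure function of ``spec``."""
    rng = random.Random(spec.seed)
    graph = PathwayGraph()

    compartments = [f"comp{i}" for i in range(spec.n_compartments)]
    for i, cid in enumerate(compartments):
        graph.add_node(Node(cid, label=f"Compartment {i}", node_class=NodeClass.COMPARTMENT))

    complexes = [f"cx{i}" for i in range(spec.n_complexes)]
    for i, xid in enumerate(complexes):
        parent = compartments[i % len(compartments)] if compartments else None
        graph.add_node(Node(xid, label=f"Complex {i}", node_class=NodeClass.COMPLEX,
                            parent=parent))

    entities = [f"ent{i}" for i in range(spec.n_entities)]
    for i, eid in enumerate(entities):
        cls = NodeClass.SIMPLE_CHEMICAL if i % 2 else NodeClass.MACROMOLECULE
        # every complex gets at least one member; the rest go to compartments
        if complexes and i < len(complexes):
            parent = complexes[i]
        elif complexes and i < 2 * len(complexes) and rng.random() < 0.5:
            parent = complexes[i - len(complexes)]
        elif compartments:
            parent = compartments[i % len(compartments)]
        else:
            parent = None
        graph.add_node(Node(eid, label=f"Entity {i}", node_class=cls, parent=parent))

    counter = 0

    def add_arc(source: str, target: str, cls: EdgeClass) -> None:
        nonlocal counter
        graph.add_edge(Edge(f"a{counter}", source, target, cls))
        counter += 1

    # only plain entities take part in arcs so the SBML encoding stays lossless
    participants = entities
    for i in range(spec.n_processes):
        pid = f"proc{i}"
        graph.add_node(Node(pid, label=f"Process {i}", node_class=NodeClass.PROCESS))
        if not participants:
            continue
        n_in = 1 + (rng.random() < 0.4)
        n_out = 1 + (rng.random() < 0.4)
        inputs = rng.sample(participants, min(n_in, len(participants)))
        outputs = rng.sample(participants, min(n_out, len(participants)))
        for eid in inputs:
            add_arc(eid, pid, EdgeClass.CONSUMPTION)
        for eid in outputs:
            if eid not in inputs:  # keep the fixture free of tight loops
                add_arc(pid, eid, EdgeClass.PRODUCTION)
        if rng.random() < 0.4:
            mod = rng.choice(participants)
            if mod not in inputs:
                add_arc(mod, pid, EdgeClass.MODULATION)
    return graph


# ---------------------------------------------------------------------------
# format emitters (fixture-quality, lossless for generated maps)
# ---------------------------------------------------------------------------

_GLYPH_NAMES: Dict[NodeClass, str] = {
    NodeClass.MACROMOLECULE: "macromolecule",
    NodeClass.SIMPLE_CHEMICAL: "simple chemical",
    NodeClass.NUCLEIC_ACID_FEATURE: "nucleic acid feature",
    NodeClass.UNSPECIFIED_ENTITY: "unspecified entity",
    NodeClass.COMPLEX: "complex",
    NodeClass.COMPARTMENT: "compartment",
    NodeClass.PROCESS: "process",
    NodeClass.ASSOCIATION: "association",
    NodeClass.DISSOCIATION: "dissociation",
    NodeClass.PHENOTYPE: "phenotype",
    NodeClass.SOURCE_SINK: "source and sink",
    NodeClass.GENERIC: "unspecified entity",
}


def write_sbgnml(graph: PathwayGraph) -> str:
    root = ET.Element("sbgn", {"xmlns": "http://sbgn.org/libsbgn/0.2"})
    map_el = ET.SubElement(root, "map", {"language": "process description"})
    glyph_els: Dict[str, ET.Element] = {}

    for nid in graph.nodes_in_document_order():
        node = graph.nodes[nid]
        attrs = {"id": nid, "class": _GLYPH_NAMES[node.node_class]}
        parent = node.parent
        container = map_el
        if parent is not None:
            if graph.nodes[parent].node_class is NodeClass.COMPARTMENT:
                attrs["compartmentRef"] = parent
            else:
                container = glyph_els[parent]
        glyph = ET.SubElement(container, "glyph", attrs)
        glyph_els[nid] = glyph
        if node.label:
            ET.SubElement(glyph, "label", {"text": node.label})
        if node.geometry is not None:
            g = node.geometry
            ET.SubElement(
                glyph,
                "bbox",
                {"x": str(g.left), "y": str(g.top), "w": str(g.w), "h": str(g.h)},
            )
    for eid, edge in graph.edges.items():
        ET.SubElement(
            map_el,
            "arc",
            {
                "id": eid,
                "class": edge.edge_class.value,
                "source": edge.source,
                "target": edge.target,
            },
        )
    return ET.tostring(root, encoding="unicode")


_SPECIES_SBO: Dict[NodeClass, str] = {
    NodeClass.SIMPLE_CHEMICAL: "SBO:0000247",
    NodeClass.MACROMOLECULE: "SBO:0000245",
    NodeClass.NUCLEIC_ACID_FEATURE: "SBO:0000250",
}

_IMPLICIT_ID = "__container__"


def write_sbml(graph: PathwayGraph) -> str:
    """Minimal SBML Level 2 document.

    Complexes are encoded as compartments tagged SBO:0000253 and nesting
    uses the ``outside`` attribute.  Parent-less species are placed in an
    implicit compartment (SBO:0000410) that the reader knows to drop, so
    fixture round-trips stay isomorphic.
    """
    root = ET.Element(
        "sbml",
        {"xmlns": "http://www.sbml.org/sbml/level2/version4", "level": "2",
         "version": "4"},
    )
    model = ET.SubElement(root, "model", {"id": "fixture"})
    comps = ET.SubElement(model, "listOfCompartments")
    species_el: Optional[ET.Element] = None
    reactions_el: Optional[ET.Element] = None

    containers = [
        n for n in graph.nodes.values() if n.node_class.compound_capable
    ]
    entities = [
        n
        for n in graph.nodes.values()
        if not n.node_class.compound_capable and n.node_class is not NodeClass.PROCESS
    ]
    processes = [n for n in graph.nodes.values() if n.node_class is NodeClass.PROCESS]

    need_implicit = any(n.parent is None for n in entities)
    if need_implicit:
        ET.SubElement(
            comps, "compartment",
            {"id": _IMPLICIT_ID, "sboTerm": "SBO:0000410", "size": "1"},
        )
    for node in containers:
        attrs = {"id": node.id, "name": node.label}
        if node.node_class is NodeClass.COMPLEX:
            attrs["sboTerm"] = "SBO:0000253"
        if node.parent is not None:
            attrs["outside"] = node.parent
        ET.SubElement(comps, "compartment", attrs)

    if entities:
        species_el = ET.SubElement(model, "listOfSpecies")
        for node in entities:
            attrs = {
                "id": node.id,
                "name": node.label,
                "compartment": node.parent or _IMPLICIT_ID,
            }
            sbo = _SPECIES_SBO.get(node.node_class)
            if sbo:
                attrs["sboTerm"] = sbo
            ET.SubElement(species_el, "species", attrs)

    if processes:
        reactions_el = ET.SubElement(model, "listOfReactions")
        for node in processes:
            rxn = ET.SubElement(
                reactions_el,
                "reaction",
                {"id": node.id, "name": node.label, "reversible": "false"},
            )
            reactants = [e for e in graph.in_edges(node.id)
                         if e.edge_class is EdgeClass.CONSUMPTION]
            modifiers = [e for e in graph.in_edges(node.id)
                         if e.edge_class is not EdgeClass.CONSUMPTION]
            products = graph.out_edges(node.id)
            if reactants:
                lst = ET.SubElement(rxn, "listOfReactants")
                for e in reactants:
                    ET.SubElement(lst, "speciesReference", {"species": e.source})
            if products:
                lst = ET.SubElement(rxn, "listOfProducts")
                for e in products:
                    ET.SubElement(lst, "speciesReference", {"species": e.target})
            if modifiers:
                lst = ET.SubElement(rxn, "listOfModifiers")
                for e in modifiers:
                    ET.SubElement(lst, "modifierSpeciesReference", {"species": e.source})
    return ET.tostring(root, encoding="unicode")


def write_graphml(graph: PathwayGraph) -> str:
    root = ET.Element("graphml", {"xmlns": "http://graphml.graphdrawing.org/xmlns"})
    keys = {}
    for i, (name, target) in enumerate(
        [("label", "node"), ("class", "node"), ("x", "node"), ("y", "node"),
         ("w", "node"), ("h", "node"), ("class", "edge")]
    ):
        kid = f"k{i}"
        ET.SubElement(
            root, "key",
            {"id": kid, "for": target, "attr.name": name, "attr.type": "string"},
        )
        keys[(name, target)] = kid

    top = ET.SubElement(root, "graph", {"id": "G", "edgedefault": "directed"})
    containers: Dict[str, ET.Element] = {}

    def node_container(nid: str) -> ET.Element:
        parent = graph.nodes[nid].parent
        if parent is None:
            return top
        if parent not in containers:
            containers[parent] = ET.SubElement(
                node_elements[parent], "graph",
                {"id": f"{parent}:g", "edgedefault": "directed"},
            )
        return containers[parent]

    node_elements: Dict[str, ET.Element] = {}
    for nid in graph.nodes_in_document_order():
        node = graph.nodes[nid]
        el = ET.SubElement(node_container(nid), "node", {"id": nid})
        node_elements[nid] = el
        for name, value in (("label", node.label), ("class", node.node_class.value)):
            if value:
                data = ET.SubElement(el, "data", {"key": keys[(name, "node")]})
                data.text = value
        if node.geometry is not None:
            g = node.geometry
            for name, value in (("x", g.x), ("y", g.y), ("w", g.w), ("h", g.h)):
                data = ET.SubElement(el, "data", {"key": keys[(name, "node")]})
                data.text = repr(float(value))
    for eid, edge in graph.edges.items():
        el = ET.SubElement(
            top, "edge", {"id": eid, "source": edge.source, "target": edge.target}
        )
        data = ET.SubElement(el, "data", {"key": keys[("class", "edge")]})
        data.text = edge.edge_class.value
    return ET.tostring(root, encoding="unicode")


def emit_all_formats(graph: PathwayGraph, directory: str, stem: str = "map") -> Dict[str, str]:
    """Write the map as .sbgn/.sbml/.graphml/.json; returns path per format."""
    os.makedirs(directory, exist_ok=True)
    outputs = {
        "sbgnml": (f"{stem}.sbgn", write_sbgnml(graph)),
        "sbml": (f"{stem}.sbml", write_sbml(graph)),
        "graphml": (f"{stem}.graphml", write_graphml(graph)),
        "json": (f"{stem}.json", write_elements_json(graph, indent=2)),
    }
    paths = {}
    for fmt, (name, text) in outputs.items():
        path = os.path.join(directory, name)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
        paths[fmt] = path
    return paths


def fingerprint(graph: PathwayGraph) -> Tuple[Tuple, Tuple]:
    """Isomorphism key: node and edge multisets by label+class+parent-label."""

    def label_of(nid: Optional[str]) -> Optional[str]:
        return None if nid is None else graph.nodes[nid].label

    nodes = sorted(
        (n.label, n.node_class.value, label_of(n.parent)) for n in graph.nodes.values()
    )
    edges = sorted(
        (label_of(e.source), label_of(e.target), e.edge_class.value)
        for e in graph.edges.values()
    )
    return tuple(nodes), tuple(edges)


# ---------------------------------------------------------------------------
# canonical oracle graphs
# ---------------------------------------------------------------------------


def _chain(graph: PathwayGraph, ids: List[str], prefix: str) -> None:
    for i, (u, v) in enumerate(zip(ids, ids[1:])):
        graph.add_edge(Edge(f"{prefix}{i}", u, v, EdgeClass.GENERIC))


def canonical_graphs() -> Dict[str, PathwayGraph]:
    """Small fixed-id graphs used as test oracles throughout the suite."""
    out: Dict[str, PathwayGraph] = {}

    star = PathwayGraph()
    star.add_node(Node("c", label="c"))
    for i in range(4):
        star.add_node(Node(f"l{i}", label=f"l{i}"))
        star.add_edge(Edge(f"e{i}", "c", f"l{i}"))
    out["star4"] = star

    path = PathwayGraph()
    for nid in "ABC":
        path.add_node(Node(nid, label=nid))
    _chain(path, list("ABC"), "e")
    out["path3"] = path

    cycle = PathwayGraph()
    for nid in "ABC":
        cycle.add_node(Node(nid, label=nid))
    cycle.add_edge(Edge("e0", "A", "B"))
    cycle.add_edge(Edge("e1", "B", "C"))
    cycle.add_edge(Edge("e2", "C", "A"))
    out["cycle3"] = cycle

    k3 = PathwayGraph()
    for nid in "ABC":
        k3.add_node(Node(nid, label=nid))
    k3.add_edge(Edge("e0", "A", "B"))
    k3.add_edge(Edge("e1", "A", "C"))
    k3.add_edge(Edge("e2", "B", "C"))
    out["k3"] = k3

    k4 = PathwayGraph()
    ids = list("ABCD")
    for nid in ids:
        k4.add_node(Node(nid, label=nid))
    c = 0
    for i, u in enumerate(ids):
        for v in ids[i + 1 :]:
            k4.add_edge(Edge(f"e{c}", u, v))
            c += 1
    out["k4"] = k4

    # compartment > complex > two macromolecules, plus an external target
    nest = PathwayGraph()
    nest.add_node(Node("comp", label="comp", node_class=NodeClass.COMPARTMENT))
    nest.add_node(Node("cx", label="cx", node_class=NodeClass.COMPLEX, parent="comp"))
    nest.add_node(Node("m1", label="m1", node_class=NodeClass.MACROMOLECULE, parent="cx"))
    nest.add_node(Node("m2", label="m2", node_class=NodeClass.MACROMOLECULE, parent="cx"))
    nest.add_node(Node("Z", label="Z", node_class=NodeClass.MACROMOLECULE))
    nest.add_edge(Edge("e0", "cx", "Z", EdgeClass.PRODUCTION))
    out["nesting3"] = nest

    # two vertex-disjoint directed routes (lengths 4 and 6) between two
    # simple chemicals, alternating through process nodes
    two = PathwayGraph()
    two.add_node(Node("s", label="s", node_class=NodeClass.SIMPLE_CHEMICAL))
    two.add_node(Node("t", label="t", node_class=NodeClass.SIMPLE_CHEMICAL))
    r1 = ["s", "p1", "m1", "p2", "t"]
    r2 = ["s", "p3", "m2", "p4", "m3", "p5", "t"]
    for route in (r1, r2):
        for nid in route[1:-1]:
            cls = NodeClass.PROCESS if nid.startswith("p") else NodeClass.MACROMOLECULE
            two.add_node(Node(nid, label=nid, node_class=cls))
    _chain(two, r1, "a")
    _chain(two, r2, "b")
    out["two_route"] = two

    # worked example: shortest s->t length 3, extra simple paths of
    # lengths 4, 5 and 6 on vertex-disjoint routes
    worked = PathwayGraph()
    worked.add_node(Node("s", label="s"))
    worked.add_node(Node("t", label="t"))
    routes = {
        "a": ["s", "a1", "a2", "t"],
        "b": ["s", "b1", "b2", "b3", "t"],
        "c": ["s", "c1", "c2", "c3", "c4", "t"],
        "d": ["s", "d1", "d2", "d3", "d4", "d5", "t"],
    }
    for prefix, route in routes.items():
        for nid in route[1:-1]:
            worked.add_node(Node(nid, label=nid))
        _chain(worked, route, prefix)
    out["worked_example"] = worked

    return out
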