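"""Compound pathway graph model.

A :class:`PathwayGraph` is a directed multigraph (parallel edges and
self-loops allowed) whose nodes additionally live in a *containment
forest*: compartments and molecular complexes may contain other nodes.
Containment is deliberately not represented as edges — nesting is a
spatial/semantic relationship, not an interaction — so every edge-based
algorithm sees only the explicit arcs.

Coordinate convention: node ``(x, y)`` is the node **center**, the y axis
grows downward and the origin is at the top-left, matching SVG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Dict, Iterator, List, Optional, Set

__all__ = [
    "NodeClass",
    "EdgeClass",
    "NodeGeometry",
    "Node",
    "Edge",
    "PathwayGraph",
    "GraphError",
    "DuplicateIdError",
    "UnknownNodeError",
    "InvalidParentError",
]


class GraphError(ValueError):
    """Base class for graph construction/lookup failures."""


class DuplicateIdError(GraphError):
    """A node or edge id is already present."""


class UnknownNodeError(GraphError):
    """A referenced node id does not exist."""


class InvalidParentError(GraphError):
    """The declared parent is missing or not compound-capable."""


class NodeClass(str, Enum):
    """Closed subset of process-description glyph classes."""

    MACROMOLECULE = "macromolecule"
    SIMPLE_CHEMICAL = "simple_chemical"
    NUCLEIC_ACID_FEATURE = "nucleic_acid_feature"
    UNSPECIFIED_ENTITY = "unspecified_entity"
    COMPLEX = "complex"
    COMPARTMENT = "compartment"
    PROCESS = "process"
    ASSOCIATION = "association"
    DISSOCIATION = "dissociation"
    PHENOTYPE = "phenotype"
    SOURCE_SINK = "source_sink"
    GENERIC = "generic"

    @property
    def compound_capable(self) -> bool:
        """Whether nodes of this class may contain children."""
        return self in (NodeClass.COMPARTMENT, NodeClass.COMPLEX)


#: Classes whose nodes may act as containment parents.
COMPOUND_CLASSES = frozenset({NodeClass.COMPARTMENT, NodeClass.COMPLEX})


class EdgeClass(str, Enum):
    """Closed subset of process-description arc classes."""

    CONSUMPTION = "consumption"
    PRODUCTION = "production"
    CATALYSIS = "catalysis"
    STIMULATION = "stimulation"
    INHIBITION = "inhibition"
    MODULATION = "modulation"
    GENERIC = "generic"


@dataclass(frozen=True)
class NodeGeometry:
    """Axis-aligned box: center position plus positive dimensions (px)."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        for v in (self.x, self.y, self.w, self.h):
            if not math.isfinite(v):
                raise ValueError("geometry coordinates must be finite")
        if self.w <= 0 or self.h <= 0:
            raise ValueError("geometry dimensions must be positive")

    @property
    def left(self) -> float:
        return self.x - self.w / 2.0

    @property
    def top(self) -> float:
        return self.y - self.h / 2.0

    @property
    def right(self) -> float:
        return self.x + self.w / 2.0

    @property
    def bottom(self) -> float:
        return self.y + self.h / 2.0

    def contains(self, other: "NodeGeometry", slack: float = 1e-6) -> bool:
        return (
            self.left - slack <= other.left
            and self.top - slack <= other.top
            and other.right <= self.right + slack
            and other.bottom <= self.bottom + slack
        )


@dataclass
class Node:
    id: str
    label: str = ""
    node_class: NodeClass = NodeClass.GENERIC
    parent: Optional[str] = None
    geometry: Optional[NodeGeometry] = None
    # Set by metrics.annotate_with_centrality; consumed by the renderer as a
    # default highlight thickness in [0, 1].
    highlight_thickness: Optional[float] = None

    def copy(self) -> "Node":
        return replace(self)


@dataclass
class Edge:
    id: str
    source: str
    target: str
    edge_class: EdgeClass = EdgeClass.GENERIC

    def copy(self) -> "Edge":
        return replace(self)


class PathwayGraph:
    """Directed multigraph with a containment forest.

    Nodes and edges are stored in insertion order (plain dicts), which all
    downstream algorithms rely on for determinism.
    """

    def __init__(self) -> None:
        self.nodes: Dict[str, Node] = {}
        self.edges: Dict[str, Edge] = {}
        self._children: Dict[str, List[str]] = {}
        self._out: Dict[str, List[str]] = {}
        self._in: Dict[str, List[str]] = {}

    # -- construction ---------------------------------------------------

    def add_node(self, node: Node) -> "PathwayGraph":
        if node.id in self.nodes:
            raise DuplicateIdError(f"duplicate node id {node.id!r}")
        if node.parent is not None:
            parent = self.nodes.get(node.parent)
            if parent is None:
                raise InvalidParentError(
                    f"node {node.id!r} declares unknown parent {node.parent!r}"
                )
            if not parent.node_class.compound_capable:
                raise InvalidParentError(
                    f"parent {node.parent!r} of class {parent.node_class.value}"
                    " is not compound-capable"
                )
        self.nodes[node.id] = node
        self._children[node.id] = []
        self._out[node.id] = []
        self._in[node.id] = []
        if node.parent is not None:
            self._children[node.parent].append(node.id)
        return self

    def add_edge(self, edge: Edge) -> "PathwayGraph":
        if edge.id in self.edges:
            raise DuplicateIdError(f"duplicate edge id {edge.id!r}")
        for endpoint in (edge.source, edge.target):
            if endpoint not in self.nodes:
                raise UnknownNodeError(
                    f"edge {edge.id!r} references unknown node {endpoint!r}"
                )
        self.edges[edge.id] = edge
        self._out[edge.source].append(edge.id)
        self._in[edge.target].append(edge.id)
        return self

    def remove_node(self, node_id: str) -> Node:
        """Remove a childless node with no incident edges."""
        node = self._require(node_id)
        if self._children[node_id]:
            raise GraphError(f"node {node_id!r} still has children")
        if self._out[node_id] or self._in[node_id]:
            raise GraphError(f"node {node_id!r} still has incident edges")
        if node.parent is not None:
            self._children[node.parent].remove(node_id)
        for table in (self.nodes, self._children, self._out, self._in):
            del table[node_id]
        return node

    def remove_edge(self, edge_id: str) -> Edge:
        edge = self.edges.pop(edge_id, None)
        if edge is None:
            raise GraphError(f"unknown edge {edge_id!r}")
        self._out[edge.source].remove(edge_id)
        self._in[edge.target].remove(edge_id)
        return edge

    # -- lookup ---------------------------------------------------------

    def _require(self, node_id: str) -> Node:
        node = self.nodes.get(node_id)
        if node is None:
            raise UnknownNodeError(f"unknown node {node_id!r}")
        return node

    def children(self, node_id: str) -> List[str]:
        self._require(node_id)
        return list(self._children[node_id])

    def out_edges(self, node_id: str) -> List[Edge]:
        self._require(node_id)
        return [self.edges[e] for e in self._out[node_id]]

    def in_edges(self, node_id: str) -> List[Edge]:
        self._require(node_id)
        return [self.edges[e] for e in self._in[node_id]]

    def degree(self, node_id: str) -> int:
        """Number of incident edge endpoints; a self-loop counts twice."""
        self._require(node_id)
        return len(self._out[node_id]) + len(self._in[node_id])

    def roots(self) -> List[str]:
        return [nid for nid, n in self.nodes.items() if n.parent is None]

    def depth(self, node_id: str) -> int:
        return len(self.ancestors(node_id))

    # -- containment traversal ------------------------------------------

    def descendants(self, node_id: str) -> List[str]:
        """All nodes below ``node_id`` in the forest, depth-first order."""
        self._require(node_id)
        out: List[str] = []
        stack = list(reversed(self._children[node_id]))
        while stack:
            nid = stack.pop()
            out.append(nid)
            stack.extend(reversed(self._children[nid]))
        return out

    def ancestors(self, node_id: str) -> List[str]:
        """Ancestor chain of ``node_id``, immediate parent first, root last."""
        node = self._require(node_id)
        out: List[str] = []
        while node.parent is not None:
            out.append(node.parent)
            node = self.nodes[node.parent]
        return out

    def effective_closure(self, node_id: str) -> Set[str]:
        """The co-reached set of a compound traversal step.

        Reaching ``node_id`` also reaches its whole ancestor chain and every
        descendant at no extra cost; siblings are *not* part of the closure —
        they are picked up transitively through the parent on the next
        zero-cost expansion.
        """
        self._require(node_id)
        return {node_id, *self.ancestors(node_id), *self.descendants(node_id)}

    def containment_tree_of(self, node_id: str) -> Set[str]:
        """All nodes sharing a containment tree with ``node_id`` (incl. self)."""
        anc = self.ancestors(node_id)
        root = anc[-1] if anc else node_id
        return {root, *self.descendants(root)}

    # -- misc -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self) -> Iterator[Node]:
        return iter(self.nodes.values())

    def __contains__(self, node_id: object) -> bool:
        return node_id in self.nodes

    def copy(self) -> "PathwayGraph":
        g = PathwayGraph()
        for node in self.nodes.values():
            g.add_node(node.copy())
        for edge in self.edges.values():
            g.add_edge(edge.copy())
        return g

    def nodes_in_document_order(self) -> List[str]:
        """Node ids ordered so that every container precedes its descendants."""
        order: List[str] = []
        for root in self.roots():
            order.append(root)
            order.extend(self.descendants(root))
        return order
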