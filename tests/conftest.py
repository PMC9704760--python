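import random
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from pathmaps.core import Edge, EdgeClass, Node, NodeClass, PathwayGraph
from pathmaps.fixtures import canonical_graphs


@pytest.fixture(scope="session")
def canon():
    return canonical_graphs()


@pytest.fixture
def path3(canon):
    return canon["path3"].copy()


@pytest.fixture
def nesting3(canon):
    return canon["nesting3"].copy()


def make_random_flat_graph(rng: random.Random, n_max: int = 12) -> PathwayGraph:
    """Seeded random simple digraph (no parallel edges, no self-loops)."""
    n = rng.randint(2, n_max)
    g = PathwayGraph()
    ids = [f"n{i}" for i in range(n)]
    for nid in ids:
        g.add_node(Node(nid, label=nid))
    pairs = [(u, v) for u in ids for v in ids if u != v]
    rng.shuffle(pairs)
    m = rng.randint(1, min(len(pairs), 2 * n))
    for i, (u, v) in enumerate(pairs[:m]):
        g.add_edge(Edge(f"e{i}", u, v))
    return g


def make_random_compound_graph(rng: random.Random, n_max: int = 12) -> PathwayGraph:
    """Seeded random graph with a containment forest and arcs (compounds may
    carry arcs of their own)."""
    n = rng.randint(2, n_max)
    g = PathwayGraph()
    ids = []
    for i in range(n):
        nid = f"n{i}"
        cls = NodeClass.COMPARTMENT if rng.random() < 0.3 else NodeClass.MACROMOLECULE
        compound_parents = [
            x for x in ids if g.nodes[x].node_class.compound_capable
        ]
        parent = (
            rng.choice(compound_parents)
            if compound_parents and rng.random() < 0.4
            else None
        )
        g.add_node(Node(nid, label=nid, node_class=cls, parent=parent))
        ids.append(nid)
    pairs = [(u, v) for u in ids for v in ids if u != v]
    rng.shuffle(pairs)
    m = rng.randint(1, min(len(pairs), 2 * n))
    for i, (u, v) in enumerate(pairs[:m]):
        g.add_edge(Edge(f"e{i}", u, v))
    return g


def build_graph(nodes, edges=()):
    """Terse graph builder: nodes as (id[, class[, parent]]), edges as
    (id, source, target[, class])."""
    g = PathwayGraph()
    for spec in nodes:
        if isinstance(spec, str):
            spec = (spec,)
        nid = spec[0]
        cls = NodeClass(spec[1]) if len(spec) > 1 else NodeClass.MACROMOLECULE
        parent = spec[2] if len(spec) > 2 else None
        g.add_node(Node(nid, label=nid, node_class=cls, parent=parent))
    for spec in edges:
        eid, src, tgt = spec[:3]
        cls = EdgeClass(spec[3]) if len(spec) > 3 else EdgeClass.GENERIC
        g.add_edge(Edge(eid, src, tgt, cls))
    return g
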