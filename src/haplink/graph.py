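"""Bidirected assembly-graph data model with telomere annotation.

The graph holds the unitigs of a (diploid) genome assembly: each node is a
sequence segment with a length, a mean read-depth estimate and, optionally,
the sequence itself.  Links are oriented: ``(A, '+') -> (B, '-')`` means that
walking off the 3' end of A in its stored orientation continues onto the
reverse complement of B.  Every link implies its reverse complement, so edges
are stored once in a canonical form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import networkx as nx

PLUS = "+"
MINUS = "-"

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def flip(orientation: str) -> str:
    """Opposite strand symbol."""
    return MINUS if orientation == PLUS else PLUS


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


OrientedNode = tuple[str, str]  # (node id, '+'/'-')
Edge = tuple[OrientedNode, OrientedNode]


def canonical_edge(a: OrientedNode, b: OrientedNode) -> Edge:
    """Canonical representative among an oriented link and its reverse complement."""
    fwd = (a, b)
    rev = ((b[0], flip(b[1])), (a[0], flip(a[1])))
    return min(fwd, rev)


@dataclass
class Node:
    """A unitig: id, length in bp, mean read depth and optional sequence.

    ``telo_start``/``telo_end`` flag telomeric repeat at the 5'/3' end of the
    stored orientation.
    """

    id: str
    length: int
    coverage: float = 0.0
    sequence: Optional[str] = None
    telo_start: bool = False
    telo_end: bool = False

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"node {self.id}: length must be >= 1, got {self.length}")
        if self.coverage < 0:
            raise ValueError(f"node {self.id}: coverage must be >= 0")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"node {self.id}: sequence length {len(self.sequence)} != length {self.length}"
            )

    def telo(self, end: str, orientation: str = PLUS) -> bool:
        """Telomere flag at the 'left' or 'right' end of the given orientation."""
        if orientation == PLUS:
            return self.telo_start if end == "left" else self.telo_end
        return self.telo_end if end == "left" else self.telo_start


class AssemblyGraph:
    """Bidirected sequence graph over :class:`Node` objects.

    Edges are stored canonically; ``successors`` exposes oriented traversal.
    """

    def __init__(self) -> None:
        self.nodes: dict[str, Node] = {}
        # canonical edge -> overlap length in bp
        self.edges: dict[Edge, int] = {}

    # -- construction ------------------------------------------------------

    def add_node(self, node: Node) -> None:
        self.nodes[node.id] = node

    def add_edge(self, a: OrientedNode, b: OrientedNode, overlap: int = 0) -> None:
        for nid in (a[0], b[0]):
            if nid not in self.nodes:
                raise KeyError(f"edge references unknown node {nid!r}")
        self.edges[canonical_edge(a, b)] = overlap

    # -- queries -----------------------------------------------------------

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.nodes

    def node(self, node_id: str) -> Node:
        return self.nodes[node_id]

    def length(self, node_id: str) -> int:
        return self.nodes[node_id].length

    def successors(self, v: OrientedNode) -> list[OrientedNode]:
        """Oriented nodes reachable by leaving the 3' end of ``v``."""
        out = []
        for (a, b) in self.edges:
            if a == v:
                out.append(b)
            rev = ((b[0], flip(b[1])), (a[0], flip(a[1])))
            if rev[0] == v and rev != (a, b):
                out.append(rev[1])
        return sorted(set(out))

    def degree(self, node_id: str) -> int:
        """Number of distinct canonical links touching the node (any end)."""
        return sum(1 for (a, b) in self.edges if node_id in (a[0], b[0]))

    def undirected(self) -> nx.Graph:
        """Plain node-level adjacency (orientation dropped); used for
        component finding, hop expansion and graph-distance queries."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (a, b) in self.edges:
            if a[0] != b[0]:
                g.add_edge(a[0], b[0])
        return g

    def components(self) -> list[set[str]]:
        comps = [set(c) for c in nx.connected_components(self.undirected())]
        return sorted(comps, key=lambda c: min(c))

    def copy(self) -> "AssemblyGraph":
        g = AssemblyGraph()
        for n in self.nodes.values():
            g.add_node(
                Node(n.id, n.length, n.coverage, n.sequence, n.telo_start, n.telo_end)
            )
        g.edges = dict(self.edges)
        return g

    def remove_nodes(self, ids: Iterable[str]) -> None:
        drop = set(ids)
        for nid in drop:
            self.nodes.pop(nid, None)
        self.edges = {
            e: ov for e, ov in self.edges.items() if e[0][0] not in drop and e[1][0] not in drop
        }

    def __repr__(self) -> str:  # pragma: no cover
        return f"AssemblyGraph({len(self.nodes)} nodes, {len(self.edges)} edges)"


# -- telomere annotation ---------------------------------------------------


def _motif_density(seq: str, motif: str) -> float:
    """Fraction of ``seq`` covered by non-overlapping occurrences of ``motif``
    or its reverse complement."""
    if not seq:
        return 0.0
    covered = 0
    for m in (motif, revcomp(motif)):
        start = 0
        while True:
            i = seq.find(m, start)
            if i < 0:
                break
            covered += len(m)
            start = i + len(m)
    return covered / len(seq)


def annotate_telomeres(
    g: AssemblyGraph,
    motif: str = "TTAGGG",
    window: int = 10_000,
    min_density: float = 0.3,
    bed: Optional[dict[str, list[tuple[int, int]]]] = None,
) -> AssemblyGraph:
    """Set ``telo_start``/``telo_end`` flags on every node, in place.

    A node end is telomeric when at least ``min_density`` of its terminal
    ``window`` bp (truncated to the node length) is covered by the telomere
    ``motif`` or its reverse complement.  A BED-style interval dict
    (node id -> list of (start, end)) overrides the sequence scan: any
    interval touching the terminal window sets the flag.
    """
    any_seq = any(n.sequence is not None for n in g.nodes.values())
    if not any_seq and bed is None:
        raise ValueError("telomere annotation needs node sequences or a BED sidecar")
    for n in g.nodes.values():
        w = min(window, n.length)
        if n.sequence is not None:
            n.telo_start = _motif_density(n.sequence[:w], motif) >= min_density
            n.telo_end = _motif_density(n.sequence[-w:], motif) >= min_density
        if bed and n.id in bed:
            for (s, e) in bed[n.id]:
                if s < w:
                    n.telo_start = True
                if e > n.length - w:
                    n.telo_end = True
    return g
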