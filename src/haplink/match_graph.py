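"""Homology Match Graph over long assembly-graph nodes.

Long nodes (> 200 kb by default) that share at least one sufficiently long
homology alignment are connected by an undirected edge whose weight is the
total number of bases the alignments cover on the two nodes.  Edges are then
classified: an edge that is a clear majority among the edges of one of its
endpoints, and long relative to the nodes it joins, links the two haplotypes
of the same locus; an edge that is not the best edge of either endpoint
links two repeats.  Everything else stays unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import pandas as pd

from .graph import AssemblyGraph
from .intervals import union_breadth
from .io import HomologyMatch

HAPLOTYPE = "haplotype"
REPEAT = "repeat"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class MatchEdge:
    node_a: str
    node_b: str
    weight: int
    klass: str = UNCLASSIFIED


@dataclass
class MatchGraph:
    nodes: set[str] = field(default_factory=set)
    edges: dict[tuple[str, str], MatchEdge] = field(default_factory=dict)
    min_node_len: int = 200_000
    min_match_len: int = 200_000

    def edge(self, a: str, b: str) -> Optional[MatchEdge]:
        return self.edges.get((min(a, b), max(a, b)))

    def incident(self, v: str) -> list[MatchEdge]:
        return [e for e in self.edges.values() if v in (e.node_a, e.node_b)]

    def haplotype_pairs(self) -> list[tuple[str, str]]:
        return sorted(
            (e.node_a, e.node_b) for e in self.edges.values() if e.klass == HAPLOTYPE
        )

    def repeat_nodes(self) -> set[str]:
        out = set()
        for e in self.edges.values():
            if e.klass == REPEAT:
                out.update((e.node_a, e.node_b))
        return out


def build_match_graph(
    g: AssemblyGraph,
    matches: Iterable[HomologyMatch],
    min_node_len: int = 200_000,
    min_match_len: int = 200_000,
    exclude: Iterable[str] = (),
) -> MatchGraph:
    """Build the Match Graph from homology alignments.

    Nodes with length <= ``min_node_len`` (and any in ``exclude``, e.g.
    coverage-flagged homozygous nodes) are ignored.  A node pair is connected
    when at least one alignment between them spans >= ``min_match_len`` on
    either node; the edge weight is the union breadth of all alignment
    intervals on node_a plus that on node_b (overlapping alignments are not
    double counted on a node).
    """
    excluded = set(exclude)

    def eligible(nid: str) -> bool:
        return nid in g and nid not in excluded and g.length(nid) > min_node_len

    per_pair: dict[tuple[str, str], list[HomologyMatch]] = {}
    for m in matches:
        if m.node_a == m.node_b:
            continue
        if not (eligible(m.node_a) and eligible(m.node_b)):
            continue
        a, b = sorted((m.node_a, m.node_b))
        per_pair.setdefault((a, b), []).append(m)

    mg = MatchGraph(min_node_len=min_node_len, min_match_len=min_match_len)
    mg.nodes = {nid for nid in g.nodes if eligible(nid)}
    for (a, b), ms in sorted(per_pair.items()):
        if not any(
            max(m.a_end - m.a_start, m.b_end - m.b_start) >= min_match_len for m in ms
        ):
            continue
        a_ivs, b_ivs = [], []
        for m in ms:
            if m.node_a == a:
                a_ivs.append((m.a_start, m.a_end))
                b_ivs.append((m.b_start, m.b_end))
            else:
                a_ivs.append((m.b_start, m.b_end))
                b_ivs.append((m.a_start, m.a_end))
        weight = union_breadth(a_ivs) + union_breadth(b_ivs)
        if weight > 0:
            mg.edges[(a, b)] = MatchEdge(a, b, weight)
    return mg


def classify_edges(
    mg: MatchGraph, g: AssemblyGraph, majority_ratio: float = 1.5
) -> MatchGraph:
    """Label every Match Graph edge haplotype, repeat or unclassified.

    At a node V, an incident edge is a haplotype candidate when its weight
    strictly exceeds ``majority_ratio`` times the second-best incident weight
    at V (0 for degree-1 nodes) and also exceeds one third of the length of
    at least one of the two nodes it joins.  An edge that is a candidate at
    either endpoint is a haplotype edge; an edge that is not the best edge
    of either endpoint is a repeat edge; the rest stay unclassified.
    Haplotype takes precedence on conflict.
    """
    incident: dict[str, list[MatchEdge]] = {v: [] for v in mg.nodes}
    for e in mg.edges.values():
        incident.setdefault(e.node_a, []).append(e)
        incident.setdefault(e.node_b, []).append(e)

    hap_edges: set[tuple[str, str]] = set()
    best_at: dict[str, int] = {}
    for v, edges in incident.items():
        if not edges:
            continue
        weights = sorted((e.weight for e in edges), reverse=True)
        best_at[v] = weights[0]
        second = weights[1] if len(weights) > 1 else 0
        for e in edges:
            long_enough = e.weight > min(g.length(e.node_a), g.length(e.node_b)) / 3
            if e.weight > majority_ratio * second and long_enough:
                hap_edges.add((e.node_a, e.node_b))

    out = MatchGraph(
        nodes=set(mg.nodes), min_node_len=mg.min_node_len, min_match_len=mg.min_match_len
    )
    for key, e in mg.edges.items():
        if key in hap_edges:
            klass = HAPLOTYPE
        elif e.weight < best_at.get(e.node_a, 0) and e.weight < best_at.get(e.node_b, 0):
            klass = REPEAT
        else:
            klass = UNCLASSIFIED
        out.edges[key] = replace(e, klass=klass)
    return out


def write_match_graph(mg: MatchGraph, path) -> None:
    df = pd.DataFrame(
        [(e.node_a, e.node_b, e.weight, e.klass) for e in mg.edges.values()],
        columns=["node_a", "node_b", "weight", "klass"],
    ).sort_values(["node_a", "node_b"])
    df.to_csv(path, sep="\t", index=False)


def read_match_graph(path) -> MatchGraph:
    df = pd.read_csv(path, sep="\t", dtype={"node_a": str, "node_b": str})
    mg = MatchGraph()
    for r in df.itertuples():
        e = MatchEdge(str(r.node_a), str(r.node_b), int(r.weight), str(r.klass))
        mg.edges[(e.node_a, e.node_b)] = e
        mg.nodes.update((e.node_a, e.node_b))
    return mg
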