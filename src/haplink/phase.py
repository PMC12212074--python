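"""Hi-C haplotype phasing of the assembly graph.

Long nodes and their filtered Hi-C link counts form the Hi-C Graph.  Node
pairs joined by a haplotype edge of the Match Graph get a large negative
weight (links between homologs are artifacts of mismapping, so a good
bipartition should cut them), nodes touching repeat edges are dropped, and
each diploid component is bipartitioned by a multi-restart Kernighan-Lin
heuristic minimising the cut weight over balanced splits.  Short nodes left
out of the Hi-C Graph are then assigned wherever a clear majority of their
Hi-C links points.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .graph import AssemblyGraph
from .io import HiCPairRecord
from .match_graph import MatchGraph

HAP1 = "hap1"
HAP2 = "hap2"
HOMOZYGOUS = "homozygous"
UNASSIGNED = "unassigned"

UNIQUE = "unique"
AMBIGUOUS = "ambiguous"


@dataclass
class Partition:
    """Node labels plus per-component bookkeeping."""

    assignment: dict[str, str] = field(default_factory=dict)
    component_of: dict[str, int] = field(default_factory=dict)
    cut_weight: dict[int, float] = field(default_factory=dict)
    seed_of: dict[int, int] = field(default_factory=dict)

    def label(self, node: str) -> str:
        return self.assignment.get(node, UNASSIGNED)

    def nodes_with(self, label: str) -> set[str]:
        return {n for n, l in self.assignment.items() if l == label}


# ---------------------------------------------------------------------------
# Coverage-based unique / homozygous classification


def classify_nodes_by_coverage(
    g: AssemblyGraph,
    long_node: int = 50_000,
    long_low: float = 0.4,
    short_low: float = 0.7,
    short_high: float = 1.3,
    upper_ratio: float = 1.75,
) -> dict[str, str]:
    """Classify nodes as unique / homozygous-candidate / ambiguous by depth.

    The baseline is the median coverage of nodes longer than ``long_node``
    within the node's connected component (global median of such nodes when
    the component has none).  Long nodes tolerate a deeper coverage drop
    (down to 40% of baseline) than short ones (70%-130%); anything above
    ``upper_ratio`` times baseline is a homozygous/repeat candidate.
    """
    covs = [n.coverage for n in g.nodes.values()]
    if not covs or all(c == 0 for c in covs):
        raise ValueError("cannot classify by coverage: all node coverages are zero")
    global_long = [n.coverage for n in g.nodes.values() if n.length > long_node]
    global_baseline = float(np.median(global_long)) if global_long else float(np.median(covs))
    out: dict[str, str] = {}
    for comp in g.components():
        comp_long = [g.node(v).coverage for v in comp if g.length(v) > long_node]
        baseline = float(np.median(comp_long)) if comp_long else global_baseline
        if baseline == 0:
            baseline = global_baseline
        for v in sorted(comp):
            c = g.node(v).coverage
            if c > upper_ratio * baseline:
                out[v] = HOMOZYGOUS
            elif g.length(v) > long_node:
                out[v] = UNIQUE if c >= long_low * baseline else AMBIGUOUS
            else:
                out[v] = UNIQUE if short_low * baseline <= c <= short_high * baseline else AMBIGUOUS
    return out


# ---------------------------------------------------------------------------
# Hi-C Graph construction


def qualifying_pairs(pairs: Iterable[HiCPairRecord]) -> dict[str, tuple[str, str]]:
    """Pairs usable for phasing: both sides uniquely mapped (mapq > 0,
    a single equivalent mapping).  Returns pair_id -> (node1, node2)."""
    by_pair: dict[str, dict[int, list[HiCPairRecord]]] = {}
    for r in pairs:
        by_pair.setdefault(r.pair_id, {}).setdefault(r.side, []).append(r)
    out = {}
    for pid, sides in by_pair.items():
        if set(sides) != {1, 2}:
            continue
        if any(len(recs) != 1 for recs in sides.values()):
            continue
        r1, r2 = sides[1][0], sides[2][0]
        if r1.mapq > 0 and r2.mapq > 0 and r1.n_equiv == 1 and r2.n_equiv == 1:
            out[pid] = (r1.node_id, r2.node_id)
    return out


def split_components(g: AssemblyGraph, mg: MatchGraph) -> list[set[str]]:
    """Diploid components: connected components of the assembly-graph
    adjacency supplemented with the haplotype edges of the Match Graph."""
    u = g.undirected()
    for a, b in mg.haplotype_pairs():
        if a in g and b in g:
            u.add_edge(a, b)
    return sorted((set(c) for c in nx.connected_components(u)), key=lambda c: min(c))


def build_hic_graph(
    g: AssemblyGraph,
    mg: MatchGraph,
    pairs: Iterable[HiCPairRecord],
    min_node_len: int = 200_000,
    negative_multiplier: float = 10.0,
    components: Optional[Sequence[set[str]]] = None,
    exclude: Iterable[str] = (),
) -> nx.Graph:
    """Build the weighted Hi-C Graph over long nodes.

    Edge weight is the count of qualifying pairs linking two nodes.  Nodes
    incident to a repeat Match edge — and any in ``exclude``, e.g. nodes the
    coverage screen flags as homozygous — are removed outright; homolog
    pairs (haplotype Match edges) get weight -negative_multiplier * the
    maximum positive weight of their component (evaluated before the
    negatives are injected, floored at 1 so homologs separate even in
    link-free components).  Hi-C links crossing the supplied diploid
    components are discarded; self-links are never counted.
    """
    drop = mg.repeat_nodes() | set(exclude)
    keep = {v for v in g.nodes if g.length(v) > min_node_len and v not in drop}
    comp_of: Optional[dict[str, int]] = None
    if components is not None:
        comp_of = {v: i for i, c in enumerate(components) for v in c}

    h = nx.Graph()
    h.add_nodes_from(sorted(keep))
    for n1, n2 in qualifying_pairs(pairs).values():
        if n1 == n2 or n1 not in keep or n2 not in keep:
            continue
        if comp_of is not None and comp_of.get(n1) != comp_of.get(n2):
            continue
        if h.has_edge(n1, n2):
            h[n1][n2]["weight"] += 1.0
            h[n1][n2]["hic_count"] += 1
        else:
            h.add_edge(n1, n2, weight=1.0, hic_count=1, forced_negative=False)

    # Force large negative weights between homolog pairs, per component.
    if comp_of is not None:
        groups: dict[int, list[str]] = {}
        for v in h.nodes:
            groups.setdefault(comp_of.get(v, -1), []).append(v)
        comp_sets = [set(vs) for _, vs in sorted(groups.items())]
    else:
        comp_sets = [set(h.nodes)]
    for comp in comp_sets:
        pos = [
            d["weight"]
            for u, v, d in h.edges(data=True)
            if u in comp and v in comp and d["weight"] > 0
        ]
        max_w = max(pos) if pos else 1.0
        for a, b in mg.haplotype_pairs():
            if a in comp and b in comp:
                h.add_edge(
                    a,
                    b,
                    weight=-negative_multiplier * max_w,
                    hic_count=h[a][b]["hic_count"] if h.has_edge(a, b) else 0,
                    forced_negative=True,
                )
    return h


# ---------------------------------------------------------------------------
# Kernighan-Lin bipartition


def cut_weight(w: np.ndarray, sides: np.ndarray) -> float:
    """Total weight of edges between the two sides (sides in {+1,-1}).

    ``w`` is the full symmetric matrix, so both the total and the quadratic
    form count every edge twice.
    """
    return float((w.sum() - sides @ w @ sides) / 4.0)


def _balanced_random_sides(rng: np.random.Generator, restarts: int, n: int) -> np.ndarray:
    base = np.ones(n)
    base[: n // 2] = -1.0
    sides = np.tile(base, (restarts, 1))
    perm = rng.permuted(np.tile(np.arange(n), (restarts, 1)), axis=1)
    return np.take_along_axis(sides, perm, axis=1)


def kernighan_lin(
    w: np.ndarray,
    restarts: int = 1000,
    max_passes: int = 10_000,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, float]:
    """Multi-restart Kernighan-Lin minimum-weight balanced bipartition.

    ``w`` is a symmetric weight matrix (zero diagonal; negative entries
    allowed).  Each restart starts from a balanced random split and runs
    gain-sorted swap passes with rollback until a pass yields no improvement
    (or the pass budget runs out); all restarts advance in lock-step as
    vectorised array operations.  Returns the best (+1/-1 side vector, cut
    weight); for odd n a zero-weight phantom slot balances the split and is
    stripped from the result.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n_orig = w.shape[0]
    if n_orig == 0:
        return np.empty(0), 0.0
    if n_orig == 1:
        return np.ones(1), 0.0
    w = np.asarray(w, dtype=float)
    if n_orig % 2 == 1:
        w = np.pad(w, ((0, 1), (0, 1)))
    n = w.shape[0]
    n2 = n // 2

    sides = _balanced_random_sides(rng, restarts, n)
    rows = np.arange(restarts)
    active = np.ones(restarts, dtype=bool)
    for _ in range(max_passes):
        if not active.any():
            break
        s = sides.copy()
        locked = np.zeros((restarts, n), dtype=bool)
        gains = np.zeros((restarts, n2))
        swaps_a = np.zeros((restarts, n2), dtype=int)
        swaps_b = np.zeros((restarts, n2), dtype=int)
        for step in range(n2):
            d = -s * (s @ w)  # external minus internal weight per node
            pair_gain = d[:, :, None] + d[:, None, :] - 2.0 * w[None, :, :]
            ok = (
                (s[:, :, None] > 0)
                & (s[:, None, :] < 0)
                & ~locked[:, :, None]
                & ~locked[:, None, :]
            )
            pair_gain = np.where(ok, pair_gain, -np.inf)
            flat = pair_gain.reshape(restarts, -1)
            idx = np.argmax(flat, axis=1)
            a, b = np.unravel_index(idx, (n, n))
            gains[:, step] = flat[rows, idx]
            swaps_a[:, step], swaps_b[:, step] = a, b
            s[rows, a] = -1.0
            s[rows, b] = 1.0
            locked[rows, a] = True
            locked[rows, b] = True
        cum = np.cumsum(gains, axis=1)
        best_k = np.argmax(cum, axis=1)
        improved = active & (cum[rows, best_k] > 1e-9)
        if not improved.any():
            break
        for step in range(n2):
            apply = improved & (best_k >= step)
            if apply.any():
                r = rows[apply]
                sides[r, swaps_a[apply, step]] = -1.0
                sides[r, swaps_b[apply, step]] = 1.0
        active = improved
    w_sum = w.sum()
    cuts = (w_sum - np.einsum("ri,ij,rj->r", sides, w, sides)) / 4.0
    best = int(np.argmin(cuts))
    return sides[best, :n_orig], float(cuts[best])


def _component_seed(seed: int, comp_nodes: Iterable[str]) -> int:
    """Stable per-component child seed, independent of iteration order."""
    key = f"{seed}:{','.join(sorted(comp_nodes))}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


def kl_bipartition(
    h: nx.Graph,
    comp_nodes: Iterable[str],
    restarts: int = 1000,
    iters: int = 10_000,
    seed: int = 0,
    component_id: int = 0,
    partition: Optional[Partition] = None,
) -> Partition:
    """Bipartition the Hi-C Graph restricted to one component.

    The best balanced split over all restarts labels the nodes hap1/hap2;
    results are deterministic given the seed, via a per-component child seed
    derived from the sorted node ids.
    """
    if partition is None:
        partition = Partition()
    nodes = sorted(v for v in comp_nodes if v in h)
    if not nodes:
        return partition
    child_seed = _component_seed(seed, nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    w = np.zeros((len(nodes), len(nodes)))
    for u, v, d in h.subgraph(nodes).edges(data=True):
        w[idx[u], idx[v]] = w[idx[v], idx[u]] = d["weight"]
    sides, cut = kernighan_lin(
        w, restarts=restarts, max_passes=iters, rng=np.random.default_rng(child_seed)
    )
    for v, s in zip(nodes, sides):
        partition.assignment[v] = HAP1 if s > 0 else HAP2
        partition.component_of[v] = component_id
    partition.cut_weight[component_id] = cut
    partition.seed_of[component_id] = child_seed
    return partition


# ---------------------------------------------------------------------------
# Leftover short-node assignment


def assign_short_nodes(
    partition: Partition,
    pairs: Iterable[HiCPairRecord],
    g: AssemblyGraph,
    ratio: float = 2.5,
    homozygous: Iterable[str] = (),
) -> Partition:
    """Assign nodes absent from the Hi-C Graph by majority of Hi-C links.

    A node gets hap1/hap2 when its qualifying-link count to that side is at
    least ``ratio`` times the count to the other side (and nonzero);
    otherwise it stays unassigned.  Coverage-flagged homozygous candidates
    are labeled homozygous instead.
    """
    hom = set(homozygous)
    counts: dict[str, dict[str, int]] = {}
    for n1, n2 in qualifying_pairs(pairs).values():
        for a, b in ((n1, n2), (n2, n1)):
            lbl = partition.assignment.get(b)
            if a not in partition.assignment and lbl in (HAP1, HAP2):
                counts.setdefault(a, {HAP1: 0, HAP2: 0})[lbl] += 1
    for v in sorted(g.nodes):
        if v in partition.assignment:
            continue
        if v in hom:
            partition.assignment[v] = HOMOZYGOUS
            continue
        c = counts.get(v, {HAP1: 0, HAP2: 0})
        best, second = (HAP1, HAP2) if c[HAP1] >= c[HAP2] else (HAP2, HAP1)
        if c[best] > 0 and c[best] >= ratio * c[second]:
            partition.assignment[v] = best
        else:
            partition.assignment[v] = UNASSIGNED
    return partition


def write_labels(partition: Partition, path) -> None:
    rows = [
        (
            v,
            partition.assignment[v],
            partition.component_of.get(v, -1),
            partition.cut_weight.get(partition.component_of.get(v, -1), 0.0),
        )
        for v in sorted(partition.assignment)
    ]
    pd.DataFrame(rows, columns=["node", "label", "component", "cut_weight"]).to_csv(
        path, sep="\t", index=False
    )


def read_labels(path) -> Partition:
    df = pd.read_csv(path, sep="\t", dtype={"node": str}, comment="#")
    p = Partition()
    for r in df.itertuples():
        p.assignment[str(r.node)] = str(r.label)
        p.component_of[str(r.node)] = int(r.component)
        p.cut_weight[int(r.component)] = float(r.cut_weight)
    return p
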