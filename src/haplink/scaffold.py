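"""Hi-C scaffolding of haplotype paths.

Link strength between two path ends is accumulated from proximity-ligation
pairs mapped within a fixed-length window at each end (5 Mb or half the path,
whichever is smaller).  A primary weight counts every retained pair at
1/(m1*m2) per induced link, where m1, m2 are the mapping multiplicities of
its two sides; a secondary weight counts only unique-unique pairs.
Multiplicative bonuses reward ends that are close in the assembly graph and
end pairs whose flanks are homologous to nearby positions on a third path.
Scaffolds are then chained from mutually best end pairs, with a clear-
majority margin, never extending through a telomere; a telomere-informed
rescue handles components where one haplotype is telomere-to-telomere and
the other is missing only a small telomeric path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd

from .graph import PLUS, AssemblyGraph
from .io import HiCPairRecord, HomologyMatch
from .paths import Gap, HaplotypePath

PREFIX = "prefix"
SUFFIX = "suffix"

End = tuple[str, str]  # (path name, prefix/suffix)


@dataclass
class JoinCandidate:
    end1: End
    end2: End
    primary: float = 0.0
    secondary: float = 0.0
    bonuses: set[str] = field(default_factory=set)

    @property
    def orientation(self) -> str:
        o1 = "fwd" if self.end1[1] == SUFFIX else "rev"
        o2 = "fwd" if self.end2[1] == PREFIX else "rev"
        return f"{o1}-{o2}"


# ---------------------------------------------------------------------------
# End windows and coordinate projection


@dataclass
class PathLayout:
    """Node placements of a path in path coordinates (overlaps ignored)."""

    path: HaplotypePath
    length: int
    # node id -> list of (path_start, path_end, orientation)
    placements: dict[str, list[tuple[int, int, str]]]
    window_len: int

    def end_interval(self, end: str) -> tuple[int, int]:
        if end == PREFIX:
            return (0, self.window_len)
        return (self.length - self.window_len, self.length)

    def terminal_node(self, end: str) -> str:
        nodes = self.path.node_steps()
        return nodes[0][0] if end == PREFIX else nodes[-1][0]

    def window_nodes(self, end: str) -> list[tuple[str, int, int]]:
        """Nodes overlapping the window, as (node, path_start, path_end)."""
        ws, we = self.end_interval(end)
        out = []
        for nid, places in self.placements.items():
            for (s, e, _) in places:
                if s < we and e > ws:
                    out.append((nid, max(s, ws), min(e, we)))
        return sorted(out)


def layout_path(
    p: HaplotypePath, g: AssemblyGraph, window_cap: int = 5_000_000
) -> PathLayout:
    placements: dict[str, list[tuple[int, int, str]]] = {}
    off = 0
    for step in p.steps:
        if isinstance(step, Gap):
            off += step.est_len
            continue
        nid, orient = step
        ln = g.length(nid)
        placements.setdefault(nid, []).append((off, off + ln, orient))
        off += ln
    window = min(window_cap, off // 2)
    return PathLayout(p, off, placements, window)


def project_position(layout: PathLayout, node: str, pos: int) -> list[int]:
    """Path coordinates of a node-local position (forward node strand)."""
    out = []
    for (s, e, orient) in layout.placements.get(node, []):
        if orient == PLUS:
            out.append(s + pos)
        else:
            out.append(e - 1 - pos)
    return out


# ---------------------------------------------------------------------------
# Pair filtering and link weights


def filter_pairs_for_scaffolding(
    pairs: Iterable[HiCPairRecord], max_equiv: int = 5
) -> dict[str, tuple[list[HiCPairRecord], list[HiCPairRecord]]]:
    """Retain pairs usable for scaffolding.

    A pair is dropped when either side has more than ``max_equiv`` equally
    scoring mappings or when the two sides share a mapped node.  Returns
    pair_id -> (side-1 records, side-2 records).
    """
    by_pair: dict[str, dict[int, list[HiCPairRecord]]] = {}
    for r in pairs:
        by_pair.setdefault(r.pair_id, {}).setdefault(r.side, []).append(r)
    out = {}
    for pid in sorted(by_pair):
        sides = by_pair[pid]
        if set(sides) != {1, 2}:
            continue
        r1, r2 = sides[1], sides[2]
        if any(r.n_equiv > max_equiv for r in r1 + r2):
            continue
        if {r.node_id for r in r1} & {r.node_id for r in r2}:
            continue
        out[pid] = (r1, r2)
    return out


def induced_links(
    side1: Sequence[HiCPairRecord], side2: Sequence[HiCPairRecord]
) -> list[tuple[HiCPairRecord, HiCPairRecord, float]]:
    """All m1*m2 links a retained pair induces, each weighted 1/(m1*m2).

    The per-pair weights always sum to exactly 1.
    """
    m1, m2 = len(side1), len(side2)
    w = 1.0 / (m1 * m2)
    return [(a, b, w) for a in side1 for b in side2]


def _canonical(c1: End, c2: End) -> tuple[End, End]:
    return (c1, c2) if c1 <= c2 else (c2, c1)


def compute_link_weights(
    layouts: dict[str, PathLayout],
    retained: dict[str, tuple[list[HiCPairRecord], list[HiCPairRecord]]],
) -> dict[tuple[End, End], JoinCandidate]:
    """Accumulate primary/secondary link weights between all path-end pairs."""

    def hit_ends(rec: HiCPairRecord) -> list[End]:
        ends = []
        for name, lay in layouts.items():
            for coord in project_position(lay, rec.node_id, rec.pos):
                for end in (PREFIX, SUFFIX):
                    ws, we = lay.end_interval(end)
                    if ws <= coord < we:
                        ends.append((name, end))
        return ends

    cands: dict[tuple[End, End], JoinCandidate] = {}
    for pid, (side1, side2) in retained.items():
        unique = len(side1) == 1 and len(side2) == 1
        for rec1, rec2, w in induced_links(side1, side2):
            for e1 in hit_ends(rec1):
                for e2 in hit_ends(rec2):
                    if e1[0] == e2[0]:
                        continue
                    key = _canonical(e1, e2)
                    c = cands.get(key)
                    if c is None:
                        c = cands[key] = JoinCandidate(*key)
                    c.primary += w
                    if unique:
                        c.secondary += 1.0
    return cands


# ---------------------------------------------------------------------------
# Bonuses


def graph_distance_between_nodes(
    g: AssemblyGraph, a: str, b: str, cutoff: int
) -> Optional[int]:
    """Total length of intervening nodes on the shortest walk from a to b
    (0 when adjacent); None when farther than ``cutoff`` or disconnected."""
    if a == b:
        return 0
    u = g.undirected()
    if a not in u or b not in u:
        return None
    try:
        d = nx.dijkstra_path_length(
            u, a, b, weight=lambda x, y, _: g.length(y)
        )
    except nx.NetworkXNoPath:
        return None
    d -= g.length(b)  # the target's own length is not intervening
    return d if d < cutoff else None


def _projected_hits(
    layout: PathLayout,
    end: str,
    matches: Sequence[HomologyMatch],
    other_layouts: dict[str, PathLayout],
    exclude: set[str],
) -> dict[str, list[tuple[int, int]]]:
    """Intervals on third paths homologous to this end's window nodes."""
    window_nodes = {nid for nid, _, _ in layout.window_nodes(end)}
    hits: dict[str, list[tuple[int, int]]] = {}
    for m in matches:
        for here, there, ts, te in (
            (m.node_a, m.node_b, m.b_start, m.b_end),
            (m.node_b, m.node_a, m.a_start, m.a_end),
        ):
            if here not in window_nodes:
                continue
            for name, lay in other_layouts.items():
                if name in exclude:
                    continue
                for (s, e, orient) in lay.placements.get(there, []):
                    if orient == PLUS:
                        iv = (s + ts, s + te)
                    else:
                        iv = (e - te, e - ts)
                    hits.setdefault(name, []).append(iv)
    return hits


def apply_bonuses(
    cands: dict[tuple[End, End], JoinCandidate],
    g: AssemblyGraph,
    layouts: dict[str, PathLayout],
    matches: Sequence[HomologyMatch] = (),
    prox_bonus: float = 3.0,
    hom_bonus: float = 5.0,
    prox_dist: int = 500_000,
    homology_gap: int = 1_000_000,
) -> dict[tuple[End, End], JoinCandidate]:
    """Multiply link weights for graph-proximal ends and for end pairs
    homologous to nearby intervals on a shared third path.  Both bonuses
    apply to the primary and the secondary weight and compound when both
    conditions hold."""
    for c in cands.values():
        l1, l2 = layouts[c.end1[0]], layouts[c.end2[0]]
        t1, t2 = l1.terminal_node(c.end1[1]), l2.terminal_node(c.end2[1])
        d = graph_distance_between_nodes(g, t1, t2, prox_dist)
        if d is not None and d < prox_dist:
            c.bonuses.add("graph_proximity")
        if matches:
            exclude = {c.end1[0], c.end2[0]}
            h1 = _projected_hits(l1, c.end1[1], matches, layouts, exclude)
            h2 = _projected_hits(l2, c.end2[1], matches, layouts, exclude)
            for third in set(h1) & set(h2):
                gap = min(
                    max(a_s - b_e, b_s - a_e, 0)
                    for (a_s, a_e) in h1[third]
                    for (b_s, b_e) in h2[third]
                )
                if gap <= homology_gap:
                    c.bonuses.add("homology")
                    break
        factor = 1.0
        if "graph_proximity" in c.bonuses:
            factor *= prox_bonus
        if "homology" in c.bonuses:
            factor *= hom_bonus
        c.primary *= factor
        c.secondary *= factor
    return cands


# ---------------------------------------------------------------------------
# Join selection


def _telomeric_ends(paths: Sequence[HaplotypePath]) -> set[End]:
    out = set()
    for p in paths:
        if p.telo_left:
            out.add((p.name, PREFIX))
        if p.telo_right:
            out.add((p.name, SUFFIX))
    return out


def select_joins(
    cands: dict[tuple[End, End], JoinCandidate],
    paths: Sequence[HaplotypePath],
    ratio: float = 1.5,
) -> list[JoinCandidate]:
    """Accept mutually best clear-majority joins, iterated to a fixpoint.

    An end with a telomere is never extended.  A join is accepted when it is
    the best candidate at both of its ends by more than ``ratio`` times the
    second-best.  Primary weights decide; secondary weights are consulted
    only in rounds where the primary weights produce no mutual pair.  All
    accepted joins of a round apply simultaneously; ends are consumed and
    joins that would put a path twice in one scaffold (circles, palindromes)
    are rejected.
    """
    blocked = _telomeric_ends(paths)
    free: set[End] = set()
    for key in cands:
        free.update(key)
    free -= blocked
    comp: dict[str, str] = {p.name: p.name for p in paths}

    def find(x: str) -> str:
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    accepted: list[JoinCandidate] = []
    while True:
        live = [
            c
            for c in cands.values()
            if c.end1 in free and c.end2 in free and find(c.end1[0]) != find(c.end2[0])
        ]
        round_joins: list[JoinCandidate] = []
        for weight_of in (lambda c: c.primary, lambda c: c.secondary):
            per_end: dict[End, list[JoinCandidate]] = {}
            for c in live:
                if weight_of(c) <= 0:
                    continue
                per_end.setdefault(c.end1, []).append(c)
                per_end.setdefault(c.end2, []).append(c)

            def clear_best(end: End, c: JoinCandidate) -> bool:
                ws = sorted((weight_of(x) for x in per_end[end]), reverse=True)
                second = ws[1] if len(ws) > 1 else 0.0
                return weight_of(c) == ws[0] and weight_of(c) > ratio * second

            round_joins = [
                c for c in live
                if weight_of(c) > 0 and clear_best(c.end1, c) and clear_best(c.end2, c)
            ]
            if round_joins:
                break
        if not round_joins:
            break
        # Apply simultaneously; drop later joins that conflict with earlier ones.
        for c in sorted(round_joins, key=lambda c: (-c.primary, c.end1, c.end2)):
            if c.end1 not in free or c.end2 not in free:
                continue
            if find(c.end1[0]) == find(c.end2[0]):
                continue
            accepted.append(c)
            free.discard(c.end1)
            free.discard(c.end2)
            comp[find(c.end1[0])] = find(c.end2[0])
    return accepted


# ---------------------------------------------------------------------------
# Telomere-informed rescue


def telomere_rescue(
    g: AssemblyGraph,
    paths: Sequence[HaplotypePath],
    matches: Sequence[HomologyMatch] = (),
    prox_dist: int = 500_000,
    big_path: int = 1_000_000,
) -> list[JoinCandidate]:
    """Rescue a missing telomeric stub on one haplotype.

    In an assembly-graph component where one path is telomere-to-telomere
    and its homologous partner has a telomere on only one end, a small path
    carrying a telomere on one end is joined onto the broken partner when it
    lies within ``prox_dist`` in the graph and no other path holds more than
    ``big_path`` bp of the component.
    """
    by_name = {p.name: p for p in paths}
    node_paths: dict[str, set[str]] = {}
    for p in paths:
        for nid in p.node_ids():
            node_paths.setdefault(nid, set()).add(p.name)
    homologous: dict[str, set[str]] = {}
    for m in matches:
        for pa in node_paths.get(m.node_a, ()):
            for pb in node_paths.get(m.node_b, ()):
                if pa != pb:
                    homologous.setdefault(pa, set()).add(pb)
                    homologous.setdefault(pb, set()).add(pa)

    joins: list[JoinCandidate] = []
    used: set[str] = set()
    for comp in g.components():
        comp_len: dict[str, int] = {}
        for p in paths:
            ln = sum(g.length(n) for n in p.node_ids() if n in comp)
            if ln:
                comp_len[p.name] = ln
        t2t = sorted(
            n for n in comp_len if by_name[n].telo_left and by_name[n].telo_right
        )
        for p1 in t2t:
            for p2 in sorted(homologous.get(p1, ())):
                if p2 not in comp_len or p2 in used:
                    continue
                b = by_name[p2]
                if b.telo_left == b.telo_right:
                    continue  # need exactly one telomeric end
                open_end = (p2, SUFFIX) if b.telo_left else (p2, PREFIX)
                stubs = [
                    n
                    for n in comp_len
                    if n not in (p1, p2)
                    and by_name[n].telo_left != by_name[n].telo_right
                    and n not in used
                ]
                others = [
                    n
                    for n in comp_len
                    if n not in (p1, p2) and comp_len[n] > big_path
                ]
                for pt in sorted(stubs, key=lambda n: -comp_len[n]):
                    if [o for o in others if o != pt]:
                        break  # condition (3): another large path in the component
                    pt_path = by_name[pt]
                    pt_end = (pt, SUFFIX) if pt_path.telo_right else (pt, PREFIX)
                    # join onto the non-telomeric end of p_t; telomere faces outward
                    join_end = (pt, PREFIX if pt_end[1] == SUFFIX else SUFFIX)
                    t_open = layout_terminal(by_name[p2], open_end[1])
                    t_stub = layout_terminal(pt_path, join_end[1])
                    d = graph_distance_between_nodes(g, t_open, t_stub, prox_dist)
                    if d is None or d >= prox_dist:
                        continue
                    joins.append(JoinCandidate(open_end, join_end))
                    used.update((p2, pt))
                    break
    return joins


def layout_terminal(p: HaplotypePath, end: str) -> str:
    nodes = p.node_steps()
    return nodes[0][0] if end == PREFIX else nodes[-1][0]


# ---------------------------------------------------------------------------
# Applying joins


def apply_joins(
    paths: Sequence[HaplotypePath],
    joins: Sequence[JoinCandidate],
    gap_len: int = 100_000,
    rdna_nodes: Iterable[str] = (),
) -> list[HaplotypePath]:
    """Merge joined paths into scaffolds, inserting a reasoned gap at each
    junction (``rdna_like`` when both flanking nodes carry an rDNA-proximity
    tag, ``scaffold_join`` otherwise).  Unjoined paths pass through."""
    rdna = set(rdna_nodes)
    by_name = {p.name: p for p in paths}
    end_join: dict[End, End] = {}
    for j in joins:
        end_join[j.end1] = j.end2
        end_join[j.end2] = j.end1

    def other_end(e: End) -> End:
        return (e[0], PREFIX if e[1] == SUFFIX else SUFFIX)

    out: list[HaplotypePath] = []
    done: set[str] = set()
    k = 0
    for p in paths:
        if p.name in done:
            continue
        if (p.name, PREFIX) not in end_join and (p.name, SUFFIX) not in end_join:
            out.append(p)
            done.add(p.name)
            continue
        # walk to the chain's start
        cur = (p.name, PREFIX)
        seen = {p.name}
        while cur in end_join:
            nxt = other_end(end_join[cur])
            if nxt[0] in seen:
                break
            seen.add(nxt[0])
            cur = nxt
        # cur is the entry end of the first path in the chain
        k += 1
        steps: list = []
        haps = set()
        chain_start = cur
        first_path = by_name[cur[0]]
        oriented_first = first_path if cur[1] == PREFIX else first_path.reversed()
        telo_left = oriented_first.telo_left
        telo_right = oriented_first.telo_right
        while True:
            name, entry = cur
            path = by_name[name]
            oriented = path if entry == PREFIX else path.reversed()
            if steps:
                prev_node = [s for s in steps if not isinstance(s, Gap)][-1][0]
                next_node = oriented.node_steps()[0][0]
                reason = (
                    "rdna_like" if prev_node in rdna and next_node in rdna else "scaffold_join"
                )
                steps.append(Gap(reason, gap_len))
            steps.extend(oriented.steps)
            haps.add(path.haplotype)
            done.add(name)
            telo_right = oriented.telo_right
            exit_end = other_end(cur)
            if exit_end not in end_join:
                break
            cur = end_join[exit_end]
        hap = haps.pop() if len(haps) == 1 else "na"
        out.append(
            HaplotypePath(f"scaffold_{k}", steps, hap, telo_left, telo_right)
        )
    return out


def write_join_evidence(joins: Sequence[JoinCandidate], path) -> None:
    rows = [
        (
            j.end1[0],
            j.end1[1],
            j.end2[0],
            j.end2[1],
            j.orientation,
            j.primary,
            j.secondary,
            ";".join(sorted(j.bonuses)) or ".",
        )
        for j in joins
    ]
    pd.DataFrame(
        rows,
        columns=[
            "path1", "end1", "path2", "end2", "orientation",
            "primary_weight", "secondary_weight", "bonuses",
        ],
    ).to_csv(path, sep="\t", index=False)


def scaffolds_to_agp_parts(
    scaffolds: Sequence[HaplotypePath], g: AssemblyGraph
) -> list[tuple[str, list]]:
    out = []
    for s in scaffolds:
        parts: list = []
        for step in s.steps:
            if isinstance(step, Gap):
                parts.append(("U", step.reason))
            else:
                nid, orient = step
                parts.append(("W", nid, g.length(nid), orient))
        out.append((s.name, parts))
    return out
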