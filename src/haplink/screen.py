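"""Post-assembly screening: drop unconnected short nodes, remove contigs
matching screening references (mitochondrion, rDNA, EBV, or any user set),
expand the removal through the graph neighbourhood, and report a trimmed
exemplar sequence per screening target.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .graph import AssemblyGraph
from .intervals import union_breadth


@dataclass(frozen=True)
class ScreenHit:
    """One alignment of a contig against a screening target."""

    contig: str
    target: str
    start: int
    end: int
    identity_est: float


def hits_from_paf_matches(matches, target_names: set[str]) -> list[ScreenHit]:
    """Interpret homology matches as contig-vs-screen hits: the side whose
    name is a screening target is the target, the other the contig."""
    hits = []
    for m in matches:
        if m.node_a in target_names and m.node_b not in target_names:
            hits.append(ScreenHit(m.node_b, m.node_a, m.b_start, m.b_end, m.identity_est))
        elif m.node_b in target_names and m.node_a not in target_names:
            hits.append(ScreenHit(m.node_a, m.node_b, m.a_start, m.a_end, m.identity_est))
    return hits


def drop_isolated(g: AssemblyGraph, min_len: int = 100_000) -> tuple[AssemblyGraph, list[str]]:
    """Remove nodes with no link to any other node and length < ``min_len``.

    Returns the filtered graph and the removed node ids.
    """
    removed = sorted(
        v for v in g.nodes if g.degree(v) == 0 and g.length(v) < min_len
    )
    out = g.copy()
    out.remove_nodes(removed)
    return out, removed


def call_matches(
    hits: Iterable[ScreenHit],
    contig_lengths: Mapping[str, int],
    min_identity: float = 0.975,
    min_hit_fraction: float = 0.10,
    min_breadth: float = 0.50,
) -> set[str]:
    """Contigs matching the screening set.

    Hits below ``min_identity`` or shorter than ``min_hit_fraction`` of the
    contig are discarded; a contig matches when the union of the remaining
    hits covers at least ``min_breadth`` of its length.
    """
    per_contig: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        ln = contig_lengths[h.contig]
        if h.identity_est < min_identity:
            continue
        if (h.end - h.start) < min_hit_fraction * ln:
            continue
        per_contig.setdefault(h.contig, []).append((h.start, h.end))
    return {
        c
        for c, ivs in per_contig.items()
        if union_breadth(ivs) >= min_breadth * contig_lengths[c]
    }


def expand_matches(
    g: AssemblyGraph, matched: set[str], hops: int = 4, len_ratio: float = 4.0
) -> set[str]:
    """Extend the matched set through the graph.

    Breadth-first from the matched nodes, up to ``hops`` hops; a neighbour
    joins when it is at most ``len_ratio`` times longer than the matched
    node it was reached from (newly added nodes expand further within the
    hop budget, compared against their own length).
    """
    u = g.undirected()
    out = set(matched)
    queue = deque((v, 0) for v in sorted(matched) if v in u)
    while queue:
        v, depth = queue.popleft()
        if depth >= hops:
            continue
        for nb in sorted(u.neighbors(v)):
            if nb in out:
                continue
            if g.length(nb) <= len_ratio * g.length(v):
                out.add(nb)
                queue.append((nb, depth + 1))
    return out


def trim_terminal_redundancy(seq: str, min_overlap: int = 1_000) -> str:
    """Remove circularity-induced duplicated sequence from a linear contig.

    While the contig's start exactly repeats at its end over more than
    ``min_overlap`` bp, one copy of the repeat is removed.
    """
    while True:
        n = len(seq)
        best = 0
        for k in range(n // 2, min_overlap, -1):
            if seq[:k] == seq[n - k :]:
                best = k
                break
        if best <= min_overlap:
            return seq
        seq = seq[: n - best]


def pick_exemplar(
    matched: Iterable[str],
    hits: Iterable[ScreenHit],
    sequences: Mapping[str, str],
    coverages: Mapping[str, float],
    min_identity: float = 0.975,
    min_hit_fraction: float = 0.10,
    high_breadth: float = 0.90,
    trim_overlap: int = 1_000,
) -> Optional[tuple[str, str]]:
    """Representative sequence among the matched contigs of one target.

    When two or more contigs are covered by filtered hits over more than
    ``high_breadth`` of their length, the one with the highest read
    coverage wins; otherwise the largest covered fraction wins.  The chosen
    sequence is trimmed of terminal self-redundancy longer than
    ``trim_overlap``.  Returns (contig id, trimmed sequence).
    """
    matched = sorted(set(matched))
    if not matched:
        return None
    breadth: dict[str, float] = {}
    per_contig: dict[str, list[tuple[int, int]]] = {c: [] for c in matched}
    for h in hits:
        if h.contig not in per_contig or h.identity_est < min_identity:
            continue
        if (h.end - h.start) < min_hit_fraction * len(sequences[h.contig]):
            continue
        per_contig[h.contig].append((h.start, h.end))
    for c in matched:
        ln = len(sequences[c])
        breadth[c] = union_breadth(per_contig[c]) / ln if ln else 0.0
    high = [c for c in matched if breadth[c] > high_breadth]
    if len(high) >= 2:
        pick = max(high, key=lambda c: (coverages.get(c, 0.0), breadth[c], c))
    else:
        pick = max(matched, key=lambda c: (breadth[c], len(sequences[c]), c))
    return pick, trim_terminal_redundancy(sequences[pick], trim_overlap)


def screen_assembly(
    g: AssemblyGraph,
    sequences: Mapping[str, str],
    hits: Sequence[ScreenHit],
    min_isolated_len: int = 100_000,
    min_identity: float = 0.975,
    min_hit_fraction: float = 0.10,
    min_breadth: float = 0.50,
    hops: int = 4,
    len_ratio: float = 4.0,
    trim_overlap: int = 1_000,
) -> tuple[dict[str, str], dict[str, tuple[str, str]], pd.DataFrame]:
    """Full screening pass.

    Returns (retained sequences, per-target exemplar (contig, sequence),
    removal report).  Removed and retained contigs partition the input.
    """
    rows = []
    filtered_g, isolated = drop_isolated(g, min_isolated_len)
    for v in isolated:
        rows.append((v, "isolated_short"))
    lengths = {c: len(s) for c, s in sequences.items()}
    usable_hits = [h for h in hits if h.contig not in isolated]
    direct = call_matches(usable_hits, lengths, min_identity, min_hit_fraction, min_breadth)
    expanded = expand_matches(filtered_g, set(direct), hops, len_ratio)
    for v in sorted(direct):
        rows.append((v, "screen_match"))
    for v in sorted(expanded - direct):
        rows.append((v, "screen_neighborhood"))
    removed = set(isolated) | expanded

    exemplars: dict[str, tuple[str, str]] = {}
    coverages = {v: g.node(v).coverage for v in g.nodes}
    for target in sorted({h.target for h in hits}):
        t_hits = [h for h in usable_hits if h.target == target]
        t_matched = call_matches(t_hits, lengths, min_identity, min_hit_fraction, min_breadth)
        ex = pick_exemplar(
            t_matched, t_hits, sequences, coverages,
            min_identity, min_hit_fraction, trim_overlap=trim_overlap,
        )
        if ex is not None:
            exemplars[target] = ex
    retained = {c: s for c, s in sequences.items() if c not in removed}
    report = pd.DataFrame(rows, columns=["contig", "reason"])
    return retained, exemplars, report
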