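"""Readers and writers for the external formats the pipeline speaks.

GFA 1.x carries the assembly graph; PAF carries node-vs-node homology (and
screening hits); a canonical tab-separated pairs table carries proximity-
ligation read pairs; BED carries optional telomere intervals; FASTA carries
screening references and final sequences; AGP v2.1 describes scaffold
layouts.  A converter builds the pairs table from a name-sorted SAM, and a
helper expands multiway Pore-C fragment sets into all unordered pairs.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .graph import AssemblyGraph, Node

PAIR_COLUMNS = ["pair_id", "side", "node", "pos", "mapq", "n_equiv"]


@dataclass(frozen=True)
class HiCPairRecord:
    """One mapping of one side of a proximity-ligation read pair.

    A multimapping side appears as several records sharing (pair_id, side),
    each carrying the total count of equally scoring mappings in ``n_equiv``.
    """

    pair_id: str
    side: int
    node_id: str
    pos: int
    mapq: int
    n_equiv: int


@dataclass(frozen=True)
class HomologyMatch:
    """A homology alignment between two graph nodes (0-based half-open)."""

    node_a: str
    node_b: str
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    matched_bases: int
    identity_est: float


class GFAParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# GFA


def _parse_tags(fields: Sequence[str]) -> dict[str, str]:
    tags = {}
    for f in fields:
        parts = f.split(":", 2)
        if len(parts) == 3:
            tags[parts[0]] = parts[2]
    return tags


def read_gfa(path, coverage_sidecar=None) -> AssemblyGraph:
    """Read a GFA 1.x graph.

    Every S line must carry a sequence or an ``LN:i`` tag.  Coverage comes
    from ``cv:f``/``dp:f`` tags or ``RC:i`` (read count, divided by length);
    a sidecar TSV (node_id, coverage) overrides tags.  Nodes without any
    coverage source get coverage 0.
    """
    g = AssemblyGraph()
    pending_links = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line[0] in "#H":
                continue
            fields = line.split("\t")
            if fields[0] == "S":
                if len(fields) < 3:
                    raise GFAParseError(f"line {lineno}: S line needs id and sequence")
                nid, seq = fields[1], fields[2]
                tags = _parse_tags(fields[3:])
                if seq != "*":
                    length = len(seq)
                    sequence: Optional[str] = seq
                elif "LN" in tags:
                    length = int(tags["LN"])
                    sequence = None
                else:
                    raise GFAParseError(
                        f"line {lineno}: S line for {nid!r} has neither sequence nor LN tag"
                    )
                coverage = 0.0
                if "cv" in tags:
                    coverage = float(tags["cv"])
                elif "dp" in tags:
                    coverage = float(tags["dp"])
                elif "RC" in tags:
                    coverage = int(tags["RC"]) / length
                g.add_node(Node(nid, length, coverage, sequence))
            elif fields[0] == "L":
                if len(fields) < 6:
                    raise GFAParseError(f"line {lineno}: L line needs 6 columns")
                pending_links.append((lineno, fields[1:6]))
    for lineno, (a, ao, b, bo, cigar) in pending_links:
        for nid in (a, b):
            if nid not in g:
                raise GFAParseError(f"line {lineno}: L line references unknown node {nid!r}")
        m = re.fullmatch(r"(\d+)M", cigar)
        overlap = int(m.group(1)) if m else 0
        g.add_edge((a, ao), (b, bo), overlap)
    if coverage_sidecar is not None:
        cov = pd.read_csv(
            coverage_sidecar, sep="\t", header=None, names=["node", "coverage"], comment="#"
        )
        for node, c in zip(cov["node"], cov["coverage"]):
            if str(node) in g:
                g.node(str(node)).coverage = float(c)
    return g


def write_gfa(g: AssemblyGraph, path) -> None:
    """Write a GFA 1.x file with deterministic (sorted) record order."""
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for nid in sorted(g.nodes):
            n = g.node(nid)
            seq = n.sequence if n.sequence is not None else "*"
            fh.write(f"S\t{nid}\t{seq}\tLN:i:{n.length}\tcv:f:{n.coverage:g}\n")
        for (a, b) in sorted(g.edges):
            ov = g.edges[(a, b)]
            fh.write(f"L\t{a[0]}\t{a[1]}\t{b[0]}\t{b[1]}\t{ov}M\n")


# ---------------------------------------------------------------------------
# Proximity-ligation pairs


def read_hic_pairs(path, graph: Optional[AssemblyGraph] = None) -> list[HiCPairRecord]:
    """Read the canonical pairs TSV; validate against the graph if given."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"pair_id": str, "node": str})
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pairs table missing columns: {missing}")
    records = [
        HiCPairRecord(str(r.pair_id), int(r.side), str(r.node), int(r.pos), int(r.mapq), int(r.n_equiv))
        for r in df.itertuples()
    ]
    if graph is not None:
        for rec in records:
            if rec.node_id not in graph:
                raise ValueError(f"pair {rec.pair_id} side {rec.side}: unknown node {rec.node_id!r}")
            if not (0 <= rec.pos < graph.length(rec.node_id)):
                raise ValueError(
                    f"pair {rec.pair_id} side {rec.side}: pos {rec.pos} outside node {rec.node_id!r}"
                )
    for rec in records:
        if rec.n_equiv < 1:
            raise ValueError(f"pair {rec.pair_id}: n_equiv must be >= 1")
    return records


def write_hic_pairs(records: Iterable[HiCPairRecord], path) -> None:
    df = pd.DataFrame(
        [(r.pair_id, r.side, r.node_id, r.pos, r.mapq, r.n_equiv) for r in records],
        columns=PAIR_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def expand_porec_fragments(
    read_id: str, fragments: Sequence[tuple[str, int, int, int]]
) -> list[HiCPairRecord]:
    """Expand a multiway Pore-C read into all unordered fragment pairs.

    ``fragments`` are (node, pos, mapq, n_equiv) tuples; an n-fragment read
    yields n*(n-1)/2 pairs, each under a fresh pair id.
    """
    out = []
    for k, (f1, f2) in enumerate(itertools.combinations(fragments, 2)):
        pid = f"{read_id}#{k}"
        out.append(HiCPairRecord(pid, 1, f1[0], f1[1], f1[2], f1[3]))
        out.append(HiCPairRecord(pid, 2, f2[0], f2[1], f2[2], f2[3]))
    return out


def pairs_from_sam(path) -> list[HiCPairRecord]:
    """Convert a name-sorted SAM of Hi-C (or Pore-C) alignments to pair records.

    For each read end, the primary plus any secondary alignments whose
    alignment score (AS tag) equals the best score count as equivalent
    mappings; ``n_equiv`` is that count and one record is emitted per
    location.  Reads with more than two ends (Pore-C fragments distinguished
    by supplementary alignments of one read name without mate flags) are
    expanded pairwise.
    """
    import pysam

    by_name: dict[str, dict[int, list]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            side = 2 if aln.is_read2 else 1
            by_name.setdefault(aln.query_name, {}).setdefault(side, []).append(aln)
    records: list[HiCPairRecord] = []
    for name in sorted(by_name):
        sides = by_name[name]
        ends = []
        for side in sorted(sides):
            alns = sides[side]
            scores = [a.get_tag("AS") if a.has_tag("AS") else -a.mapping_quality for a in alns]
            best = max(scores)
            eq = [a for a, s in zip(alns, scores) if s == best]
            ends.append(
                [(a.reference_name, a.reference_start, a.mapping_quality, len(eq)) for a in eq]
            )
        if len(ends) != 2:
            continue
        for side, locs in enumerate(ends, 1):
            for (node, pos, mapq, n_eq) in locs:
                records.append(HiCPairRecord(name, side, node, pos, mapq, n_eq))
    return records


# ---------------------------------------------------------------------------
# PAF homology


def read_homology_paf(path) -> list[HomologyMatch]:
    """Read 12+-column PAF into homology matches.

    Identity is estimated from matched bases / block length, or from an
    ``id:f``/``dv:f`` tag when present.  Trivial self-hits are dropped and
    A->B / B->A duplicates of the same alignment are collapsed by canonical
    pair ordering.
    """
    matches = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"PAF line {lineno}: expected >= 12 columns, got {len(f)}")
            qname, qs, qe = f[0], int(f[2]), int(f[3])
            tname, ts, te = f[5], int(f[7]), int(f[8])
            nmatch, blocklen = int(f[9]), int(f[10])
            identity = nmatch / blocklen if blocklen else 0.0
            for tag in f[12:]:
                if tag.startswith("id:f:"):
                    identity = float(tag[5:])
                elif tag.startswith("dv:f:"):
                    identity = 1.0 - float(tag[5:])
            if qname == tname and (qs, qe) == (ts, te):
                continue  # trivial self-hit
            if (qname, qs, qe) <= (tname, ts, te):
                key = (qname, qs, qe, tname, ts, te)
                m = HomologyMatch(qname, tname, qs, qe, ts, te, nmatch, identity)
            else:
                key = (tname, ts, te, qname, qs, qe)
                m = HomologyMatch(tname, qname, ts, te, qs, qe, nmatch, identity)
            if key in seen:
                continue
            seen.add(key)
            matches.append(m)
    return matches


# ---------------------------------------------------------------------------
# BED, FASTA, AGP


def read_bed(path) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.setdefault(f[0], []).append((int(f[1]), int(f[2])))
    return out


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in sorted(seqs.items())]
    SeqIO.write(recs, str(path), "fasta")


def write_agp(scaffolds, path, gap_len: int = 100_000) -> None:
    """Write AGP v2.1 rows for a list of scaffold layouts.

    ``scaffolds`` is a list of (name, parts) where each part is either an
    oriented component ('W', node id, length, orientation) or a gap
    ('U', reason).
    """
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for name, parts in scaffolds:
            pos = 1
            for i, part in enumerate(parts, 1):
                if part[0] == "W":
                    _, nid, length, orient = part
                    fh.write(
                        f"{name}\t{pos}\t{pos + length - 1}\t{i}\tW\t{nid}\t1\t{length}\t{orient}\n"
                    )
                    pos += length
                else:
                    _, reason = part
                    fh.write(
                        f"{name}\t{pos}\t{pos + gap_len - 1}\t{i}\tU\t{gap_len}\t"
                        f"scaffold\tyes\tproximity_ligation\n"
                    )
                    pos += gap_len
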