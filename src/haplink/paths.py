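"""Haplotype path reconstruction from a labeled assembly graph.

Given hap1/hap2/homozygous node labels, label refinement first rescues
unassigned nodes (majority rule for big nodes, ratio rule for small ones,
tangle inheritance, bubble-arm forcing), then a greedy walk seeds at long
labeled nodes and extends through label-consistent neighbours, emitting a
reasoned gap token wherever the walk is blocked.  Homozygous nodes are
shared sequence and may be traversed by one path of each haplotype.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

import numpy as np

from .graph import MINUS, PLUS, AssemblyGraph, OrientedNode, flip
from .phase import HAP1, HAP2, HOMOZYGOUS, UNASSIGNED, Partition

GAP_REASONS = ("tangle", "coverage_dropout", "ambiguous_bubble", "scaffold_join", "rdna_like")


@dataclass(frozen=True)
class Gap:
    reason: str
    est_len: int

    def token(self) -> str:
        return f"[gap:{self.reason}:{self.est_len}]"


Step = Union[OrientedNode, Gap]


@dataclass
class HaplotypePath:
    name: str
    steps: list[Step] = field(default_factory=list)
    haplotype: str = "na"
    telo_left: bool = False
    telo_right: bool = False

    def node_steps(self) -> list[OrientedNode]:
        return [s for s in self.steps if not isinstance(s, Gap)]

    def node_ids(self) -> list[str]:
        return [s[0] for s in self.node_steps()]

    def gaps(self) -> list[Gap]:
        return [s for s in self.steps if isinstance(s, Gap)]

    def length(self, g: AssemblyGraph) -> int:
        return sum(g.length(n) for n in self.node_ids()) + sum(
            gp.est_len for gp in self.gaps()
        )

    def reversed(self, name: Optional[str] = None) -> "HaplotypePath":
        steps: list[Step] = []
        for s in reversed(self.steps):
            steps.append(s if isinstance(s, Gap) else (s[0], flip(s[1])))
        return HaplotypePath(
            name or self.name, steps, self.haplotype, self.telo_right, self.telo_left
        )


# ---------------------------------------------------------------------------
# Label refinement


def _oriented_out_degree(g: AssemblyGraph, v: str) -> dict[str, int]:
    return {
        PLUS: len(g.successors((v, PLUS))),
        MINUS: len(g.successors((v, MINUS))),
    }


def _find_simple_bubbles(
    g: AssemblyGraph, max_arm: int = 3
) -> list[tuple[OrientedNode, OrientedNode, list[str], list[str]]]:
    """Simple bubbles: two vertex-disjoint linear arms (each <= max_arm
    nodes) between a shared source end and sink end."""
    bubbles = []
    seen = set()
    for v in sorted(g.nodes):
        for o in (PLUS, MINUS):
            succ = g.successors((v, o))
            if len(succ) != 2:
                continue
            arms = []
            for start in succ:
                arm = []
                cur = start
                ok = False
                for _ in range(max_arm):
                    if len(g.successors((cur[0], flip(cur[1])))) != 1:
                        break  # arm node must have a single way back
                    arm.append(cur[0])
                    nxt = g.successors(cur)
                    if len(nxt) != 1:
                        break
                    cur = nxt[0]
                    ok = True
                if ok:
                    arms.append((arm, cur))
            if len(arms) != 2:
                continue
            (arm1, sink1), (arm2, sink2) = arms
            if sink1 != sink2 or set(arm1) & set(arm2):
                continue
            if sink1[0] in set(arm1) | set(arm2) | {v}:
                continue
            key = frozenset([(v, o), (sink1[0], flip(sink1[1]))])
            if key in seen:
                continue
            seen.add(key)
            bubbles.append(((v, o), sink1, arm1, arm2))
    return bubbles


def refine_labels(
    g: AssemblyGraph,
    labels: Partition,
    evidence: Optional[dict[str, tuple[float, float]]] = None,
    marker_ratio: float = 5.0,
    big_node: int = 500_000,
    tangle_max_node: int = 500_000,
    seed: int = 0,
) -> Partition:
    """Rescue unassigned nodes before path extraction.

    ``evidence`` maps a node to its (hap1, hap2) support counts (Hi-C links
    or markers).  Big nodes (> ``big_node`` bp) are assigned by strict
    majority; smaller nodes need a ``marker_ratio``: 1 majority.  Unassigned
    tangles whose labeled boundary touches a single haplotype inherit it,
    and the two arms of a signal-free simple bubble are forced onto opposite
    haplotypes (seed-deterministic side choice when there is no signal).
    """
    evidence = evidence or {}
    out = Partition(
        dict(labels.assignment),
        dict(labels.component_of),
        dict(labels.cut_weight),
        dict(labels.seed_of),
    )

    def unassigned(v: str) -> bool:
        return out.assignment.get(v, UNASSIGNED) == UNASSIGNED

    # 1 & 2: evidence-based assignment, majority for big nodes, ratio for small.
    for v in sorted(g.nodes):
        if not unassigned(v) or v not in evidence:
            continue
        c1, c2 = evidence[v]
        best, cb, cs = (HAP1, c1, c2) if c1 >= c2 else (HAP2, c2, c1)
        if cb == 0:
            continue
        if g.length(v) > big_node:
            if cb > cs:
                out.assignment[v] = best
        elif cb >= marker_ratio * cs:
            out.assignment[v] = best

    # 3: tangle inheritance.
    u = g.undirected()
    todo = {v for v in g.nodes if unassigned(v) and g.length(v) <= tangle_max_node}
    while todo:
        v = min(todo)
        comp = {v}
        frontier = [v]
        while frontier:
            x = frontier.pop()
            for y in u.neighbors(x):
                if y in todo and y not in comp:
                    comp.add(y)
                    frontier.append(y)
        todo -= comp
        boundary_labels = {
            out.assignment.get(y)
            for x in comp
            for y in u.neighbors(x)
            if out.assignment.get(y) in (HAP1, HAP2)
        }
        if len(boundary_labels) == 1:
            lbl = boundary_labels.pop()
            for x in comp:
                out.assignment[x] = lbl

    # 4: force simple-bubble arms onto opposite haplotypes.
    rng = np.random.default_rng(seed)
    for (_, _, arm1, arm2) in _find_simple_bubbles(g):
        if not all(unassigned(x) for x in arm1 + arm2):
            continue
        s1 = sum(evidence.get(x, (0, 0))[0] - evidence.get(x, (0, 0))[1] for x in arm1)
        s2 = sum(evidence.get(x, (0, 0))[0] - evidence.get(x, (0, 0))[1] for x in arm2)
        if s1 > s2:
            first = HAP1
        elif s2 > s1:
            first = HAP2
        else:
            first = HAP1 if rng.integers(2) == 0 else HAP2
        second = HAP2 if first == HAP1 else HAP1
        for x in arm1:
            out.assignment[x] = first
        for x in arm2:
            out.assignment[x] = second
    return out


# ---------------------------------------------------------------------------
# Greedy path extraction


def _extend(
    g: AssemblyGraph,
    start: OrientedNode,
    hap: str,
    labels: Partition,
    used: set[str],
    used_hap: set[str],
    gap_est_len: int,
) -> tuple[list[Step], bool]:
    """Walk forward from ``start`` (excluded) through label-consistent nodes.

    Returns the appended steps and whether the walk ended on a telomere.
    """
    steps: list[Step] = []
    cur = start
    in_path = set(used)
    while True:
        succ = g.successors(cur)
        if not succ:
            return steps, g.node(cur[0]).telo("right", cur[1])
        cands = []
        for s in succ:
            lbl = labels.label(s[0])
            if lbl != hap and lbl != HOMOZYGOUS:
                continue
            if s[0] in in_path or s[0] in used_hap:
                continue
            cands.append(s)
        if len(cands) == 1:
            cur = cands[0]
            steps.append(cur)
            in_path.add(cur[0])
            continue
        if len(cands) == 0:
            other = HAP2 if hap == HAP1 else HAP1
            lbls = {labels.label(s[0]) for s in succ}
            if UNASSIGNED not in lbls:
                # the walk reaches the other haplotype's (or exhausted)
                # territory: a clean border, not missing sequence
                return steps, False
            # blocked by unlabeled structure: name the gap after what lies ahead
            if len(succ) > 2:
                reason = "tangle"
            elif len(succ) == 2:
                reason = "ambiguous_bubble"
            else:
                ahead = g.successors(succ[0])
                if len(ahead) > 2:
                    reason = "tangle"
                elif len(ahead) == 2:
                    reason = "ambiguous_bubble"
                else:
                    reason = "coverage_dropout"
            steps.append(Gap(reason, gap_est_len))
            return steps, False
        reason = "ambiguous_bubble" if len(cands) == 2 else "tangle"
        steps.append(Gap(reason, gap_est_len))
        return steps, False


def extract_paths(
    g: AssemblyGraph,
    labels: Partition,
    seed_min_len: int = 500_000,
    gap_est_len: int = 50_000,
) -> list[HaplotypePath]:
    """Greedy haplotype path extraction.

    Paths seed at the longest unvisited hap-labeled node of at least
    ``seed_min_len`` bp and extend in both directions along the unique
    label-consistent edge; blocked extensions emit a reasoned gap token.
    Homozygous nodes may appear in one path of each haplotype.
    """
    used: dict[str, set[str]] = {HAP1: set(), HAP2: set()}
    paths: list[HaplotypePath] = []
    seeds = sorted(
        (v for v in g.nodes if labels.label(v) in (HAP1, HAP2) and g.length(v) >= seed_min_len),
        key=lambda v: (-g.length(v), v),
    )
    counter = {HAP1: 0, HAP2: 0}
    for seed_node in seeds:
        hap = labels.label(seed_node)
        if seed_node in used[hap]:
            continue
        fwd, fwd_telo = _extend(
            g, (seed_node, PLUS), hap, labels, {seed_node}, used[hap], gap_est_len
        )
        walked = {seed_node} | {s[0] for s in fwd if not isinstance(s, Gap)}
        bwd, bwd_telo = _extend(
            g, (seed_node, MINUS), hap, labels, walked, used[hap], gap_est_len
        )
        left = [
            (s if isinstance(s, Gap) else (s[0], flip(s[1]))) for s in reversed(bwd)
        ]
        steps: list[Step] = left + [(seed_node, PLUS)] + fwd
        counter[hap] += 1
        path = HaplotypePath(f"{hap}_path_{counter[hap]}", steps, hap)
        node_steps = path.node_steps()
        first, last = node_steps[0], node_steps[-1]
        path.telo_left = (
            g.node(first[0]).telo("left", first[1]) and not isinstance(path.steps[0], Gap)
        )
        path.telo_right = (
            g.node(last[0]).telo("right", last[1]) and not isinstance(path.steps[-1], Gap)
        )
        for nid in path.node_ids():
            if labels.label(nid) == HOMOZYGOUS:
                used[hap].add(nid)
            else:
                used[HAP1].add(nid)
                used[HAP2].add(nid)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Path file io

_GAP_RE = re.compile(r"\[gap:([a-z_]+):(\d+)\]")


def path_to_string(path: HaplotypePath) -> str:
    out = []
    for s in path.steps:
        out.append(s.token() if isinstance(s, Gap) else f"{s[0]}{s[1]}")
    return ",".join(out)


def parse_path_string(s: str) -> list[Step]:
    steps: list[Step] = []
    if not s:
        return steps
    if s.startswith((">", "<")) and "," not in s:
        for m in re.finditer(r"([><])([^><]+)", s):
            steps.append((m.group(2), PLUS if m.group(1) == ">" else MINUS))
        return steps
    for tok in s.split(","):
        m = _GAP_RE.fullmatch(tok)
        if m:
            steps.append(Gap(m.group(1), int(m.group(2))))
        else:
            steps.append((tok[:-1], tok[-1]))
    return steps


def write_paths(paths: Iterable[HaplotypePath], path) -> None:
    fh = path if hasattr(path, "write") else open(path, "w")
    try:
        fh.write("name\tpath\tassignment\ttelo_left\ttelo_right\n")
        for p in paths:
            fh.write(
                f"{p.name}\t{path_to_string(p)}\t{p.haplotype}\t"
                f"{int(p.telo_left)}\t{int(p.telo_right)}\n"
            )
    finally:
        if fh is not path:
            fh.close()


def read_paths(path) -> list[HaplotypePath]:
    out = []
    with open(path) as fh:
        lines = [l for l in fh if not l.startswith("#")]
    if lines:
        for line in lines[1:]:  # first non-comment line is the header
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                continue
            p = HaplotypePath(f[0], parse_path_string(f[1]), f[2])
            if len(f) >= 5:
                p.telo_left = bool(int(f[3]))
                p.telo_right = bool(int(f[4]))
            out.append(p)
    return out
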