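"""Synthetic diploid assembly graphs and proximity-ligation pairs.

The generator plants a known diploid structure — per-chromosome node chains
for two haplotypes, homology matches between homolog pairs, optionally
collapsed homozygous nodes and a shared high-coverage tangle node joining
chromosome arms (an acrocentric/rDNA mimic) — and simulates Hi-C read pairs
with the two properties the method relies on: pairs come from the same
haplotype more often than not, and from close rather than distant positions
(discrete power-law distance decay).  A configurable fraction of pairs is
turned into mapping confounders (zero mapping quality or multimappings onto
the homolog) to exercise the filters.  Everything is a deterministic
function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .graph import PLUS, AssemblyGraph, Node
from .io import HiCPairRecord, HomologyMatch
from .paths import HaplotypePath
from .phase import HAP1, HAP2, HOMOZYGOUS


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults describe a small diploid genome: two chromosomes with twenty
    long unitigs per haplotype (250-600 kb, so every node clears the 200 kb
    phasing threshold), ~30x per-haplotype depth, fifty uniquely mapped
    Hi-C pairs anchored per node, 90% of pairs intra-haplotype and a unit
    power-law distance decay.  Confounders (``multimap_fraction``) are off
    by default and enabled where a scenario needs them.
    """

    n_chromosomes: int = 2
    nodes_per_haplotype: int = 20
    node_len_min: int = 250_000
    node_len_max: int = 600_000
    homology_fraction: float = 0.95
    coverage_mean: float = 30.0
    coverage_sd: float = 3.0
    hic_pairs_per_node: int = 50
    intra_haplotype_fraction: float = 0.9
    distance_decay: float = 1.0
    min_pair_distance: int = 1_000
    multimap_fraction: float = 0.0
    homozygous_fraction: float = 0.0
    tangle: bool = False
    tangle_len: int = 150_000
    telomeres: bool = True
    seed: int = 0


@dataclass
class SimResult:
    graph: AssemblyGraph
    truth_labels: dict[str, str]
    truth_paths: list[HaplotypePath]
    matches: list[HomologyMatch]
    tangle_node: Optional[str] = None
    # truth paths split at the tangle (two per haplotype per chromosome)
    split_paths: list[HaplotypePath] = field(default_factory=list)


def simulate_diploid_graph(cfg: SimConfig) -> SimResult:
    """Build the planted diploid graph, labels, walks and homology matches."""
    rng = np.random.default_rng(cfg.seed)
    g = AssemblyGraph()
    labels: dict[str, str] = {}
    truth_paths: list[HaplotypePath] = []
    matches: list[HomologyMatch] = []
    split_paths: list[HaplotypePath] = []
    tangle_node: Optional[str] = None
    k = cfg.nodes_per_haplotype
    mid = k // 2

    if cfg.tangle:
        if cfg.n_chromosomes < 2:
            raise ValueError("the shared-tangle mimic needs at least 2 chromosomes")
        tangle_node = "rdna_tangle"
        g.add_node(
            Node(tangle_node, cfg.tangle_len, 4.0 * cfg.coverage_mean)
        )
        labels[tangle_node] = "unassigned"

    for c in range(1, cfg.n_chromosomes + 1):
        lens = rng.integers(cfg.node_len_min, cfg.node_len_max, size=k)
        hom_pos = set(np.where(rng.random(k) < cfg.homozygous_fraction)[0])
        hom_pos -= {0, k - 1, mid - 1, mid}  # keep ends and the break heterozygous
        chrom_nodes: dict[str, list[str]] = {HAP1: [], HAP2: []}
        for i in range(k):
            if i in hom_pos:
                nid = f"chr{c}_hom_n{i:02d}"
                g.add_node(Node(nid, int(lens[i]), 2.0 * _cov(rng, cfg)))
                labels[nid] = HOMOZYGOUS
                chrom_nodes[HAP1].append(nid)
                chrom_nodes[HAP2].append(nid)
            else:
                for h, hap in ((1, HAP1), (2, HAP2)):
                    nid = f"chr{c}_h{h}_n{i:02d}"
                    g.add_node(Node(nid, int(lens[i]), _cov(rng, cfg)))
                    labels[nid] = hap
                    chrom_nodes[hap].append(nid)
                a, b = f"chr{c}_h1_n{i:02d}", f"chr{c}_h2_n{i:02d}"
                mlen = int(cfg.homology_fraction * lens[i])
                if mlen > 0:
                    matches.append(
                        HomologyMatch(a, b, 0, mlen, 0, mlen, mlen, 0.99)
                    )
        for hap in (HAP1, HAP2):
            chain = chrom_nodes[hap]
            for x, y in zip(chain, chain[1:]):
                if cfg.tangle and chain.index(y) == mid:
                    g.add_edge((x, PLUS), (tangle_node, PLUS))
                    g.add_edge((tangle_node, PLUS), (y, PLUS))
                else:
                    g.add_edge((x, PLUS), (y, PLUS))
            if cfg.telomeres:
                g.node(chain[0]).telo_start = True
                g.node(chain[-1]).telo_end = True
            steps = [(n, PLUS) for n in chain]
            truth_paths.append(
                HaplotypePath(
                    f"chr{c}_{hap}", steps, hap, cfg.telomeres, cfg.telomeres
                )
            )
            if cfg.tangle:
                left = HaplotypePath(
                    f"chr{c}_{hap}_left", steps[:mid], hap, cfg.telomeres, False
                )
                right = HaplotypePath(
                    f"chr{c}_{hap}_right", steps[mid:], hap, False, cfg.telomeres
                )
                split_paths.extend([left, right])
    return SimResult(g, labels, truth_paths, matches, tangle_node, split_paths)


def _cov(rng: np.random.Generator, cfg: SimConfig) -> float:
    return float(max(1.0, rng.normal(cfg.coverage_mean, cfg.coverage_sd)))


def homolog_of(node: str) -> Optional[str]:
    """Planted homolog of a haplotype-specific simulated node, if any."""
    if "_h1_" in node:
        return node.replace("_h1_", "_h2_")
    if "_h2_" in node:
        return node.replace("_h2_", "_h1_")
    return None


def _power_law_distance(
    rng: np.random.Generator, d_min: float, d_max: float, alpha: float
) -> float:
    """Draw from p(d) ~ d^-alpha truncated to [d_min, d_max]."""
    u = rng.random()
    if abs(alpha - 1.0) < 1e-9:
        return d_min * (d_max / d_min) ** u
    a = 1.0 - alpha
    return (d_min**a + u * (d_max**a - d_min**a)) ** (1.0 / a)


def simulate_hic_pairs(
    g: AssemblyGraph, sim: SimResult, cfg: SimConfig
) -> list[HiCPairRecord]:
    """Simulate proximity-ligation pairs along the planted chromosome walks.

    Each node occurrence anchors ``hic_pairs_per_node`` pairs; the partner
    lies on the same haplotype's walk with probability
    ``intra_haplotype_fraction`` (else on the homologous walk) at a
    power-law-distributed genomic distance.  With probability
    ``multimap_fraction`` a pair becomes a confounder: its second side
    either maps with quality zero or multimaps equally onto the planted
    homolog node.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    layouts = {}
    for p in sim.truth_paths:
        nodes = [s[0] for s in p.steps]
        lens = np.array([g.length(n) for n in nodes], dtype=np.int64)
        offs = np.concatenate([[0], np.cumsum(lens)])
        layouts[p.name] = (nodes, offs, int(offs[-1]))
    # trans contacts go anywhere on the opposite haplotype: homolog pairing
    # of chromosomes is rare, so the partner molecule is not biased toward
    # the homologous chromosome
    partner_of: dict[str, list[str]] = {}
    for p in sim.truth_paths:
        hap = p.name.rsplit("_", 1)[1]
        partner_of[p.name] = sorted(
            q.name for q in sim.truth_paths if q.haplotype != hap
        )

    records: list[HiCPairRecord] = []
    pid = 0
    for pname in sorted(layouts):
        nodes, offs, total = layouts[pname]
        for ni, node in enumerate(nodes):
            for _ in range(cfg.hic_pairs_per_node):
                x = int(offs[ni] + rng.integers(0, g.length(node)))
                same = rng.random() < cfg.intra_haplotype_fraction
                if same:
                    target = pname
                else:
                    opts = partner_of[pname]
                    target = opts[int(rng.integers(len(opts)))]
                t_nodes, t_offs, t_total = layouts[target]
                if same:
                    # contacts along one molecule decay with genomic distance
                    d = _power_law_distance(
                        rng,
                        cfg.min_pair_distance,
                        max(t_total - 1, cfg.min_pair_distance + 1),
                        cfg.distance_decay,
                    )
                    y = x + d if rng.random() < 0.5 else x - d
                    y = int(min(max(y, 0), t_total - 1))
                else:
                    # the homolog is a different molecule: no shared polymer
                    # coordinate, so its contact positions are unstructured
                    y = int(rng.integers(0, t_total))
                tj = int(np.searchsorted(t_offs, y, side="right") - 1)
                t_node = t_nodes[tj]
                t_pos = y - int(t_offs[tj])
                pid += 1
                name = f"p{pid}"
                confound = rng.random() < cfg.multimap_fraction
                records.append(HiCPairRecord(name, 1, node, x - int(offs[ni]), 60, 1))
                if not confound:
                    records.append(HiCPairRecord(name, 2, t_node, t_pos, 60, 1))
                    continue
                hom = homolog_of(t_node)
                if hom is not None and hom in g and rng.random() < 0.5:
                    hpos = min(t_pos, g.length(hom) - 1)
                    records.append(HiCPairRecord(name, 2, t_node, t_pos, 60, 2))
                    records.append(HiCPairRecord(name, 2, hom, hpos, 60, 2))
                else:
                    records.append(HiCPairRecord(name, 2, t_node, t_pos, 0, 1))
    return records
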