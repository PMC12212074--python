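"""Stage orchestration: phase -> paths -> scaffold -> screen.

Each stage is a pure function of (inputs, config, seed) and reads/writes
only the declared file formats, so stages can be run independently or
chained by the command-line wrapper.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

from .config import PipelineConfig
from .graph import AssemblyGraph
from .io import HiCPairRecord, HomologyMatch
from .match_graph import MatchGraph, build_match_graph, classify_edges
from .paths import HaplotypePath, extract_paths, refine_labels, write_paths
from .phase import (
    HAP1,
    HAP2,
    HOMOZYGOUS,
    Partition,
    assign_short_nodes,
    build_hic_graph,
    classify_nodes_by_coverage,
    kl_bipartition,
    qualifying_pairs,
    split_components,
    write_labels,
)
from .scaffold import (
    apply_bonuses,
    apply_joins,
    compute_link_weights,
    filter_pairs_for_scaffolding,
    layout_path,
    scaffolds_to_agp_parts,
    select_joins,
    telomere_rescue,
    write_join_evidence,
)
from .screen import ScreenHit, screen_assembly

log = logging.getLogger("haplink")


def build_classified_match_graph(
    g: AssemblyGraph, matches: Sequence[HomologyMatch], cfg: PipelineConfig
) -> MatchGraph:
    try:
        coverage_class = classify_nodes_by_coverage(g, cfg.coverage_long_node)
        homozygous = {v for v, c in coverage_class.items() if c == HOMOZYGOUS}
    except ValueError:
        homozygous = set()
    mg = build_match_graph(
        g, matches, cfg.min_node_len, cfg.min_match_len, exclude=homozygous
    )
    return classify_edges(mg, g, cfg.match_majority_ratio)


def run_phase(
    g: AssemblyGraph,
    matches: Sequence[HomologyMatch],
    pairs: Sequence[HiCPairRecord],
    cfg: Optional[PipelineConfig] = None,
) -> tuple[Partition, MatchGraph]:
    """Match Graph -> Hi-C Graph -> per-component KL -> short-node rescue."""
    cfg = cfg or PipelineConfig()
    try:
        coverage_class = classify_nodes_by_coverage(g, cfg.coverage_long_node)
    except ValueError:
        coverage_class = {}
    homozygous = {v for v, c in coverage_class.items() if c == HOMOZYGOUS}
    mg = build_match_graph(
        g, matches, cfg.min_node_len, cfg.min_match_len, exclude=homozygous
    )
    mg = classify_edges(mg, g, cfg.match_majority_ratio)
    components = split_components(g, mg)
    h = build_hic_graph(
        g, mg, pairs, cfg.min_node_len, cfg.negative_multiplier, components,
        exclude=homozygous,
    )
    partition = Partition()
    if not qualifying_pairs(pairs):
        log.warning("no qualifying Hi-C pairs: all long nodes left unassigned")
        components = []
    for i, comp in enumerate(components):
        comp_hic = [v for v in comp if v in h]
        if not comp_hic:
            continue
        if len(comp_hic) == 1 or h.subgraph(comp_hic).number_of_edges() == 0:
            continue  # nothing to bipartition on
        kl_bipartition(
            h, comp_hic, cfg.kl_restarts, cfg.kl_iters, cfg.seed, i, partition
        )
        log.info(
            "component %d: %d nodes, cut weight %.1f",
            i, len(comp_hic), partition.cut_weight[i],
        )
    assign_short_nodes(partition, pairs, g, cfg.short_node_ratio, homozygous)
    return partition, mg


def hic_link_evidence(
    partition: Partition, pairs: Sequence[HiCPairRecord]
) -> dict[str, tuple[float, float]]:
    """Per-node (hap1, hap2) qualifying-link counts, for label refinement."""
    counts: dict[str, list[float]] = {}
    for n1, n2 in qualifying_pairs(pairs).values():
        for a, b in ((n1, n2), (n2, n1)):
            lbl = partition.assignment.get(b)
            if lbl == HAP1:
                counts.setdefault(a, [0.0, 0.0])[0] += 1
            elif lbl == HAP2:
                counts.setdefault(a, [0.0, 0.0])[1] += 1
    return {k: (v[0], v[1]) for k, v in counts.items()}


def run_paths(
    g: AssemblyGraph,
    partition: Partition,
    pairs: Sequence[HiCPairRecord] = (),
    cfg: Optional[PipelineConfig] = None,
) -> list[HaplotypePath]:
    cfg = cfg or PipelineConfig()
    evidence = hic_link_evidence(partition, pairs) if pairs else {}
    refined = refine_labels(
        g, partition, evidence, cfg.marker_ratio, cfg.big_node, seed=cfg.seed
    )
    return extract_paths(g, refined, cfg.seed_min_len, cfg.gap_est_len)


def run_scaffold(
    g: AssemblyGraph,
    paths: Sequence[HaplotypePath],
    pairs: Sequence[HiCPairRecord],
    matches: Sequence[HomologyMatch] = (),
    cfg: Optional[PipelineConfig] = None,
    ref_matches: Sequence[HomologyMatch] = (),
    rdna_nodes: Iterable[str] = (),
) -> tuple[list[HaplotypePath], list]:
    """End-window link weights -> bonuses -> mutual-best joins -> rescue."""
    cfg = cfg or PipelineConfig()
    layouts = {p.name: layout_path(p, g, cfg.window_cap) for p in paths}
    retained = filter_pairs_for_scaffolding(pairs, cfg.max_equiv)
    log.info("scaffolding: %d pairs retained", len(retained))
    cands = compute_link_weights(layouts, retained)
    cands = apply_bonuses(
        cands, g, layouts, list(matches) + list(ref_matches),
        cfg.prox_bonus, cfg.hom_bonus, cfg.prox_dist, cfg.homology_gap,
    )
    joins = select_joins(cands, paths, cfg.join_ratio)
    used_ends = {e for j in joins for e in (j.end1, j.end2)}
    rescue = [
        j
        for j in telomere_rescue(g, paths, matches, cfg.prox_dist, cfg.rescue_big_path)
        if j.end1 not in used_ends and j.end2 not in used_ends
    ]
    all_joins = joins + rescue
    scaffolds = apply_joins(paths, all_joins, cfg.join_gap_len, rdna_nodes)
    return scaffolds, all_joins


def run_screen(
    g: AssemblyGraph,
    sequences: dict[str, str],
    hits: Sequence[ScreenHit],
    cfg: Optional[PipelineConfig] = None,
):
    cfg = cfg or PipelineConfig()
    return screen_assembly(
        g, sequences, hits,
        cfg.min_isolated_len, cfg.screen_min_identity, cfg.screen_min_hit_fraction,
        cfg.screen_min_breadth, cfg.screen_hops, cfg.screen_len_ratio,
        cfg.screen_trim_overlap,
    )


def write_labels_with_header(partition: Partition, path, cfg: PipelineConfig) -> None:
    import io as _io

    buf = _io.StringIO()
    write_labels(partition, buf)
    with open(path, "w") as fh:
        fh.write(cfg.header() + "\n")
        fh.write(buf.getvalue())


def write_paths_with_header(paths: Sequence[HaplotypePath], path, cfg: PipelineConfig) -> None:
    import io as _io

    buf = _io.StringIO()
    write_paths(paths, buf)
    with open(path, "w") as fh:
        fh.write(cfg.header() + "\n")
        fh.write(buf.getvalue())
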