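"""Extract haplotype paths from a labeled graph, with gap reasons.

Runs the full phase -> refine -> walk chain on a simulated diploid graph
containing collapsed homozygous nodes, and prints the resulting paths with
their telomere status and any gap annotations.
"""

from haplink import PipelineConfig, SimConfig, run_phase
from haplink.pipeline import run_paths
from haplink.paths import path_to_string
from haplink.simulate import simulate_diploid_graph, simulate_hic_pairs

sim_cfg = SimConfig(
    n_chromosomes=2, nodes_per_haplotype=12, homozygous_fraction=0.15, seed=6
)
sim = simulate_diploid_graph(sim_cfg)
pairs = simulate_hic_pairs(sim.graph, sim, sim_cfg)

cfg = PipelineConfig(seed=6)
partition, _ = run_phase(sim.graph, sim.matches, pairs, cfg)
paths = run_paths(sim.graph, partition, pairs, cfg)

for p in paths:
    mb = p.length(sim.graph) / 1e6
    telo = ("(" + ("T" if p.telo_left else "-") + "," +
            ("T" if p.telo_right else "-") + ")")
    print(f"{p.name:<14} {p.haplotype:<5} {mb:5.1f} Mb  telomeres {telo}")
    print(f"   {path_to_string(p)}")
# homozygous (collapsed) nodes appear in one path of each haplotype;
# T2T paths carry telomeres on both ends
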