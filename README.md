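# haplink

Proximity-ligation (Hi-C / Pore-C) phasing and scaffolding of diploid
assembly graphs.

Modern telomere-to-telomere assembly pipelines produce a bidirected unitig
graph in which the two parental haplotypes are interleaved, and regions such
as the short arms of acrocentric chromosomes — where several chromosomes
share near-identical distal satellites and rDNA arrays — defeat phasing
methods that assume a clean diploid bubble-chain structure. `haplink`
implements a graph-aware alternative for assembly developers and researchers
working on diploid genome reconstruction: it phases the graph with Hi-C
links corrected by sequence homology, extracts haplotype paths, scaffolds
those paths across gaps and tangles using multiplicity-normalised Hi-C
weights, and screens the final assembly for organelle/contaminant sequences.

## Method

**Phasing.** Long nodes (> 200 kb) sharing a homology alignment ≥ 200 kb
form the *Match Graph*, with edge weight the total aligned bases on the two
nodes. An edge that is a clear majority at one of its nodes
(w > 1.5 · w_second) and longer than ⅓ of a node it joins links two
*haplotypes*; an edge best for neither node links two *repeats*. The *Hi-C
Graph* then counts uniquely-mapped Hi-C pairs between long nodes; homolog
pairs get weight −10 · w_max (their Hi-C links are mapping artifacts and
should be cut), repeat-linked nodes are removed. Each diploid component
(assembly adjacency ∪ haplotype edges) is bipartitioned by multi-restart
Kernighan–Lin (1000 random balanced starts, gain-sorted swap passes with
rollback), minimising the cut weight

&nbsp;&nbsp;&nbsp;&nbsp;cut(A, B) = Σ<sub>u∈A, v∈B</sub> w(u, v),

and leftover short nodes join a haplotype when their link counts satisfy
best ≥ 2.5 · second-best. Homozygous nodes are recognised by depth against
their component's median and are shared by both haplotypes.

**Scaffolding.** For each pair of haplotype-path ends, contacts inside
5 Mb end windows (or half the path) accumulate a *primary* weight
Σ 1/(m₁·m₂) over the m₁·m₂ links each retained pair induces (a pair mapped
to 2 × 3 places adds 1/6 per link) and a *secondary* weight from
unique-unique pairs only. Ends within 500 kb in the graph get a ×3 bonus;
end pairs homologous to nearby intervals of a third path (or a reference)
get ×5. Mutually-best end pairs with margin best > 1.5 · second are joined
iteratively; telomeric ends are never extended, and a telomere-informed
rescue reattaches small telomeric stubs when the homologous haplotype is
already telomere-to-telomere.

**Screening.** Isolated nodes < 100 kb are dropped; contigs whose screening
hits (identity ≥ 97.5%, per-hit breadth ≥ 10%) union to ≥ 50% coverage are
removed along with neighbours within 4 hops and ≤ 4× length; per target an
exemplar is reported with circularity-induced terminal duplications > 1 kb
trimmed.

A synthetic-data module (`haplink.simulate`) generates diploid graphs with
planted haplotypes, homology, coverage, telomeres, an optional shared
acrocentric-like tangle, and Hi-C pairs with intra-haplotype preference and
power-law distance decay, so the whole stack is testable without downloads.

## Worked example

`examples/02_scaffold_across_shared_tangle.py` simulates two chromosomes
whose four haplotype paths are all interrupted by one shared high-coverage
tangle node (the rDNA situation) and rejoins them:

```
input: 8 broken haplotype paths (two per haplotype per chromosome), shared tangle node 'rdna_tangle'
join ('chr1_hap1_left', 'suffix') <-> ('chr1_hap1_right', 'prefix')  orientation fwd-fwd  primary 144.0  secondary 144.0  bonuses ['graph_proximity']
join ('chr1_hap2_left', 'suffix') <-> ('chr1_hap2_right', 'prefix')  orientation fwd-fwd  primary 120.0  secondary 120.0  bonuses ['graph_proximity']
join ('chr2_hap1_left', 'suffix') <-> ('chr2_hap1_right', 'prefix')  orientation fwd-fwd  primary 96.0   secondary 96.0   bonuses ['graph_proximity']
join ('chr2_hap2_left', 'suffix') <-> ('chr2_hap2_right', 'prefix')  orientation fwd-fwd  primary 90.0   secondary 90.0   bonuses ['graph_proximity']

output scaffolds:
  scaffold_1     hap1   20 nodes  T2T  scaffold_join
  scaffold_2     hap2   20 nodes  T2T  scaffold_join
  scaffold_3     hap1   20 nodes  T2T  scaffold_join
  scaffold_4     hap2   20 nodes  T2T  scaffold_join
```

Each accepted join pairs the two halves of the same haplotype in the
correct orientation (no haplotype switch across the tangle gap); the
primary weight is the bonus-multiplied, multiplicity-normalised contact
count between the joined end windows, and every scaffold ends telomeric on
both sides (T2T). The other examples cover phasing
(`01_phase_simulated_diploid.py`, which prints per-component cut weights
and 100% label accuracy against the planted truth), path extraction with
gap reasons (`04_paths_from_labels.py`) and assembly screening with
exemplar trimming (`03_screen_final_assembly.py`).

A thin CLI mirrors the stages:

```bash
haplink simulate --out data --seed 5 --tangle
haplink all --graph data/graph.gfa --homology data/homology.paf \
    --pairs data/pairs.tsv --out-dir results --seed 5
```

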