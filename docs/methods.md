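# Methods

This note documents the models, parameter choices and numerical details
behind `haplink`, and what the synthetic benchmarks do and do not show.

## Data model and conventions

The assembly graph is bidirected: a link `(A,+) -> (B,-)` means walking off
the 3′ end of A continues onto the reverse complement of B, and every link
implies its reverse complement. Links are stored once in canonical form.
All coordinates are 0-based, half-open, in bp of the input graph's
coordinate space; homopolymer compression, if any, is upstream of this
package. Coverage is mean read depth per node, read from `cv:f`/`dp:f`
tags, `RC:i` (divided by node length) or a sidecar TSV, which wins over
tags because real GFAs disagree about dialects.

Proximity-ligation data enter as a canonical pairs table
(`pair_id, side, node, pos, mapq, n_equiv`): one row per mapping, so a side
with `n_equiv = k` equally-scoring mappings contributes k rows. This makes
the pipeline testable without an aligner; a converter builds the table from
name-sorted SAM (equal-`AS` secondary alignments count toward `n_equiv`),
and multiway Pore-C reads are pre-expanded into all n·(n−1)/2 unordered
fragment pairs under fresh pair ids.

## Phasing

*Match Graph.* Nodes ≤ 200 kb and nodes the coverage screen flags as
homozygous are ignored. A node pair needs at least one homology alignment
spanning ≥ 200 kb; the edge weight is the interval-union breadth of all
alignments on one node plus that on the other, which is robust to
overlapping and duplicated PAF records. Classification per node V: an
incident edge is a haplotype candidate when its weight strictly exceeds
1.5× the second-best incident weight (0 for degree-1 nodes; ties at exactly
1.5× fail) *and* exceeds one third of the length of at least one of the two
nodes it joins. Haplotype if candidate at either endpoint; repeat if
strictly below the best weight at both endpoints; otherwise unclassified.
Haplotype takes precedence when both descriptions could apply.

*Coverage classes.* The depth baseline is the median coverage of > 50 kb
nodes in the node's connected component (global median as fallback). Nodes
> 50 kb are "unique" down to 0.4× baseline — large nodes are rarely
collapsed repeats, so a deep coverage drop is tolerated — while nodes
≤ 50 kb need 0.7–1.3×. Above 1.75× baseline a node is a homozygous/repeat
candidate; this upper bound is a package choice (collapsed diploid regions
sit near 2×, and 1.75 splits the 1× and 2× modes at typical depth noise).

*Hi-C Graph.* Only pairs with both sides uniquely mapped (mapq > 0 and
`n_equiv` = 1) count; the edge weight between two long nodes is the pair
count. Nodes touching a repeat Match edge are removed; homolog pairs get
weight −10 · w_max, with w_max the maximum positive weight of the diploid
component *before* negatives are injected, floored at 1 so that homologs
still separate in components with no usable Hi-C links at all (the raw
product would be 0 there and carry no signal). Self links are dropped.
Diploid components are the connected components of the assembly adjacency
plus the haplotype Match edges; Hi-C links across components are discarded,
which both shrinks the optimisation and handles heterogametic sex
chromosomes.

*Kernighan–Lin.* Each component is bipartitioned from 1000 random balanced
starts; a pass computes, for every unlocked cross pair (a, b), the gain
D(a) + D(b) − 2·w(a,b) with D(v) = external − internal weight, greedily
swaps and locks the best pair until all are locked, then applies the best
prefix of the swap sequence if its cumulative gain is positive (rollback
otherwise). Passes repeat until no restart improves, within a 10,000-pass
budget (classic KL converges in a handful). All restarts advance in
lock-step as dense numpy operations, so the 1000-restart default costs
about a second on a 40-node component. Balance is exact up to ±1: odd
components get a zero-weight phantom slot. Argmax ties break to the lowest
index, making results reproducible; each component derives its own child
seed from a SHA-256 of the sorted node ids and the pipeline seed, so
results do not depend on component iteration order. Within a component the
two sides are arbitrary (hap1/hap2 naming is up to a swap, per component).

*Short nodes.* Nodes absent from the Hi-C Graph get a haplotype when their
qualifying-link count to one side is ≥ 2.5× the count to the other (and
nonzero); coverage-flagged homozygous candidates are labeled homozygous;
the rest stay unassigned. With no qualifying pairs at all the stage warns
and leaves every node unassigned rather than phasing from homology alone,
which would be structurally valid but biologically arbitrary.

## Haplotype paths

Label refinement: (1) unassigned nodes > 500 kb with single-copy coverage
take the strict majority of their (hap1, hap2) link/marker evidence;
(2) smaller nodes need a 5:1 ratio; (3) a connected set of unassigned nodes
(each ≤ 500 kb) whose labeled boundary touches exactly one haplotype
inherits it; (4) in a simple bubble — two vertex-disjoint linear arms of
≤ 3 nodes between a shared source and sink, a bound this package fixes
since none is standard — two unassignable arms are forced onto opposite
haplotypes, using net evidence when present and a seed-deterministic coin
otherwise (a deliberate arbitrary choice that preserves heterozygosity).

Extraction seeds at the longest unvisited labeled node ≥ 500 kb and extends
both ways along the unique successor whose label matches the path's
haplotype or is homozygous; homozygous nodes may appear in one path per
haplotype. When the walk is blocked by unlabeled structure it emits a gap
token named after what lies ahead: > 2 branches → `tangle`, 2 →
`ambiguous_bubble`, a petering unlabeled chain → `coverage_dropout`. A walk
that simply reaches a dead end or the other haplotype's territory stops
cleanly without a gap, so plain contigs stay gapless. Walk gaps carry a
nominal 50 kb estimated length (the true extent is unknowable from the
graph); scaffold joins use 100 kb. These estimates only affect reported
path lengths and AGP gap rows, not any decision. Full tangle traversal via
ultralong-read support is explicitly out of scope: the walk stops and
gaps instead.

## Scaffolding

End windows span min(5 Mb, path_length/2) from each path end, in path
coordinates (node lengths concatenated; graph edge overlaps are ignored for
layout, a simplification that misstates window boundaries by at most the
overlap lengths). Pairs are retained when no side has > 5 equal mappings
and the sides share no node. Primary weight: each retained pair distributes
exactly 1.0 over the m₁·m₂ links it induces (1/(m₁·m₂) each); links whose
two mappings fall into end windows of two different paths accumulate into
that end-pair candidate. Secondary weight counts unique-unique pairs at 1.
Mappings on nodes absent from every path are ignored.

Bonuses multiply both weights (the secondary too — the evidence the bonus
encodes is independent of mapping uniqueness): ×3 when the joined ends'
terminal nodes are < 500 kb apart in the graph, measured as the Dijkstra
sum of intervening node lengths (endpoints excluded, overlaps ignored);
×5 when both ends have homology, through the match list, to intervals on a
common third path whose projected gap is ≤ 1 Mb (the "close in p3" notion
needed a number; 1 Mb is configurable). A reference genome can serve as the
third path by supplying paths-vs-reference alignments. Both bonuses
compound to ×15.

Joins: per round, a candidate is accepted when it is the best at both of
its ends with margin > 1.5× the second best, on primary weights; secondary
weights are consulted only in rounds where primaries yield no mutual pair.
Accepted joins of a round apply simultaneously (avoiding order dependence
among independent mutual-best pairs), consume their ends, and a union-find
over paths rejects circles and palindromes; rounds iterate to a fixpoint.
Telomeric ends never extend. The telomere rescue then handles components
where one haplotype is T2T and its homolog (identified through node-level
homology between paths) has one telomere: a one-ended telomeric stub within
500 kb of the open end is attached, telomere outward, unless another path
holds > 1 Mb of the component. Scaffold gaps are annotated `scaffold_join`,
or `rdna_like` when both flanking nodes carry a user-supplied
rDNA-proximity tag.

## Screening

Isolated nodes < 100 kb are removed first. A contig matches the screening
set when hits with identity ≥ 97.5% and per-hit length ≥ 10% *of the
contig* (the contig-side reading matches the intent of discarding short
spurious hits) union to ≥ 50% of the contig. Matches expand ≤ 4 hops
through the graph; a neighbour joins when ≤ 4× the length of the node it
was reached from (nearest-reached, so diverged copies chain but large
flanking nodes stop the spread). Exemplars: among a target's matched
contigs, ≥ 2 contigs with > 90% match breadth are ranked by read coverage,
otherwise the largest breadth wins; the exemplar is trimmed while its start
exactly repeats at its end over > 1 kb (exact match only; a k-mer-based
relaxation exists but is off by default), run to a fixpoint so trimming is
idempotent.

## Synthetic data

The generator plants, per chromosome, two parallel chains of long unitigs
(250–600 kb uniform, all above the 200 kb phasing threshold), homology
matches covering 95% of each homolog pair, ~30× per-haplotype depth
(Gaussian, σ 3), telomere flags on terminal nodes, optionally collapsed
homozygous nodes at 2× depth shared by both chains, and optionally one
shared 150 kb, 4×-depth tangle node splicing into every chain's midpoint —
the acrocentric/rDNA mimic, which also yields the split truth paths (two
per haplotype per chromosome) used by the scaffolding benchmark.

Contacts follow the two properties the method exploits: a pair stays on its
own molecule with probability 0.9, at a genomic distance drawn from a
truncated power law p(d) ∝ d^(−1) (d ≥ 1 kb); otherwise it lands uniformly
on a molecule of the opposite haplotype — homologous chromosomes do not
pair in most nuclei, so trans contacts carry no positional structure and no
bias toward the homologous chromosome. Each node anchors 50 pairs by
default. Mapping confounders are off by default and opt-in via
`multimap_fraction`: an affected pair's second side either maps with
quality 0 or multimaps equally onto the planted homolog node, the hardest
realistic confusion. Everything is a bit-exact function of the seed.

What the simulation does not model: sequence-level reads and base errors,
restriction-site distributions, chromatin-compartment structure in the
contact decay, heterozygosity as length differences between homologs,
segmental duplications beyond the single shared tangle, and coverage along
nodes (depth is per-node). Passing benchmarks therefore demonstrate the
correctness and determinism of the algorithms under the stated generative
assumptions, not end-to-end accuracy on real Hi-C libraries.

## Benchmark sizes and determinism

The shipped benchmarks use two chromosomes × 20 nodes per haplotype
(~8 Mb per chromosome), 50 pairs per node, 20 replicate seeds, and 100
random ≤ 12-node graphs for the exhaustive Kernighan–Lin cross-check —
sizes at which the exhaustive oracle is enumerable and a full run stays
comfortably within a coffee break on one CPU. All randomness flows from a
single seed through `numpy.random.default_rng`; per-component and
per-replicate child seeds are derived arithmetically (or by SHA-256 for
node-set dependence), never from Python's randomized `hash`. Two runs with
the same seed produce byte-identical output files.

## Known limitations

- Phasing output labels are per-component consistent only; joining
  components across chromosomes (e.g. for karyotype-level naming) is out of
  scope, as in trio-labeled pipelines.
- The walk heuristic never traverses unlabeled tangles, trading continuity
  for a guaranteed absence of phase-ambiguous sequence inside contigs.
- Multiway Pore-C contacts are reduced to pairs; higher-order information
  is discarded.
- Secondary-weight bonuses and the 1 Mb third-path gap are package choices
  where the method description is silent; both are configurable.
- Polyploid genomes are unsupported (the bipartition is inherently 2-way).
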