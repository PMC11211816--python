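# Methods

`metassemble` reconstructs full-length transcripts jointly from many
aligned bulk or single-cell RNA-seq samples. This note describes the
model, the algorithms, the defaults, and the limits of what the
synthetic benchmarks show.

## Splice graphs

Each gene locus in each sample is modelled as a weighted DAG
G = (V, E, w). Vertices are partial exons: maximal covered intervals
cut at every splice position observed in the sample. Edges are of four
kinds: *junction* edges (introns implied by spliced alignments, weight
= number of spanning reads), *adjacent* edges (coordinate-touching
exon pieces with continuous coverage, weight = number of read blocks
spanning the boundary), and *source*/*sink* edges added so that every
transcript is an s–t path. A source edge into a starting vertex
carries the sum of that vertex's out-edge weights (mirrored for sink
edges); an isolated single vertex carries its own average coverage so
single-exon loci remain extractable. Vertex weight is average per-base
coverage. Coordinates are 0-based half-open everywhere inside the
package; GTF I/O converts at the boundary.

Dips in coverage shorter than the locus-bundling gap (50 bp) are
bridged when forming covered runs, so a one-base sequencing dip inside
an exon does not fracture the vertex set. Junctions require
`--min-junction-support` reads (default 1: sensitivity is cheap here
because the scorer, not the graph builder, is the precision gate).

## Clustering across samples

Graphs from different samples describing the same locus are grouped by
single-linkage agglomeration on the Jaccard similarity of their
splice-position sets, in decreasing similarity order; a merge that
would push a cluster past the size cap (default: the number of input
samples) is skipped, and linkage stops below `--min-similarity`
(default 0.1, preventing unrelated loci that share one splice site
from merging). Candidate pairs are restricted to graphs that overlap
genomically. Two junction-free graphs have similarity 0 by convention;
they co-locate only through genomic overlap. Each cluster gets a
*combined graph* built from the pooled reads of all members.

## Bridging

A paired-end fragment leaves its middle unsequenced. Bridging infers
it as a path in the splice graph connecting the two mates, each mate's
own junction chain being forced. Among candidate connecting paths the
package maximizes the minimum edge weight along the connection
(bottleneck objective), breaking ties by fewer junctions and then by
shorter exonic length, via dynamic programming over the DAG in
coordinate order. This is deterministic and favours well-supported
routes.

Bridging runs in two stages. Stage 1 bridges every fragment in its own
sample's graph. Only fragments that fail — typically because their
sample's graph misses a junction — are retried against the combined
graph (stage 2). Stage-2 successes are used to *refine* the individual
graph: every junction their paths traverse that is absent from the
sample's graph is restored with weight equal to the number of rescued
fragments crossing it, and the exon partition and coverages are
recomputed. After refinement all fragments are re-expressed as
*phasing paths* in the refined graph; fragments failing both stages
contribute their two mate paths separately. Fragments wider than
`--max-bridge-span` (500 kb) fail fast.

## Edge supports

For every edge e of every graph in a cluster, a length-N vector M_e
records the corroboration from each member graph: exact-coordinate
junction weight for junction edges; same-boundary adjacent edge weight
— or, failing that, the coverage of a vertex strictly spanning the
boundary — for adjacent edges; and, for source/sink edges, the weight
of a boundary edge at the matching terminal exon, allowing one
adjacent hop outward limited to `--max-boundary-ext` bases (default
200, strict). When both an adjacent-edge match and a spanning vertex
exist, the explicit edge wins. A member supports its own edges (the
self-entry equals the edge's weight). Supports compose across merged
edges by elementwise minimum.

## Decomposition

Graphs are reduced vertex by vertex until only parallel s–t edges
remain; each surviving edge, with its recorded interior vertices, is a
candidate transcript. Two principles:

1. **Phase preservation.** Whenever a phasing path threads in-edge,
   vertex, out-edge, that pair is realized as a new edge; no phasing
   path is ever broken, so each appears contiguously in at least one
   output transcript.
2. **Support guidance.** At a complex vertex (in- and out-degree ≥ 2),
   in/out edges untouched by phasing are paired with the counterpart
   maximizing the summed composed support across samples (isolated
   vertices of the bipartite pairing graph, resolved left side first,
   then right, in edge order; ties to the first counterpart).

Trivial vertices (in- or out-degree 1) pair all in/out combinations and
are processed first; among complex vertices the one with the smallest
in-degree x out-degree is decomposed next (leftmost on ties).

Two bookkeeping details matter for correctness:

* **Disjunctive path ends.** When a vertex at one *end* of a phasing
  path is decomposed, the path's terminal edge is absorbed into
  several merged edges. The fragment witnessed only the terminal edge,
  so the path then asserts *one of* the merged candidates — a pending
  disjunction resolved at the neighbouring vertex, preferring an
  already-phased pairing and otherwise choosing by support. Treating
  the end as a definite continuation would fabricate phasing evidence
  and measurably increases chimeric output; treating it as droppable
  breaks phase preservation. When both ends have been absorbed the
  path degenerates to a join constraint (some lead candidate must pair
  with some trail candidate), after which its content provably lies
  inside one surviving edge.
* **Weight reallocation.** Each in-edge's weight is split across its
  paired out-edges proportionally to their weights (equal split when
  all partners have zero weight). This conserves the total weight
  leaving the source exactly — the final edge weights are the inferred
  abundances and their sum equals the source-side total to floating
  point precision.

Each merge is also recorded as *phased* (forced by a phasing path) or
*guessed* (support-resolved at a complex vertex), together with the
relative margin of each guess's argmax; these feed the scorer.

## Features and scoring

Every candidate is described by 50 features in four groups — abundance
(14), graph-structural (12), boundary (14), intron (10) — enumerated
with their depth-scaling class in `features.FEATURE_SCHEMA`. They
include the inferred abundance, the supporting-sample count and summed
support of the final edge, bottleneck weight and its support,
phasing-evidence quantities (fraction of phased merges, number of
guessed merges, minimum guess margin), vertex/junction counts of the
individual and combined graphs, whether the identical chain was also
assembled from the other graph type and at what abundance, start/end
boundary weights with their cross-sample supports, and
intron-retention competitiveness (coverage of a junction-spanning
transcript exon relative to the junction weight). Each feature is
declared `count` (scales with depth), `size`/`ratio`/`binary`
(depth-invariant) or `log`; the declaration is tested by duplicating
every read. The schema hash is stored with every model and checked at
scoring time.

The scorer is a random forest (100 trees, maximum depth 20, fixed
seed, balanced class weights because synthetic training sets skew
heavily toward correct candidates). Candidates sharing an intron chain
merge into a meta-transcript scored by the arithmetic mean of member
scores; the representative exon chain comes from the highest-abundance
member. Emission keeps meta-transcripts with score ≥ threshold
(default 0.5; 0.2 is the recommended floor below which output should
be discarded). Single-exon candidates are aggregated by exact span and
emitted, but excluded from training and evaluation, which are
intron-chain based.

The reference model used by the benchmarks
(`pipeline.train_reference_model`) is trained on 12 simulated fixtures
of 60 loci each, alternating sharing fractions 0.5 and 0.9 — the
half-shared fixtures supply the divergent, harder loci whose wrong
candidates the forest must learn to reject.

## Evaluation

A predicted multi-exon transcript matches if its intron chain equals a
reference transcript's exactly (chromosome- and strand-aware);
duplicate predicted chains count once. Precision = matched/predicted,
recall = matched/reference, both over distinct multi-exon chains.
Sweeping the score (or, for baselines, abundance) over a grid yields a
precision–recall curve; pAUC is the trapezoidal area restricted to a
recall interval, by default the curve's own span, or the intersection
of two curves' spans when comparing rankings.

## The simulator

`simulate` generates random gene models (3–12 exon skeletons, exons
80–600 bp, introns 200–5000 bp, ~4 isoforms per locus as ordered
subsets of the skeleton sharing first and last exon), per-sample
truths where each sample expresses a fraction p of the transcript set,
and paired-end reads (100 bp, fragment length N(300, 50) truncated)
emitted directly as perfect spliced SAM alignments — the assembler
consumes alignments, so no sequence-level error model is applied.
Per-sample, per-transcript expression is log-normal(μ=1, σ=1), and the
fragment count targets `depth` × relative-expression coverage (default
20×). Junction dropout removes every read *spanning* a designated
junction while keeping pairs that merely straddle it — exactly the
material stage-2 bridging must rescue; dropped (sample, junction)
pairs are written to `expected_rescues.tsv`.

What the simulator does **not** emulate: alignment errors and soft
clips, coverage bias (GC, 3'/5'), intron-signal noise from unspliced
pre-mRNA, PCR duplicates, or genuinely novel junctions absent from all
samples. Passing benchmarks therefore demonstrate algorithmic
correctness and cross-sample information flow under clean alignments,
not robustness to aligner artefacts.

## Problem sizes for the benchmarks

The randomized property suites use 200 graphs (≤ 15 vertices) for
phase preservation/conservation and 100 three-sample clusters for the
support oracle. End-to-end benchmarks use fixtures of 25–60 loci with
5 samples; the reference corpus totals ≈ 700 loci. These sizes give
stable statistics while keeping the full suite in a few minutes on one
core.

## Known limitations

* **Structurally unphaseable vertices.** A complex vertex whose exon
  is longer than the fragment span cannot be threaded by any phasing
  path; its resolution falls back to support argmax, which composes
  supports by elementwise minimum and therefore tends to favour heavy
  partners. Candidates assembled through such guesses are genuinely
  ambiguous: the scorer assigns them mid-range probabilities, so they
  dominate both errors and discoveries near the 0.2 floor. On clean
  20× five-sample fixtures this caps precision at the 0.2 floor around
  0.72–0.81 (recall ≈ 0.9); at the 0.5 default threshold precision is
  ≈ 0.9 at recall ≈ 0.8.
* **Score calibration is regime-dependent.** Clean synthetic data
  yields ~80% correct candidates, so an honestly calibrated score for
  an ambiguous candidate sits near 0.4–0.5, not below 0.2. Balanced
  class weights mitigate but do not remove this; thresholds tuned on
  one data regime should be re-examined on another.
* Clip-based junction inference is not implemented; junctions come
  only from N operations in CIGAR strings.
* The bridging objective is bottleneck-optimal dynamic programming,
  not the full nomination/voting scheme of dedicated bridging tools.
* Weight updating is one-pass proportional reallocation, not an
  LP-based flow balancing; abundances are deliberately conservative
  point estimates, not EM-polished quantifications.
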