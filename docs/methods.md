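# Methods

`homoclust` infers homologous clusters of protein sequences and serves
annotation-support queries over them.  This note records the model, the
parameters that matter, the numerical choices, and what the synthetic data
used for testing does and does not establish.

## Pairwise similarity model

Two proteins are compared by **semi-global (free-end-gap) alignment**:
global alignment in which gap runs at either end of either sequence cost
nothing, while internal gaps pay affine penalties (a gap of length *L*
costs `gap_open + L·gap_extend`).  This mode is appropriate when homologs
differ in length or overlap end-to-end: terminal overhangs carry no
evidence against homology and should not be penalized.  Defaults are the
BLASTP standards — BLOSUM62, gap open 11, gap extend 1 — and are
configurable (`ScoringParams`; matrices in NCBI text format can be loaded).

Each aligned pair yields three ratio statistics:

* **len_ratio** = aligned-region length / max(|a|, |b|).  The aligned
  region spans the columns from the first to the last column pairing two
  residues, inclusive: terminal overhangs are excluded, internal gaps are
  included.  With internal gaps the region can slightly exceed the longer
  sequence's length, so values marginally above 1 are possible and are
  kept as-is.
* **match_ratio** = exactly matching columns / aligned-region length
  (percent identity over the aligned region).
* **score_ratio** = alignment score / min(self-score of a, self-score of
  b), where a self-score is the sum of diagonal matrix entries.  The
  smaller denominator keeps the ratio ≤ 1 for dominant-diagonal matrices.

All three equal 1 for identical sequences, and all are invariant under
argument swap (the pair is aligned in a canonical order so tie-broken
tracebacks cannot differ between `(a,b)` and `(b,a)`).

Numerical/degenerate choices: the dynamic program is biotite's C aligner
with terminal penalties disabled; on top of it the **empty-overlap
alignment** (every residue against a terminal gap, score 0) is admitted,
because for incompatible sequences it beats any forced residue pairing.
Internal insert/delete adjacency is never optimal at these penalties (two
gap opens cost 24, worse than the worst BLOSUM62 substitution −4), so
`max(engine, 0)` is the exact free-end-gap optimum; this is validated in
the test-suite against brute-force enumeration of every alignment of short
strings.  When no column pairs two residues, the region length is 0 and
match_ratio is defined as 0.

## Similarity graph

Vertices are sequences; an undirected edge joins a pair with
`len_ratio` **strictly greater than 0.80** (the default threshold) and
carries `len_ratio` as its weight.  A secondary identity gate,
`match_ratio ≥ 0.40`, is applied as well (configurable; 0 disables).  The
gate is necessary, not cosmetic: free-end-gap alignment at 11/1 penalties
lets *unrelated* sequences of similar length reach full-span, gap-riddled
alignments whose coverage exceeds 80% by chance, and on synthetic data
such chance alignments produce abundant spurious edges that fuse unrelated
families.  Chance alignments have near-random identity (≈ 20% over the
region), while genuinely homologous pairs sit far above 40% — the classic
floor below which sequence similarity stops being reliable evidence of
homology.  Coverage alone still decides the weight.

All pairs are evaluated (no pre-filter); at the scales this package
targets (10²–10⁴ sequences per batch) this is the simplest correct choice.

## Community detection

Clusters are communities under weighted **modularity**

    Q = Σ_c [ w_in(c)/m − (d(c)/2m)² ]

maximized by a sequential, fully deterministic **Louvain** scheme: phase 1
sweeps vertices in ascending input order, moving each to the neighboring
community with the largest strictly positive gain (ties: stay put; among
better communities the smallest index wins); phase 2 aggregates
communities and repeats.  The process stops when a full level improves Q
by less than `gain_threshold = 1e-6` (applied per level; configurable).
Q is recomputed per level and asserted never to decrease.  An edgeless
graph returns the all-singleton partition.  On every test graph small
enough to solve exhaustively (≤ 8 vertices: cliques, paths, a barbell,
disjoint triangles and squares, weighted variants) the result attains the
global modularity maximum.

## Iterative batch clustering and merging

Sets too large to cluster at once are divided into batches:

1. Each batch is clustered; communities of size ≥ 2 become *sub-clusters*,
   size-1 communities *singletons*.
2. Each batch is condensed to its **representatives** — the first (lowest
   within-batch index) member of each sub-cluster — plus all singletons;
   a schedule groups condensed batches into new batches, which are
   clustered again.  Outputs not consumed by a grouping carry forward.
   Indices are frozen before any deduplication.
3. The final iteration clusters a single batch.

When condensed batches are combined, exact duplicate residue strings are
dropped (first kept; default on, disable with `cross_batch_dedup=False`).
Every drop is recorded as a merge onto the kept sequence, so the dropped
sequence's lineage still reaches the final cluster — nothing is lost and
the final clusters plus singletons always partition the filtered input
exactly.

**Merging** expands the final communities back through the recorded
provenance: an original sequence expands to itself, a carried singleton to
its own expansion in the source batch, a representative to the union of
expansions of its sub-cluster's members.  A final-iteration singleton that
represents an intermediate sub-cluster (whose members grouped at an
earlier level but never re-clustered) keeps those members together as a
cluster; only an expansion of size 1 remains a singleton.  Batch labels
(`A_11#a_15` for members, `Sa_1#a_1` for singletons) extend bijectively
beyond 26 batches (A…Z, AA…).

Under separability — every within-family pair passes both edge gates,
no between-family pair does — iterative clustering with merging is
identical to clustering everything as a single batch; this equivalence is
asserted on synthetic data for 2- and 3-way splits over five seeds.

## Query engine and SSNs

The membership store is a single-file SQLite database (member id,
accession, annotation, cluster id, validation flag — flags start at 0 and
are flipped by a curator-driven `mark_validated`), with a FASTA copy of
all sequences alongside.  A query ranks every stored sequence by
semi-global score (ties: higher len_ratio, then accession), and returns
the best hit's full cluster; a top hit with `len_ratio < 0.5`
(configurable) is reported as no match.  The search is an internal
alignment scan, dependency-free and deterministic; a BLAST-backed engine
would be a drop-in behind the same interface but is not required by
anything in the package.

**Sequence similarity networks** compare selected sequences alignment-free
by k-mer distance, `d = 1 − Σ_t min(count_a(t), count_b(t)) /
(min(|a|,|b|) − k + 1)` with default k = 3: one minus the fraction of
shared k-mers relative to the shorter sequence.  d = 0 is a perfect match;
1 means nothing shared.  Only symmetry, range and zero diagonal are
claimed — k-mer distance is not a metric.  The SSN is the complete graph
over query plus ≥ 2 selected sequences; distances render with 6 decimals.

## Synthetic data

`synth` plants homologous families: each family is a set of independent
mutants of one random seed sequence, with i.i.d. per-site substitutions
(uniform over the 19 alternatives) and optional indels (per-site events;
insertions have geometric length, p = 0.5, deletions are single-site).
Around them it plants length-matched random decoys (so coverage, not
length, must separate them), exact duplicate copies, and records annotated
"hypothetical protein".  All randomness flows through one seeded NumPy
generator; outputs are byte-identical across runs and platforms.

Defaults: 5 members per family, seed length 120 (a typical protein-domain
scale), substitution rate 0.05, no indels.  Guidance for the 0.80
threshold: sub_rate ≤ 0.15 and indel_rate ≤ 0.02 keep planted families
connected.  For two independent mutants at rate r, per-site identity is
(1−r)² + r²/19, which the generator reproduces within one percentage
point.

What the synthetic data does *not* emulate: real protein families have
rate heterogeneity across sites, domain architecture and shuffling, shared
low-complexity regions, and between-family similarity continua.  Passing
tests establish the pipeline's correctness contracts (conservation,
equivalence, determinism, exact recovery under separability), not recall
or precision on real proteomes, where threshold choice dominates.

## Problem sizes in tests and the acceptance script

The exhaustive alignment oracle covers all pairs of strings of length ≤ 2
over a 4-letter alphabet plus 200 seeded random pairs of lengths 3–6 (the
number of alignments per pair grows as Delannoy numbers, so exhaustive
enumeration is kept to short strings).  The Louvain optimality suite uses
graphs of ≤ 8 vertices (Bell(8) = 4140 partitions each).  Equivalence runs
use 10 families × 5 members with 2 decoys per seed.  These sizes are the
package's chosen verification scale; all checks are regenerated
programmatically at run time.

## Known limitations

* All-pairs graph construction is O(n²) alignments; batching is the
  intended mitigation, not a k-mer pre-filter.
* The match_ratio gate (0.40) is a package addition motivated above; on
  datasets where remote homologs fall below 40% identity over the aligned
  region it should be lowered (it is a single keyword argument).
* Louvain is a greedy heuristic: optimality is verified only on the
  exhaustively solvable suite; on larger graphs it inherits Louvain's
  usual resolution behavior.
* The query engine's no-match floor (len_ratio 0.5) is a pragmatic
  default with no external calibration.
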