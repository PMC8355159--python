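# Methods

## Clone model

A *clone* is the set of IgH rearrangements inferred to descend from one
VDJ recombination event. Two sequences can belong to the same clone only
if they use the same V gene, the same J gene, and have CDR3s of the same
nucleotide length; within such a partition, membership is decided by
CDR3 amino-acid identity.

**Stage 1 — identity clustering.** Within each (V gene, J gene, CDR3
length) cell, sequences are single-linkage clustered at identity ≥ 0.85
(inclusive: 85% is read as a floor). A single-linkage hierarchy cut at
one threshold equals the connected components of the graph with an edge
wherever identity ≥ 0.85, which is what the implementation computes;
this makes the default order-invariant and exactly reproducible.
Complete linkage is available as an option for users who prefer
non-chaining clusters. Identity is positionwise: matches / length, with
`X` (a masked or ambiguous residue) matching only `X`. Partitions whose
CDR3 length is not a multiple of 3 cannot be translated; they fall back
to nucleotide identity at the same threshold so that non-productive
records can still be organised when the productive-only switch is off.

**Stage 2 — consensus collapse.** Each cluster gets a copy-weighted
per-position majority consensus CDR3 (ties broken A<C<G<T; `N` never
beats a concrete base). Clones whose consensus sequences are within
Hamming distance 2 are merged transitively, *ignoring* V/J calls — the
stage exists to absorb clones split off by incorrect gene calls — but
never across CDR3 lengths, where Hamming distance is undefined. The
merged clone takes its V/J labels from the largest pre-merge clone and
recomputes its consensus from the pooled members. Because recomputed
consensi can create new ≤ 2-nt pairs, the merge iterates to a fixed
point; this is what makes a second application of the collapse a no-op.

Gene calls are reduced to gene level at ingest (allele suffix after `*`
stripped, first of a comma-separated ambiguous call kept), since the
partition rule operates on genes, not alleles.

## Metrics

* **D20** — sort clone copy counts descending (stable sort, ties by
  clone id, so the rank-20 boundary is deterministic), sum the top 20,
  divide by the total. With ≤ 20 clones the index is 1 by construction.
* **Replicate Jaccard** — each sorted sample is amplified as two
  libraries; the Jaccard index of their clone-id sets (each clone
  counted once, no size weighting) measures clone resampling, an
  independent correlate of clone size. Two empty sets define 0 with a
  warning rather than NaN.
* **SHM** — per clone and per subset, the copy-weighted mean percent of
  mutated V positions over that subset's member sequences, from
  `v_mutation_count` or from Hamming distance between the
  germline-aligned V segment and its germline slice (positions with `N`
  on either side are excluded from the denominator). A clone is "with
  SHM" when this percent is ≥ 1% of compared positions — a conventional
  buffer against sequencing error, configurable; a threshold of 0 means
  the strict reading (any mutation). The fraction of mutated clones per
  stratum is reported unweighted (each clone once) and copy-weighted;
  the two coincide when all clones have equal subset copies.
* **CDR3 length / VH usage** — each clone counts once per
  (strain, subset) stratum. VH usage keeps the 20 most used genes
  (total clone count, lexicographic tie-break) and min–max normalizes
  each gene row to [0, 1], the behaviour of relative-scheme heatmap
  tools; a constant row has no dynamic range and maps to 0, flagged in
  the returned object.
* **Overlap** — computed within one animal only; clones from different
  mice arise from independent recombinations and are never pooled
  (cross-animal summaries average matrices). Presence merges the two
  replicate libraries of each sample by default. Jaccard uses presence,
  cosine uses copy-count vectors over the union clone axis; both
  diagonals are reported as 1 and should be masked for display scaling.
  Venn regions are exact membership-combination counts and partition the
  clones present in at least one subset.

## Productive-sequence handling

A rearrangement is *functional* when its CDR3 length is a multiple of 3
and the translation contains no stop codon (an explicit `productive`
flag wins when present; any codon containing `N` translates to `X`).
Whether non-functional sequences are excluded from all analyses or only
from the replicate-overlap comparison is not externally fixed; the
pipeline exposes one switch and excludes them everywhere by default.

## Synthetic repertoire generator

The generator emulates the targeted study design — 4 strains × 2 mice ×
6 sorted subsets × 2 replicate libraries, 200 clones and 600 copies per
sorted sample — with these mechanisms:

* **Clone sizes**: a truncated discrete power law. Each clone receives
  one guaranteed copy, and the remaining copies fall multinomially on
  Zipf weights rank^(−α) over a random rank assignment. Defaults
  α = 0.4 (FoB), 0.9 (ABC), 1.3 (GCB), 1.8 (PB/PC) produce a clear,
  well-separated D20 gradient at n = 200 clones while keeping every
  subset polyclonal; repertoire clone-size distributions are heavy
  tailed, and a single exponent is the smallest model with tunable skew.
* **Sharing**: per mouse, subsets are processed in a fixed order; subset
  k adopts each clone already present in an earlier subset l with
  probability `sharing[{l,k}]` (deduplicated), then draws fresh founders
  up to its clone count. For an isolated pair at equal n the shared
  count is Binomial(n, p), giving E[Jaccard] ≈ p/(2−p), the closed form
  the calibration tests check; sharing 0 yields exactly disjoint pools
  and sharing 1 (equal n) identical ones. Defaults: 0.15 between all
  pairs, 0.35 for ABC↔PB/PC, realizing the elevated ABC–plasmablast
  association as the simplest pairwise upweighting.
* **SHM**: per emitted sequence, Poisson(rate × 300 nt) substitutions on
  the germline V; rates 0.001 (FoB), 0.008 (ABC), 0.02 (GCB, PB/PC) per
  nucleotide. With the 1% calling threshold these give near-zero FoB,
  intermediate ABC and high GCB/PB mutated-clone fractions.
* **Within-clone structure**: each clone-sample draws 1 + Poisson(0.5)
  CDR3 variants; the founder-identical variant always exists and takes
  the largest expected share (60%). Other variants mutate the founder
  CDR3 at 0.02 substitutions per base — ~0.8 nt on a typical CDR3, so
  expected within-clone amino-acid identity stays well above the 0.85
  clustering threshold.
* **Errors and replicates**: each variant's V call is relabeled to a
  random other gene with probability 0.02 (these are what the 2-nt
  collapse is designed to absorb), and its copies split binomially
  (p = 0.5) between the two libraries.
* **Germlines** are synthetic random sequences with IMGT-style names:
  tests need no downloads, and mutation counting only requires a
  consistent reference, not a biological one.

CDR3s are sampled as random amino-acid strings (Cys…Trp anchors,
10–18 aa) and back-translated through random synonymous codons, so
founder clones essentially never collide; real repertoires have biased
VDJ junction statistics, convergent (public) clones, indel sequencing
errors and primer/amplification biases that the generator does not
model. Recovery results on it therefore demonstrate correctness of the
clustering logic under the modelled noise sources, not clone-calling
accuracy on real MiSeq libraries. One known departure from real data:
with equal clone counts per subset, replicate-library Jaccard runs
*against* the D20 gradient (steeper-skew subsets carry more singleton
clones that miss one library); in the real design the effector subsets
are also far less diverse, which is what drives their higher resampling.

## Numerical and degenerate-input choices

Clone ids are assigned by (descending total copies, consensus CDR3,
V call, J call), so reports are stable across runs and platforms. The
identity threshold comparison uses a 1e-12 tolerance to protect exact
boundary cases (e.g. 17/20) from float rounding. Empty strata raise
rather than return NaN; zero-clone or zero-abundance subsets in overlap
matrices yield 0 entries with warnings. Feasibility of a simulation
config (every clone must receive ≥ 1 copy) is checked before sampling.

## Verification scale

The test suite verifies the clustering against a brute-force all-pairs
oracle on 500 random ≤ 12-record instances, conservation/idempotence
properties on 200 random instances, ground-truth recovery (ARI ≥ 0.95,
collapse strictly reducing split errors) over 20 single-mouse cohorts at
the default design, subset-ordering reproduction over 50 seeds, and
Jaccard-estimator calibration over 200 simulated mice at n = 500 per
subset — sizes chosen so the full suite runs in well under a minute on
one core while keeping Monte-Carlo standard errors far below the effect
sizes being checked.
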