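# Methods

This note records the models, conventions and numerical choices behind
each module, what the synthetic generators do and do not emulate, and
the design decisions taken where the underlying procedure was open.

## Coordinates and formats

All internal coordinates are 0-based half-open. GFF3 (1-based,
inclusive) is converted at the parse boundary; the conversion and its
inverse are exercised as involutions in the tests. Chromosome labels
match exactly — no "chr"-prefix normalization is applied, because
silent renaming hides data errors. narrowPeak column 10 holds the
summit offset, with −1 the single encoding of "summit absent"; BED6
peaks never carry a summit. UCSC chains with a minus-strand target are
stored as written (reversed frame) for lossless round-trips and flipped
to forward coordinates (pos′ = size − pos) when blocks are expanded, so
everything downstream sees one coordinate frame.

## QC metrics

Library complexity is computed on a tally of read positions keyed by
(chromosome, strand, 5′ end): NRF = distinct/total, PBC1 = M1/distinct,
PBC2 = M1/M2 with M1 and M2 the positions observed exactly once and
exactly twice. M2 = 0 yields PBC2 = +inf, the sentinel for a maximally
complex library. FRiP counts a fragment when it shares ≥ 1 bp with the
merged peak set — the common operational rule; a stricter 5′-end
containment mode is available. Pass/concern tiers default to ENCODE
guideline values (NRF, PBC1 ≥ 0.8; PBC2 ≥ 3; FRiP ≥ 0.01) and are
configuration, not constants.

## Element annotation

The anchor of a peak is its summit when present, else the interval
midpoint. The class boundary is *strict* on the enhancer side: distance
> cutoff (default 1,000 bp) → enhancer, distance ≤ cutoff → promoter,
so a peak exactly at the cutoff is a promoter. Equidistant TSS ties
resolve to the lexicographically smaller gene id for determinism. The
target window *N* is the median gap between merged gene bodies
(chromosome ends excluded; even counts take the mean of the middle
two), capped at 3,000 bp. Target assignment: genes overlapping the
element body by ≥ 1 bp win outright; otherwise the nearest gene start
within *N* bp on *each* side is taken (≤ 2 genes), reconciling a
single-nearest reading with the observed ≤ 2-genes-per-element bound; a
strict single-nearest mode is a flag. miRNA genes use the 5′ end of the
precursor as their start, which is the same strand rule as the TSS.

## Tissue specificity

The primary score is the Jensen-Shannon divergence of the normalized
profile from the uniform distribution, in bits, with 0·log 0 ≡ 0. It is
0 for flat profiles and maximal, JSmax(K) < 1 bit, on unit vectors
(≈ 0.7583 bits at K = 10), scale-invariant and permutation-symmetric.
A normalized mode divides by JSmax(K). The highly-specific call uses a
strict inequality (score > cutoff, default 0.26) and the cutoff is a
parameter rather than a constant because published pipelines differ in
the variant and scale they use; a per-tissue 1 − √JS(p, e_t) variant is
provided for compatibility. Clustering of called elements row-
normalizes profiles and runs k-means with 25 seeded restarts (best
within-cluster sum of squares kept, fixed max 300 iterations), which
makes the partition deterministic under a seed. Sample similarity is
Spearman correlation between tissue columns, with constant columns
recorded as 0 with a warning, ordered by average-linkage clustering on
1 − r.

## TF co-association

Footprints are merged per TF before scoring; multiple experiments per
TF should be pooled upstream (union), the simplest reduction consistent
with one row per TF. The elbow statistic sorts all off-diagonal scores
descending, scales both axes to [0, 1], and takes the score at maximum
perpendicular distance from the endpoint chord (kneedle-style; ties to
the smaller rank). Curves with < 3 distinct values or no measurable
knee (max distance < 1e-9 on the unit square) fall back to the
configured 0.2 operating point with a warning. Modules are greedy
modularity-maximizing communities on the thresholded weighted graph;
isolated nodes are reported separately. The module method is validated
purely on planted synthetic structure — on real data it is a heuristic
like any community detection.

## Regulatory networks

The miRNA-target filter is inclusive (score ≤ 4 by default) with a
direction flag, since predictors differ in whether lower is better.
Self-edges a→a are retained in the graph, but a feed-forward loop
requires three distinct roles, so tf_b ≠ tf_a. Target-layer membership
is restricted to a TF-gene catalog by default (relaxable by flag). The
overlap test between two loop sets is Pearson's chi-square without
continuity correction on the 2×2 membership table over a declared
universe; degenerate margins are flagged rather than scored.

## Cross-species conservation

Projection intersects an element with all gapless chain blocks and
keeps the single (chain, block) pair of largest bp overlap (ties:
higher chain score, then smaller chain id), mapping that piece linearly
into the target genome — one orthologous interval per element.
Alignability requires ≥ 1 projected bp by default; a minimum
aligned-fraction gate exists because "alignable" is not quantitatively
pinned down in common usage. Conservation requires the orthologous
interval to be covered by a peak at ≥ 50 % of *its own* length
(inclusive boundary); the denominator is deliberately the orthologous
interval, not the source element. Chromatin-state conservation projects
*all* state bp blockwise (not just the largest piece) and reports
conserved bp over the union of the projected track and the partner
state track. State vocabularies across species are a user-supplied
mapping concern, not inferred.

## Synthetic data: what a green test establishes

All generators derive their randomness from one integer seed fanned out
through (seed, generator-name) streams, so outputs are byte-identical
under a fixed seed and adding a generator never perturbs another.

- **Genome**: gene lengths gamma(shape 4, mean 2 kb), intergenic gaps
  gamma(shape 1.5, mean 8 kb), genes packed sequentially per
  chromosome. The emitted gap median is checked against the analytic
  gamma median.
- **Atlas**: specific elements put weight w = 0.9 on one tissue and
  spread the rest uniformly; broad elements draw from a symmetric
  Dirichlet(8) (near-uniform with realistic jitter). Noise is
  multiplicative log-normal, σ = 0.25 — positive signal with plausible
  dispersion; no claim is made that real accessibility noise is
  log-normal. A peak is "called" in a tissue when the element's signal
  exceeds 5 % of its row sum, chosen so broad elements are called in
  most tissues and specific ones essentially only in their own.
- **TF sets**: module site pools are laid out on a disjoint slot grid,
  so the p_in = 1, p_out = 0 extreme yields within-module Jaccard
  exactly 1 and cross-module exactly 0.
- **Meta-network**: edges are sampled independently at densities
  0.15/0.10/0.15 over 50 TFs, 20 miRNAs and 80 targets; the planted
  loop count is an exhaustive enumeration at generation time, and decoy
  miRNA-target rows above the score cutoff force the filter to do real
  work.
- **Species**: one shared blockwise partition (exponential blocks, mean
  5 kb) underlies all comparison species; each species keeps a block
  with probability q_align = 0.8 and concatenates survivors with random
  ≤ 200 bp spacers into one chain per chromosome. Source peaks are
  placed strictly inside single blocks, which makes the planted
  alignable probability exactly q_align and the conserved probability
  exactly q_align·q_peak (q_peak = 0.7), free of block-straddling edge
  effects. Class-specific q_peak overrides let experiments plant a
  promoter-vs-enhancer conservation contrast.

None of the generators model sequence, read errors, within-block
indels, or inversions (minus-strand chains are exercised only through
the coordinate-flip parser tests). A green recovery test therefore
establishes that the estimators recover the planted structure under
this stated world — not that the distributional choices match any real
organism.

## Pipeline

Stages write outputs atomically (temp-then-rename) into the output
directory; `run-all` recomputes a stage only when an output is missing
or an upstream stage re-ran. The manifest records parameter snapshots,
SHA-256 digests of outputs, wall time and captured warnings; it is the
only output excluded from the byte-determinism guarantee (it contains
timings). Floats in TSV outputs are formatted with %.10g so identical
computations serialize identically. The `network` stage consumes the
generator's TF→target edge table directly; on real data that table is
the join of element target assignments with per-experiment TF labels,
produced by the annotation stage.

## Known limitations

- Nearest-TSS queries index TSS positions only; gene-body overlap in
  target assignment is a linear scan per element, adequate at the
  tested scales (≤ 10⁴ elements × few hundred genes) but not tuned for
  whole-mammalian-genome annotation sets.
- The co-association elbow is a geometric heuristic; on score
  distributions without a knee it falls back to a fixed operating
  point.
- `conservation_scores` reprojects each element per species with a
  linear scan over that species' chains; chain sets with very many
  records would warrant an interval index.
- Statistical significance of co-association (vs the Jaccard value
  itself) and loop-level motif statistics are out of scope.
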