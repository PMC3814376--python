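# Methods

This note documents the models and procedures implemented in `chromarch`,
the parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions that
matter for reproducing results.

## Differential transcription from GRO replicates

GRO measures nascent transcription (RNA polymerase density), so the
pipeline interprets signal ratios as transcription-rate changes, not mRNA
abundance changes. Processing per gene and strain:

1. **Normalization.** Each replicate's signals are divided row-wise by the
   genomic-DNA hybridization signal, which cancels per-filter (or per-probe,
   if supplied per gene) efficiency differences. A missing or non-positive
   gdna value is an error naming the strain and replicate — silently
   skipping a replicate would bias the ratio.
2. **Outlier filtering.** A value is kept iff |x − median| ≤ k·MAD with the
   unscaled MAD = median(|x − median|) and k = 3. Two degenerate guards:
   MAD = 0 keeps everything, and vectors with fewer than 4 values are never
   filtered. The second guard is deliberate: for a triplet the sample MAD
   equals the smaller of the two gaps around the median, so any k of a few
   units flags a value in roughly half of Gaussian triplets — an absurd
   discard rate for ordinary noise. With triplicate designs the filter
   therefore only reports, matching the expectation that no more than ~2%
   of signals are discarded (the `OutlierRule.max_discard_frac` cap is a
   reporting threshold, not an enforcement mechanism).
3. **Merging.** Arithmetic mean of surviving replicates; a gene needs at
   least two valid replicates in *each* strain, otherwise it is excluded
   from the analysis universe (and from every downstream enrichment).
4. **Calling.** R = mutant mean / control mean; up if R > 1.5, down if
   R < 0.65, strict inequalities. The ratio-of-means (rather than
   mean-of-ratios) form is robust to per-replicate dropout, since the two
   strains' replicate sets need not align after filtering.
5. **ESR subtraction.** Strict sets are raw sets minus the corresponding
   environmental-stress-response list, a plain id-set difference; ESR
   membership is consumed as given, never re-derived.

Replicate quality is summarized as pairwise Pearson correlations of
normalized signals per strain (computed on genes present in both members
of a pair).

## Enrichment statistics

* **Relative enrichment**: observed/expected with expected =
  |subset|·|class ∩ universe|/|universe|. An expected count of zero is an
  error (undefined ratio), not a zero.
* **Fisher exact (two-sided)**: sums hypergeometric probabilities of
  tables, given the margins, that are no more probable than the observed
  one. Delegated to `scipy.stats.fisher_exact`; the test suite verifies it
  against an independent full enumeration for every 2×2 table with margins
  ≤ 10 (2925 tables).
* **Bootstrap enrichment p**: the null draws subsets of the observed size
  uniformly without replacement; the trial overlap count is sampled from
  the equivalent hypergeometric distribution (identical in law, much
  faster). p = (1 + #extreme trials)/(1 + n_trials) with n_trials = 1000,
  so p is never exactly 0. Two-sided extremeness is |ratio − 1| ≥
  |observed − 1|; a one-sided alternative is available. Every call is
  seed-deterministic.
* **Wilcoxon rank-sum**: midranks for ties; exact distribution for pooled
  n ≤ 12 without ties, normal approximation with tie correction otherwise
  (`scipy.stats.mannwhitneyu`). Two groups of all-identical values return
  p = 1. All tests are two-sided by default; sidedness is a caller option
  since enrichment direction is reported separately.
* **Z-scores** use the population convention (divisor n); a zero-variance
  vector is an error so the caller decides the fallback (TFBS matrices
  leave such rows raw and flag them).
* **Expression variability** is |q98 − q2| (linear-interpolation
  percentiles) after dropping the strictly lowest and highest
  floor(0.01·n) values.
* **Moving average by covariate** sorts genes by the covariate (stable
  sort) and averages a centered window (default 100 genes), shrinking the
  window symmetrically at the edges so every output stays centered.

Multiple testing: raw p-values are reported with a fixed significance
threshold of 0.001 for mark/remodeler flags; no FDR correction is applied,
matching the analysis convention this pipeline reproduces.

## Promoter and sequence analyses

Coordinates are 0-based half-open everywhere; offset 0 is the TSS base,
upstream is negative, and all profiles are oriented 5'→3' along the gene.

* **Promoter** = the complete intergenic interval from the TSS-side gene
  boundary to the nearest boundary (5' or 3') of the closest other gene on
  either strand, clipped at chromosome edges; abutting neighbors give
  length 0.
* **Bidirectional promoters**: adjacent gene pairs with strands (−,+) in
  coordinate order, nothing between them, TSS-to-TSS span ≤ 600 bp, each
  gene in at most one pair. TSS-to-TSS distance is used for the span.
* **TFBS matrices**: site counts per factor in 20-bp bins over −500..+300
  around the TSS (40 bins). The downstream extension reconciles a 40-column
  layout with a 20-bp bin width; both bounds are configurable. Optional
  per-factor Z-scoring.
* **Sliding composition**: GC fraction, (A−T)/(A+T) and (G−C)/(G+C) in
  100-nt windows stepped by 1 nt, value assigned to the window center
  (start + window//2 — note an even window has a half-position center
  asymmetry under strand reversal, bounded by 1 bp). Zero-denominator
  windows yield 0 with a flag rather than a hole, keeping profiles
  rectangular.
* **Meta-profiles** average per-gene windows position-wise; minus-strand
  genes are reversed and skew statistics are negated on reversal (strand
  complementation negates A−T and G−C). Genes whose window crosses a
  chromosome edge are dropped and counted. Conservation tracks may have
  missing positions; these are averaged over the genes that have data, and
  a warning is recorded when more than half the interrogated positions are
  missing.

## Nucleosome analyses

* **Spacing**: nucleosomes are assigned to a gene body when their midpoint
  lies inside it (an any-overlap rule is available); spacing is the mean of
  the N−1 edge-to-edge gaps between consecutive sorted nucleosomes,
  undefined (not an error) for N < 2. Edge-to-edge linker length is the
  only reading compatible with mean spacings of ~21–29 bp for ~147-bp
  particles.
* **Occupancy profiles**: per gene, the fraction of each 10-bp bin covered
  by the union of nucleosome intervals, averaged over genes, optionally
  Z-scored. Verified against a per-bp counting oracle to 1e−12.
* **Dynamic classes**: the same computation restricted to the appearing /
  evicted / fragile label, reported in percent.
* **Remodeler enrichment**: observed/expected ratio plus bootstrap p per
  (remodeler, gene set) pair; per-pair seeds are derived deterministically
  from the stage seed.
* **Histone marks**: Wilcoxon rank-sum of subset vs rest-of-universe scores
  per mark and compartment, with the sign of the median difference giving
  the enriched/depleted direction. Marks scored for less than half the
  subset are skipped with a warning.

## Curvature symmetry (nucleosome-forming potential)

The score follows the concept of dyad-symmetric intrinsic curvature.
Curvature uses a dinucleotide wedge model: each step contributes a bend of
fixed magnitude (bundled consensus-style table, degrees per step,
reverse-complement symmetric, editable via `CurvatureModel`) pointing along
the helical phase 2π/10.4 per step; over a 31-bp window the deflections are
summed as 2-D vectors and the mean resultant magnitude is assigned to the
center base. This makes helically phased bends (A-tracts every ~10.5 bp)
add coherently while unphased flexibility cancels. Symmetry is
S(i) = 1/(1 + D(i)) with D(i) the mean |c(i−k) − c(i+k)| over k = 1..73
(half a nucleosome). Properties guaranteed and tested: S ∈ (0, 1], S = 1
exactly on mirror-symmetric flanks, exact strand invariance given the
reverse-complement-symmetric table, and NaN propagation from ambiguous
bases through every window touching them. The window lengths and the table
are documented defaults of this implementation, not values taken from any
published score, and no numerical equality with other curvature tools is
claimed.

## Synthetic world

The generator's defaults encode the study conditions the pipeline is
validated under:

| parameter | default | rationale |
|---|---|---|
| fold_up / fold_down | 2.0 / 0.5 | comfortably beyond the 1.5 / 0.65 call thresholds |
| noise_sigma | 0.1 | log-scale replicate noise giving replicate r > 0.95 |
| n_replicates | 3 | triplicate design |
| frac_up / frac_down | 5% / 3% | deregulated-set sizes at the few-percent scale |
| esr_overlap_frac | 1/3 | fraction of deregulated genes also in ESR lists |
| gc_background | 0.375 | yeast genome average GC |
| gc_dip_depth | 0.10 | depth of the promoter GC dip over (−250, 0) |
| pr2_switch_amp | 0.10 | purine excess downstream / pyrimidine excess upstream of TSS |
| linkers (down/up/background) | 21 / 29 / 25 bp | class-specific spacing planted for recovery |
| nucleosome_width / NFR half-width | 147 / 90 bp | canonical particle, NFR over (−90, 0) |
| mean intergenic gap | 400 bp (geometric) | compact yeast-like intergenic spacing |
| base expression | lognormal, σ_log = 0.5 | right-skewed intensity distribution |
| mark_shift | 1 SD | planted acetylation loss in upregulated genes |
| remodeler_boost | 3× | planted remodeler-target enrichment of downregulated genes |

Gene placement tiles chromosomes with uniform gene lengths (1–2 kb) and
geometric intergenic gaps; strands are random, so divergent pairs arise
naturally. Sequences are sampled per base from position-dependent
probabilities implementing the GC dip and the PR2 switch on the gene
strand (mapped through complementation for minus-strand genes).
Upregulated genes additionally receive a 146-bp reverse-complement
palindromic cassette at the +1 nucleosome position: the palindrome makes
the curvature track mirror-symmetric about the cassette center (any
RC-symmetric wedge table), planting a recoverable curvature-symmetry peak
near +73, and its phased A-tracts give it high curvature. Nucleosome
arrays are deterministic: +1 at the TSS, then class-linker-spaced
particles within the gene body; −1/−2 upstream of the NFR but only within
the gene's share of the intergenic gap (half the gap when the neighbor's
promoter faces it), so bulk nucleosomes never overlap and each gene body
contains exactly its own array — which is what makes linker recovery exact.
GRO signals are base·fold·lognormal-noise·gdna-factor, so with zero noise
the ratio is exactly the planted fold and truth recovery is perfect by
construction.

A single seed drives generation; sub-generators (layout, classes,
sequence, GRO, TFBS, marks, lists) are spawned at fixed offsets, so worlds
and written files are bit-identical across runs.

What the generator does **not** emulate: array-image noise, probe
cross-hybridization and saturation, cell-cycle or growth-phase
heterogeneity, transcript-length effects, correlated replicate structure,
overlapping or nested genes, introns, and realistic sequence composition
beyond the planted GC/PR2/cassette features. Passing the desk-scale
validations therefore demonstrates correctness of the estimators on data
that match the model's assumptions, not robustness to every artifact of
real arrays.

## Pipeline and reproducibility

The orchestrator loads all inputs up front (a missing file aborts with the
stage name and path), runs the stages in order, and writes one TSV per
analysis plus `summary.json`. Outputs are staged in a temporary directory
and moved into place only after all stages succeed, so failures leave no
partial results. All thresholds and bin sizes live in `PipelineConfig`
(YAML-loadable, CLI-overridable); all randomness flows from its single
seed, and reruns are byte-identical. Profile values in the JSON are
rounded to 6 decimals.

Problem sizes used by the validation suite and `scripts/acceptance.py`:
the study world has 2000 genes on 4×1.15-Mb chromosomes; oracle checks use
2925 Fisher tables and 100 random occupancy instances; null calibrations
use 500 simulations of 1000-trial bootstraps (subsets of 1000 from a
universe of 10000) and 500 Wilcoxon tests (n = 25 vs 40). These sizes give
stable estimates at interactive runtimes.

## Known limitations

* The MAD filter is inert for fewer than 4 replicates by design (see
  above); studies with many replicates engage it as usual.
* Bidirectional-pair detection uses TSS-to-TSS distance; annotations whose
  ORF ends differ greatly from TSSs may warrant the configurable span.
* The TFBS window (−500..+300) is a reconciliation of a 40-bin layout with
  20-bp bins; both bounds are configurable.
* The curvature model is a deliberately simple wedge-magnitude model; it
  captures phased-bend structure but not sequence-specific flexibility or
  protein-DNA energetics.
* Enrichment p-values are reported raw with a fixed 0.001 flag; users
  needing family-wise control should correct externally.
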