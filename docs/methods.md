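# Methods

## The locus model

The package is organized around a `LocusModel`: an ordered list of genes, a
boundary interval (the insulator anchor), and a catalog of regulatory
elements. The default model is the Chr11q22.2 MMP cluster with the IE8
insulator at chr11:102,732,800–102,733,900 (hg38, stored 0-based
half-open). Gene spans are approximate (rounded to the kb); only their
order and rough spacing matter for the synthetic analyses, and the package
accepts any user-supplied annotation where exact coordinates matter. A
gene's side of the boundary is decided by its strand-resolved TSS relative
to the boundary midpoint — the TSS is the regulatory anchor for every
promoter-centric analysis, so it is also the partitioning anchor. The
non-MMP neighbors TMEM123 and BIRC3 co-express with the 5' block but are
excluded from the default 5' signature (the normalization convention is
defined per MMP gene); `include_neighbors=True` restores the wider cluster
membership.

All coordinates are internally BED-convention (0-based, half-open).
Conversion to the 1-based inclusive coordinates used in prose happens only
in `to_display`/`parse_region`, so exactly one code path can host an
off-by-one. Element catalogs with unknown strand are treated as "+" where
orientation matters.

## Signature scores

Normalization follows the cohort convention: non-detected values (zeros)
are replaced by the gene's minimal detected signal across the cohort, on
the raw count scale, *before* the log transform — "minimal detected
signal" is a signal-scale quantity, and replacing before the transform
keeps the floor interpretable. Then log2(count + 1), then subtraction of
each gene's cohort median (idempotent; per-gene medians are exactly zero
afterwards).

The 3'/5' "ratio" is a difference of per-set means on the standardized
log2 scale — equivalently the log of a ratio of geometric means — never a
quotient of linear values, which would be undefined at zero. Per-set
aggregation is the unweighted mean by default (the simplest symmetric
choice); `aggregator="median"` is available because the choice is a
convention, not a derivation. `SignatureScorer` packages the chain as a
scikit-learn transformer: `fit` learns the per-gene floors and medians on a
reference cohort, `transform` applies them, so scores for held-out samples
are computed against the training cohort's calibration.

Group comparisons use the Mann–Whitney rank-sum test with midranks. For
combined n ≤ 10 the null is enumerated exactly over all label assignments
(this handles ties correctly, which textbook exact tables do not);
otherwise the normal approximation with tie and continuity correction is
used.

## Coexpression boundary scan

The two-block structure of the locus correlation matrix is formalized as a
scan: for each split k of the coordinate-ordered genes,
score(k) = mean within-block correlation (both blocks pooled, diagonal
excluded) minus mean between-block correlation; the boundary estimate is
the argmax (ties to the smallest k). Spearman correlation is the default
(robust to residual skew on the log scale); Pearson is a flag. Undefined
correlations from zero-variance genes are excluded pairwise, and the scan
refuses to run if more than 20% of pairs are missing.

Significance comes from a max-statistic permutation null: random gene-order
permutations are re-scanned and the best scores compared. Arrangement
symmetries (any permutation that maps the best bipartition onto a
contiguous split) produce exact ties with the observed maximum, which makes
naive inclusive counting conservative (~3% rejection at nominal 5%); the
implementation therefore breaks ties uniformly at random —
p = (#greater + U·(#tied + 1))/(B + 1) with U ~ Uniform(0,1) drawn from the
same seeded generator — giving an exact randomization test (measured null
rejection ≈ 5–6% at α = 0.05). The same device is used for the eQTL
statistic below, whose null distribution is discrete.

## Survival and progression

Survival statistics are deliberately implemented from first principles so
each has a hand-checkable oracle: the Kaplan–Meier product-limit estimator;
the two-group log-rank test with hypergeometric variance; and the O/E
(Pike) hazard-ratio estimator HR = (O₁/E₁)/(O₂/E₂) with
SE(log HR) = √(1/E₁ + 1/E₂). The O/E estimator was chosen over a
partial-likelihood fit because it is dependency-free, testable cell by
cell, and adequate for two-group stratification; lifelines serves as an
independent cross-check in the test suite, not as the implementation.
Conventions: follow-up restriction administratively censors at the cutoff
(default 60 months, event → 0, time → cutoff); censored subjects tied with
an event time remain at risk at that time; stratification defaults to the
median split of the analyzed cohort (an explicit cutoff is a flag — the
median is a convention, and cutoff optimization would need a max-statistic
correction that is out of scope).

AUC is the midrank Mann–Whitney concordance probability, with ROC points
at every distinct threshold and a percentile bootstrap CI stratified by
class (default 2,000 resamples, seeded) so small cohorts keep their class
balance in every resample.

## Differential accessibility and enrichment

A consensus peak (present in every replicate) is differential either by
*unique presence* — nonzero in all replicates of one condition and zero in
all replicates of the other — or by *intensity shift*: Welch's unequal-
variance t on log2 counts-per-million, Benjamini–Hochberg across tested
peaks, significant iff FDR < 0.05 and |log2FC| ≥ 1 (both flags). The sign
of the fold change labels the peak gained or lost in the perturbed
condition. Both thresholds are conventions exposed as parameters.

Windowed enrichment around the anchor uses peak-midpoint membership (so
counts partition consistently across nested windows), the representation
factor RF = (k/n)/(K/N), and the exact hypergeometric upper tail
P(X ≥ k). The universe N is the consensus peaks on the anchor's
chromosome, matching the chromosome-vs-windows contrast the analysis
makes; a whole-chromosome control row (RF = 1 identically) is always
emitted. TSS profiles average normalized intensity in ±2 kb around each
TSS in 40 bins, flip minus-strand genes so bins run 5'→3', and compare
per-gene deltas between the 5' and 3' clusters with the rank test.

## Insulation and architecture

The insulation score is the standard sliding-square statistic: raw(i) is
the mean of the w×w submatrix of contacts between the w bins upstream and
w bins downstream of bin i (default w = 10 bins = 100 kb at 10-kb
resolution, sized for desk-scale matrices), normalized as
log2(raw / chromosome-wide mean). It is invariant to global scaling of the
matrix. Boundaries are local minima whose dip strength — the smaller of
the score rises to the nearest flanking local maxima — clears
`min_strength` (default 0.1). Contact matrices round-trip through a
header + upper-triangle triplet text format, symmetrized on load.

Convergent CTCF pairs are (upstream "+", downstream "−") motif pairs in
which exactly one member overlaps the anchor — the orientation required
for loop formation between insulator elements. The eQTL statistic is the
fraction of links whose SNP and target TSS fall on the same side of the
boundary; positions exactly at the boundary count as upstream (arbitrary
but deterministic). Its null preserves SNP positions and permutes the
observed target genes across links — conditioning on both marginals — with
the randomized tie rule above.

## Synthetic data

The generators are pure functions of (config, seed); each draws from its
own RNG stream derived from the root seed by a fixed offset, so adding a
generator never perturbs the others, and identical seeds give
byte-identical outputs end to end.

* **Expression** — a latent Gaussian copula: multivariate normal log2
  values with correlation ρ_within = 0.5 inside each cluster and
  ρ_between = −0.3 across (PSD-checked), location μ = 8, scale σ = 1,
  exponentiated and rounded to counts, with 5% dropout producing
  non-detected zeros. The copula gives exact control of the correlation
  target, which correlated negative-binomial constructions do not.
* **Outcomes** — exponential event times with hazard
  h₀·exp(β·z(score)), h₀ = 0.012/month, β = 0.283 (chosen so the
  median-split hazard ratio under this model is near 1.6, the regime of
  interest); 30% of subjects receive Uniform(0, 60) censoring; everything
  truncates at 60 months. Progression labels follow the binormal model:
  scores are mapped through their ranks onto the binormal marginal and
  labelled with that model's posterior, so the population AUC is exactly
  Φ(d/√2); the default separation d = 1.045 targets AUC 0.77 on the
  driving marker. In the in situ preset (n = 85, prevalence 14/85) the
  MMP1/MMP8 contrast drives progression — it is the stronger marker — and
  the correlated 3'/5' ratio then shows its naturally lower AUC; in the
  invasive preset (n = 417) the ratio drives relapse hazard.
* **ATAC peak sets** — 34,047 consensus peaks (study-scale) uniform on one
  20-Mb synthetic chromosome (long enough to hold the ±10 Mb outermost
  window), anchor at the midpoint. Differential probability is 10%
  background, ×3 within ±0.5 Mb of the anchor. Differential peaks draw
  |log2FC| from (2, 3); 20% are emitted condition-unique (mean zero on one
  side but kept in the consensus list, so the unique-presence branch is
  exercised on a single coordinate universe). Replicate counts are
  negative binomial, mean ≈ 200, dispersion 0.01 — the tight
  reproducibility of clonal cell-line replicates, and the operating point
  at which a 3-replicate Welch t + BH analysis has the sensitivity (≥ 0.8
  at log2FC = 2) the pipeline is validated against.
* **Contact matrices** — expected contacts depth·|i−j|^(−1) (depth 100 at
  adjacent bins), multiplied by 0.2 for pairs strictly straddling the
  boundary bin (i < b < j); the boundary bin itself contacts both domains,
  which makes the noiseless insulation minimum unique at b. Entries are
  Poisson-sampled on the upper triangle and mirrored. Defaults: 100 bins
  of 10 kb with the origin placed so the IE8 midpoint falls in bin 50.
* **eQTL links** — SNPs uniform over the locus span; targets drawn from
  the SNP-side genes with probability 0.9 (same_side_prob), the far side
  otherwise.

What the generators do *not* emulate: batch and platform effects, copy
number, tumor purity and stromal admixture, overdispersed single-sample
library composition, realistic peak width/GC structure, distance-dependent
eQTL effect sizes, or loop-level contact enrichment. Passing tests
therefore demonstrate the correctness and calibration of the statistics
under the stated generative assumptions — not robustness to every artifact
of real cohorts.

## Problem sizes and numerical conventions

Validation sizes were chosen to make the statistical checks decisive while
keeping the full suite fast on a laptop: exhaustive oracles (all censoring
patterns n ≤ 6; all hypergeometric tuples N ≤ 60; full 6! correlation
permutations), 100-seed recovery runs for each generator at default
conditions, 200–1,000-replicate null calibrations, and 199–999 permutations
inside each permutation test. Bootstrap and permutation counts are
parameters, so heavier runs are one flag away.

Degenerate inputs fail loudly rather than silently: empty groups,
single-class labels, constant score vectors, genes with no detected
values, all-zero replicates, non-PSD correlation targets, anchors outside
the matrix span. Floating-point tie comparisons in permutation tests use
a 1e-9..1e-12 guard band on the relevant scale.

## Known limitations

The O/E hazard ratio is mildly conservative for large effects and is not a
covariate-adjusted model; use a proportional-hazards fit when covariates
matter. The boundary scan assumes the two blocks are contiguous in genomic
order and finds exactly one split. The consensus-peak operation anchors
coordinates on the first replicate rather than building a re-merged
coordinate set. The insulation caller reports bin-resolution boundaries;
sub-bin localization is out of scope. External-cohort effect sizes (hazard
ratios, AUCs measured on real tumors) depend on cohort composition and
platform processing that the synthetic cohorts deliberately do not model;
the package reproduces the methods, and its synthetic presets reproduce
the qualitative regime, not the printed point estimates.
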