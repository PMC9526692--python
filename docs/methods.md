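# Methods

This note documents the statistical and geometric methods implemented in
`osteomics`, the choices made where the underlying procedures are commonly
left under-specified, and what the synthetic-data generators do and do not
emulate.

## Study design and data model

The package targets a four-class label-free quantification (LFQ) design:
bone marrow stromal cells in osteogenic differentiation sampled at day 8 and
day 28, each under normal gravity (GC) and simulated microgravity on a
random positioning machine (RPM), plus a day-zero (T0) reference. The
replicate structure is three biological replicates per class except two for
T8_GC — 14 samples in total. Intensities live in an `IntensityMatrix`
(protein groups × samples, gene-symbol index, `CLASS_rep` column labels,
`NaN` for missing).

## Differential-abundance chain

The processing order is fixed and mirrors the Perseus-style workflow:

1. **T0 referencing.** Per-gene arithmetic mean of non-missing T0
   intensities; every later sample is divided by it and T0 is dropped.
   A missing or non-positive reference voids the gene's ratios (warning
   logged) rather than aborting, so noisy synthetic edge cases survive.
2. **Valid-value filter.** A gene is kept iff some class has
   (non-missing / class size) ≥ 0.7, computed on the exact class size with
   no rounding: 2/3 fails, 2/2 passes.
3. **log2 transform.** Non-positive non-missing values are an error.
4. **Downshifted-Gaussian imputation.** Missing entries in sample column
   *s* are drawn from `N(μ_s − 1.8·σ_s, (0.3·σ_s)²)`, with `μ_s`, `σ_s` the
   column's observed mean and sample sd. Width 0.3 and downshift 1.8 are
   the de-facto Perseus defaults for left-censored LFQ data; both are
   configurable. Imputation is per sample column, requiring ≥ 2 observed
   values per column.
5. **One-way ANOVA.** Classical between/within mean-square F over the four
   classes, p from F(k−1, N−k). Implemented directly (vectorised sums of
   squares) because the permutation loop recomputes it thousands of times
   and because degenerate rows need a defined convention: zero between and
   within sums of squares ⇒ F = 0, p = 1; zero within with distinct means
   ⇒ p = 0.
6. **Permutation-based FDR** (default 250 permutations, 5 % target). Class
   labels are shuffled across all 11 samples (class sizes preserved) and
   all ANOVA p-values recomputed per permutation. The estimated FDR at
   cutoff *c* is `mean_perm #{p_perm ≤ c} / max(1, #{p_obs ≤ c})`; the
   significance cutoff is the largest observed p with estimated FDR ≤ 5 %,
   and no genes are called when none qualifies. This is the plain ratio
   estimator with no variance-moderation (s0 = 0) term — the simplest
   faithful reading of a permutation FDR on ANOVA p-values.
7. **Tukey HSD post hoc** on significant genes (Tukey–Kramer for the
   unequal T8_GC class), via the studentized-range distribution; each of
   the six class pairs records which mean is higher and significance at
   α = 0.05.
8. **Isoform de-duplication.** Records whose gene symbols share a base
   name after stripping a trailing `-N` suffix collapse to the
   smallest-p record (ties by name). This automates what is usually a
   manual curation step.
9. **Trend classification.** Direction at each time point is read off the
   same-time GC-vs-RPM pair: e.g. significant with RPM lower at T8 and
   nothing at T28 ⇒ `down_T8_only`; both times down ⇒ `down_both`;
   opposite directions ⇒ `mixed`. Genes with no significant same-time SMG
   pair fall into `time_only` (the maturation signal, judged from the
   within-condition time pairs); genes significant only in a cross pair
   (e.g. T8_GC vs T28_RPM) are also binned as `time_only` so the eight
   categories stay exhaustive. Percentages are reported at 1-decimal
   rounding.

Determinism: `run_pipeline` threads a single `numpy` Generator through
imputation and permutation, so a fixed seed gives bit-identical results.

Reported `neg_log_p` is −log10 of the ANOVA p-value, the convention of the
software this workflow emulates.

### Summaries

- **Top regulated genes**: ranked by the mean RPM−GC log2 difference
  averaged over the two time points, ties by gene name.
- **Z-score + hierarchical clustering**: per-row z-scores (sample sd),
  average-linkage Euclidean clustering of rows and columns with scipy's
  deterministic leaf order; zero-variance rows are an error naming the
  gene.
- **PCA**: samples as observations on the mean-centered processed (log2
  ratio, imputed) matrix; variance fractions normalised to sum to 1. A
  count-style variance-stabilizing transform is deliberately not applied
  to proteomic intensities; the log2 ratio matrix is the natural input
  here.

## Concentric-belt image quantification

For a cell image with a manually drawn edge polygon and a centrosome
(brightest in-cell pixel; ties broken by smallest row then column, maxima
outside the polygon ignored), each interior pixel *p* gets a normalized
radius `ρ = |p − c| / R(θ)` where `R(θ)` is the distance from the
centrosome to the **first** boundary intersection of the ray through *p*.
Belt index is `min(floor(ρ·n_belts), n_belts − 1)` with 11 belts by default
(belt 0 at the centrosome, belt 10 at the periphery). Using the per-ray
edge distance rather than a single maximal radius makes belts follow the
drawn cell shape; belts are equal in radial fraction, not in area — the
annular appearance of the masks motivates this reading.

Geometry conventions: (row, col) coordinates, 0-based, pixel-center
rasterization (a pixel is interior iff its center lies inside the polygon);
ray–segment intersections are solved in continuous coordinates against the
polygon edges, vectorised over pixels, taking the nearest positive hit.
For non-convex cells a pixel beyond the first boundary crossing can have
ρ > 1; the clamp to the outermost belt absorbs it.

Per belt, the profile records the mean intensity and the area fraction —
pixels strictly above a single per-cell threshold (Otsu on interior pixels
by default; a fixed value can be supplied) divided by the belt's pixel
count. Empty belts are flagged NaN. Group comparisons (e.g. 15 GC vs 15
RPM cells) run a pooled-variance Student's t per belt on the cells' mean
intensities. Whole-image totals (sum of intensities, thresholded area) are
provided for extracellular-matrix immunostaining images.

## Assay calculators

- **2^−ΔΔCt**: ΔCt = mean Ct(target) − mean Ct(reference, default 18S) per
  condition; ΔΔCt against the gravity-control calibrator at the same time
  point; fold change 2^−ΔΔCt. Spread is propagated as the sd of
  per-replicate ΔCt values, giving the asymmetric range 2^−(ΔΔCt ± sd) —
  the common practice when only "mean ± sd" is specified.
- **Standard curves**: ordinary least-squares line absorbance =
  slope·concentration + intercept (both assays operate in their linear
  range; a four-parameter logistic is deliberately omitted).
  Back-calculation inverts the line; values outside the standards' range
  are flagged extrapolated, not rejected.
- **Crystal statistics**: per-group min/max/mean, a shared-bin frequency
  distribution (fractions summing to 1 per group), and a pooled-variance
  Student's t.
- **Student's t** is pooled-variance by default everywhere (Welch behind a
  flag), two-sided. Zero pooled variance with equal means gives (0, 1);
  with unequal means, p = 0 flagged by an infinite statistic. A
  summary-statistic variant supports reconstructing tests from published
  mean ± sd tables.

## Over-representation analysis

Hypergeometric upper tail `P(X ≥ k)` with background N, set size K (after
intersecting the annotation set with the background), list size n, overlap
k; enrichment ratio `(k/n)/(K/N)`. Query genes missing from the background
are an error listing the offenders. No multiple-testing correction by
default, matching the raw p < 0.05 convention of the workflow this
replaces; Benjamini–Hochberg is available behind a flag. The default
background is the quantified matrix's gene set. The four regulation lists
are `down_T8 = down_T8_only ∪ down_both` etc.; a gene regulated at both
times appears in two lists.

## Synthetic-data generators

- **Proteomics**: per-gene baseline log2 intensity ~ N(20, 2²), replicate
  noise sd 0.25 (typical median-normalized LFQ scales), linear intensity
  2^(baseline + class effect + noise). A fraction `frac_dapg` of genes is
  spiked; with a scalar effect magnitude each spiked gene receives one of
  the six RPM-trend patterns uniformly at random (shifts applied to the
  RPM classes), so the ground-truth category follows the same sign mapping
  the classifier uses and recovery is well-posed. Missingness is
  missing-not-at-random by construction: within each sample column, values
  below the column's empirical `mnar_quantile` (default 0.05) are
  censored — exactly the left-censoring the downshifted-Gaussian
  imputation assumes. What is *not* emulated: correlated proteins,
  batch/run-order effects, peptide-to-protein roll-up noise, and
  intensity-dependent variance; passing tests therefore demonstrate
  correctness of the statistical machinery under its own assumptions, not
  performance on real acquisitions.
- **Cell images**: intensity inside the polygon is
  `peak·exp(−decay·ρ) + noise` with ρ the same normalized radius the belt
  algorithm uses, background noise outside, non-negative clipping, and the
  specified centrosome enforced as the brightest pixel. Multi-channel
  stacks, optics (PSF blur) and segmentation error are not simulated.
- **qPCR / plates**: triplicate wells; Ct tables built so the 2^−ΔΔCt
  round trip is exact at zero noise (gravity-control ΔCt equals a fixed
  baseline offset, default 5 cycles); absorbances follow the specified
  line. Pipetting drift and plate-position effects are not modelled.

All generators are deterministic functions of their seed.

## Problem sizes and validation choices

The package's own validation (test suite and `scripts/acceptance.py`) uses
1000-protein matrices in the 14-sample study design: 20 null simulations
for the false-discovery check and 5 spiked simulations (10 % spiked,
|effect| = 2 log2 units, noise sd 0.25) for power and trend recovery, with
250 permutations throughout. Sensitivity is defined as recall among spiked
genes present in the preprocessed matrix: genes removed by the valid-value
filter (fully censored in every class) never enter the test, so they
measure the censoring level, not the power of the statistics. Belt
geometry is validated on a 64×64 irregular cell against an exhaustive
per-pixel ray-casting oracle (shapely) and on a 128×128 circular cell
against analytic annuli; the radial decay constant is recovered from a
log-linear fit of belt means at belt midpoints.

## Known limitations

- The permutation-FDR ratio estimator is not monotonised; with few
  permutations the estimated-FDR curve can be non-monotone in the cutoff.
  At 250 permutations and the tested sizes this has no practical effect.
- The trend classifier reads direction only from the same-time GC-vs-RPM
  pairs; cross-pair-only significance is absorbed into `time_only`.
- `dedupe_isoforms` is purely lexical (suffix stripping); it cannot know
  about biologically distinct paralogs whose symbols look like isoform
  suffixes.
- The belt algorithm assumes a simple polygon and a centrosome strictly
  inside it; self-intersecting hand-drawn edges are rejected rather than
  repaired.
- ORA treats annotation sets as flat gene sets; no ontology-graph
  redundancy reduction is attempted.
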