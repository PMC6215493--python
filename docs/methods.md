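# Methods

## The decomposition

For two column-matched, row-independent matrices `D_1` (tumor bins ×
patients) and `D_2` (normal bins × patients), each of full column rank
`N ≤ min(M_1, M_2)`, the GSVD `D_i = U_i Σ_i Vᵀ` is computed by:

1. thin QR of each `D_i`, giving `N × N` triangular factors — nothing of
   size `M_i × M_i` is ever formed, so the routine is memory-safe for
   millions of bins;
2. QR of the stacked factor pair, then the cosine-sine decomposition of the
   resulting `2N × N` orthonormal block (via an SVD of its upper block;
   the lower block's columns are orthogonal with norms `s_n = √(1−c_n²)`);
3. back-transformation and row-normalization of `Vᵀ`, absorbing the row
   norms into the generalized singular values.

Components are ordered by decreasing `σ_{1,n}/σ_{2,n}` (the SVD's
descending cosines give this ordering directly; a stable argsort enforces
it, ties kept in index order). The factorization is unique up to ±1 per
component triplet outside degenerate subspaces; we fix the phase by making
the largest-magnitude entry of each row of `Vᵀ` positive (ties broken by
lowest index), which makes repeated runs bit-identical. Components whose
ratios agree within a relative 1e-8 are flagged as one degenerate subspace:
their basis vectors are reported but not unique. Rank deficiency (smallest
singular value ≤ 1e-12 × largest, per matrix) is an error naming the
offending matrix and its numerical rank, raised before any factor is
returned.

Exactness is not approximate: tests require relative Frobenius
reconstruction error and basis orthonormality at 1e-10 on pairs up to
5000 × 40, and squared ratios equal to the generalized eigenvalues of the
Gram-matrix pencil `(D_1ᵀD_1, D_2ᵀD_2)` at 1e-8 — the independent oracle
for the same quantity.

### Significance calculus

- Angular distance `θ_n = arctan(σ_{1,n}/σ_{2,n}) − π/4`, strictly inside
  (−π/4, π/4), antisymmetric under dataset exchange.
- Generalized fractions `p_{i,n} = σ_{i,n}^k / Σ_m σ_{i,m}^k`. The default
  exponent is k = 2, the variance-like convention of the GSVD literature;
  k = 1 (weights proportional to the values themselves) is available via
  `fraction_exponent`. The normalized entropy `−Σ p log p / log N` ∈ [0, 1]
  summarizes how concentrated a dataset's information is.
- Component calls: exclusive to dataset 1 when `θ ≥ θ*` and `p_{1,n} ≥ p*`;
  symmetric for dataset 2; common when `|θ| < θ*` and both fractions
  significant; else unassigned. Defaults `θ* = π/8`, `p* = 0.01` are
  operational choices exposed in configuration — the underlying theory only
  distinguishes θ ≈ ±π/4 from θ ≈ 0, so the thresholds mark "clearly
  tilted" vs "clearly shared" at half and an eighth of the extreme value.

## Preprocessing

Raw bin read counts are rescaled per patient so the genome-wide mean is 1
(relative copy number, diploid baseline ≈ 1). Deliberately nothing else —
no per-bin normalization and no GC correction — because separating the GC
artifact is the decomposition's job and correcting it upstream would
destroy the test of that claim. Coordinates are BED-convention (0-based,
half-open) throughout; chromosome Y and non-canonical contigs are dropped
on input with a warning (the analysis covers autosomes + X); an optional
log2 transform for microarray-style inputs is intentionally out of the
default path.

## Segmentation and segment classification

CBS variant: per chromosome, recursively find the circular arc `(i, j)`
maximizing the two-sample t-statistic (pooled whole-segment variance)
between arc and complement; accept the split if the within-segment
permutation p-value of that max-t statistic is below `alpha`; recurse.
Defaults `alpha = 0.01`, `n_perm = 1000`, `min_width = 3`. The conservative
estimator `(1 + b)/(1 + B)` is used, and permutation stops early once the
final estimate can no longer fall below `alpha` — this keeps pure-noise
runs cheap without changing any decision. No pruning/"undo" heuristics:
determinism given the seed is worth more here than the reference method's
small sensitivity gain. The permutation generator is consumed in a fixed
segment order, so results are bit-reproducible.

Segments are classified against a reference (all autosomal bins by
default, or the segment's own chromosome) by
`z = (segment mean − reference mean) / (reference bin SD / √n_bins)`,
amplified/deleted at `|z| ≥ 2` (configurable). The denominator is the
standard error of the segment mean: a raw per-bin SD criterion would make
long segments unclassifiable, since their means are estimated far more
precisely than single bins. z is invariant to affine rescaling of the
pattern, so basis-vector scale is irrelevant.

Cross-pattern bounding (`compare_patterns`) reports, over a shared segment
list, per-class agreement, whether one pattern's altered segments are a
subset of the other's with the same sign, and the fraction also bounded in
magnitude — the "bounded above / below" comparison between patterns from
different technologies or grades.

## Patient classification

Patients are labeled high/low by two routes that the data should make
agree: Pearson correlation of each tumor profile with the pattern
(cutoff 0.15, signed — "high" means positively carrying the pattern), and
superposition coefficients (projections of bin-centered profiles on the
unit pattern; on column-centered data this vector is exactly proportional
to the corresponding row basis vector). The coefficient cutoff transports
0.15 to the coefficient scale as `c_j/‖c‖ ≥ 0.15/‖r‖` — the unique reading
under which the two rules coincide exactly whenever `c ∝ r`; the literal
product form `c_j ≥ 0.15·‖r‖` is available behind a flag but is not
dimensionally consistent. Pattern orientation (the ±1 phase is
statistically arbitrary) is fixed so the mean projection is positive: the
component exists because a subset of patients carries the pattern with a
consistent sign while the rest project near zero, so the mean points
toward the carrier class whatever its size. For the same reason the
X-deletion direction of the gender component is phase-dependent in
isolation; oriented male-positive in the row basis vector, both datasets
report deletion.

### Selecting "the pattern"

Default: among components called exclusive to the tumor dataset, the one
with the largest tumor generalized fraction — skipping components whose
column basis vector correlates with bin GC at |r| ≥ 0.5 when GC is
available. The skip matters because in realistic data the *most*
tumor-exclusive, most significant component is the GC sequencing artifact,
not the biology; an analyst would discard it on sight of the GC
correlation, and the rule encodes exactly that. A manual component index
override is supported everywhere.

## Survival analysis

Kaplan-Meier curves and medians per group (median = first time survival
≤ 0.5; unreached medians reported as NaN and flagged), two-sided unweighted
log-rank, Cox proportional hazards via lifelines with Efron tie handling,
Wald 95% CIs, and Harrell's concordance; uni- and bivariate modes. Age is
dichotomized at the cohort median and grade as IV vs II–III for
comparison analyses (the convention here; both cutpoints configurable).
Non-convergence or complete separation raises an error naming the
covariates.

## Association tests

Mann-Whitney-Wilcoxon through scipy with exact enumeration when
`n_a·n_b ≤ 400` and no ties, otherwise the tie-corrected normal
approximation; two-sided by default. Hypergeometric enrichment is the
upper-tail probability at the observed overlap. Row basis vectors are
converted to patient groups by sign (configurable quantile split). The GC
test pairs the Pearson correlation with an MWW of lowest- vs highest-GC
quartile bins (capturing depressed GC-poor bins specifically). Raw
p-values are reported without multiple-testing correction, matching how
such thresholds are conventionally quoted; the expression panel emits a
Bonferroni column as a convenience.

## The synthetic cohort

The generator defines the study conditions; its defaults are fixed, not
tuning knobs:

- 85 patients, 23 chromosomes (1–22, X) × 870 bins of 1 Kb ≈ 20K bins —
  the cohort's shape at desk scale (the emulated data had ~2.8M bins;
  everything here is per-bin i.i.d. noise, so scale changes cost, not
  structure). The normal bin table carries 25 extra bins so `M_2 > M_1`.
- Carriers: 52/85; the planted pattern is a glioma-like set of co-occurring
  autosomal CNAs (gain of 7, losses of 10 and 9p, partial ±0.5–1-copy
  segments elsewhere; X unaltered), added to carrier tumor profiles only.
- Gender: 53/85 male; males carry one X copy in both tumor and normal — a
  common (θ ≈ 0) component by construction.
- GC artifact: multiplicative `exp(slope·(gc − mean gc))` on expected
  counts with positive slopes, so GC-poor bins are depressed (the
  PCR-dependent underestimation of GC-poor fragments). Slopes differ by
  batch (tumor batches 1.8/1.0/0.3; normal 1.7/1.2/0.7/0.25, ±0.1
  per-sample jitter), and tumor/normal batch labels are assigned
  independently — which is what makes the tumor- and normal-side artifacts
  separate into distinct exclusive components rather than one common one.
  Bin GC is Beta-distributed with mean 0.41, SD 0.055.
- Noise: negative-binomial counts (gamma-Poisson, dispersion 0.02) at mean
  depth 300 per bin, then the same count preprocessing as real data;
  Gaussian and noise-free modes exist for fast or exact tests.
- Survival: exponential event times per group (medians 12 vs 60 months, or
  a specified hazard ratio), under *independent* uniform censoring whose
  horizon is solved so the expected censored fraction matches the
  configured 20%. Independence matters: censoring correlated with the
  event time biases Kaplan-Meier upward, which is a bug in a generator
  meant to calibrate KM recovery.

What the generator does not emulate: real LD-like correlation between
neighboring bins' noise, mappability/blacklist structure, intratumor
heterogeneity and subclonal fractions, bins missing per patient, waning or
non-proportional hazards. Passing recovery tests therefore demonstrates
the pipeline's correctness under its own model, not performance on any
real cohort.

## Numerical notes and limitations

- The cosine-sine construction divides by `s_n`; pairs so close to rank
  deficiency that some `s_n` underflows raise a numerical error rather
  than returning garbage. Orthonormality of `U_2` degrades as
  `σ_1/σ_2 → ∞`; for ratios up to ~1e4 the 1e-10 guarantees hold.
- Monte-Carlo problem sizes in the test suite (50 pairs ≤ 5000×40, 500
  CBS noise replicates of 200 bins, 2 × 200 survival simulations at
  n = 85, 1000 log-rank permutations) were chosen as the smallest runs
  whose pass/fail margins are comfortably beyond sampling noise.
- A single n = 85 cohort estimates a 60-month exponential median with a
  sampling SE near 15 months; median-recovery checks therefore aggregate
  over replicate cohorts instead of asserting tight tolerances on one
  draw.
- The pipeline is two-matrix only (no higher-order or tensor extensions,
  no canonical correlation analysis, which is a different decomposition),
  supports dense matrices only (no per-patient missing bins), and does no
  gene-level annotation of segments.
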