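# gsvdcna

Comparative spectral decomposition of patient-matched **tumor and normal
copy-number profiles** by the generalized singular value decomposition
(GSVD): blind separation of a tumor-exclusive genome-wide copy-number
alteration (CNA) pattern from inherited copy-number variation (the gender/X
relation) and from GC-content sequencing artifacts that vary with
experimental batch, followed by survival-phenotype classification of the
patients.

The package is written for analysts of matched tumor/normal cohorts (e.g.
binned WGS read-count profiles) who want the full pipeline — from bin-level
matrices to Kaplan-Meier curves — as tested, scriptable Python, exercised
end to end on a built-in synthetic-cohort generator with planted ground
truth.

## The model

Given two real matrices `D_i ∈ R^{M_i×N}` (i = 1 tumor, 2 normal) with
column-matched patients but independent row sets (bins; `M_1 ≠ M_2` is
legal), each of full column rank, the GSVD is the exact simultaneous
factorization

```
D_i = U_i Σ_i Vᵀ,   i = 1, 2
```

with `U_i` column-orthonormal (dataset-specific column basis vectors =
genome-wide patterns), `Vᵀ` invertible with unit-norm rows (shared row
basis vectors = patient weights), and `Σ_i = diag(σ_{i,n})` positive.
Components are ordered by decreasing `σ_{1,n}/σ_{2,n}`. Per component, the
**angular distance**

```
θ_n = arctan(σ_{1,n}/σ_{2,n}) − π/4  ∈ (−π/4, π/4)
```

measures exclusivity (≈ +π/4 tumor-exclusive, ≈ 0 common, ≈ −π/4
normal-exclusive), and **generalized fractions** `p_{i,n} ∝ σ_{i,n}²` with
their normalized Shannon entropy measure per-dataset significance. The
decomposition is blind to all labels: patient, bin, and dataset labels are
used only afterwards to interpret components (GC correlation, X-vs-autosome
and gender tests, batch enrichment).

Downstream, a selected tumor-exclusive column basis vector is segmented by
circular binary segmentation (CBS), its segments are classified
amplified/unaltered/deleted by segment-mean z-scores, patients are labeled
high/low by Pearson correlation of their profiles with the pattern (cutoff
0.15, with an equivalent superposition-coefficient cutoff), and the two
classes are compared by Kaplan-Meier/log-rank and Cox proportional hazards.

## Worked example

The whole pipeline on the default synthetic cohort (85 patients, ~20K
1K-nucleotide bins over chromosomes 1–22 + X, 52 planted pattern carriers
with median survival 12 vs 60 months, 53 males with one X copy, batch-
dependent GC artifact, negative-binomial count noise):

```python
from gsvdcna import synthetic_cohort as sc, genome_io, core_gsvd
from gsvdcna import patient_classification as pc, survival_analysis as sa
from gsvdcna.cli import select_pattern_component, _oriented_pattern

tumor, normal, cohort, truth = sc.generate(sc.SimulationConfig(seed=7))
pair = genome_io.match_pair(tumor, normal)
res = core_gsvd.gsvd(pair)
calls = core_gsvd.call_components(res)
k = select_pattern_component(res, calls, tumor.bins)

u = _oriented_pattern(res, k, pair)
cls = pc.classify(pc.pattern_correlations(pair.D1, u),
                  pc.superposition_coefficients(pair.D1, u),
                  patient_ids=pair.patient_ids)
df = cohort.df.assign(high_corr=cls.high_by_correlation.astype(int))
km = sa.km_compare(df, "high_corr")
cox = sa.cox_fit(df, ["high_corr"])
```

Output of this run:

```
pattern component: 0   theta: 0.613   tumor fraction: 0.0223
high-correlation patients: 52 / 85    coefficient/correlation agreement: 1.0
KM medians (months): high 9.6, low 43.8    log-rank p: 8.8e-10
Cox hazard ratio: 5.54  (95% CI 3.07–10.0)  concordance: 0.676
recovery vs ground truth: pattern |r| = 0.982, classification accuracy 1.00
```

Reading: the most tumor-exclusive component (θ = 0.61, near π/4) is the
planted CNA pattern (|r| = 0.98 with truth); thresholding correlations at
0.15 labels exactly the 52 planted carriers; their Kaplan-Meier median is
~10 months against ~44 for the rest (planted 12 vs 60; single-cohort
sampling noise), a hazard ratio of ~5.5. A near-zero-θ component
(θ = −0.005, common to tumor and normal) separates the sexes and shows an
X-chromosome deletion in both datasets (MWW p ≈ 1e-223), and the component
most correlated with GC content (r = 0.88) tracks the batch-dependent
sequencing artifact — neither contaminates the pattern.

The same pipeline runs from the shell:

```
gsvdcna run --out runs/demo --seed 7
gsvdcna simulate --out data/ --seed 7
gsvdcna decompose --tumor-matrix data/tumor.h5 --tumor-bins data/tumor_bins.bed \
    --normal-matrix data/normal.h5 --normal-bins data/normal_bins.bed --out gsvd/
```

## Layout

- `gsvdcna.core_gsvd` — the exact GSVD (thin-QR + cosine-sine reduction), angular distances, fractions/entropy, exclusivity calls, HDF5 I/O
- `gsvdcna.genome_io` — BED/TSV/HDF5/FASTA readers and writers, minimal count preprocessing, pair matching
- `gsvdcna.pattern_analysis` — CBS, segment classification, cross-pattern bounding comparison
- `gsvdcna.patient_classification` — superposition coefficients, correlations, the 0.15-cutoff rule
- `gsvdcna.survival_analysis` — Kaplan-Meier/log-rank/Cox (via lifelines)
- `gsvdcna.association_tests` — MWW, hypergeometric enrichment, GC and X-chromosome tests
- `gsvdcna.synthetic_cohort` — the cohort generator and recovery scoring
- `gsvdcna.cli` — the `gsvdcna` command and `run_pipeline`

See `docs/methods.md` for the modeling choices, parameters, and limitations.
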