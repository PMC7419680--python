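# Methods

This note documents the models and numerical choices behind `tnbcstrat`,
what the synthetic generator does and does not emulate, and the known
limitations.

## Preprocessing

Expression matrices are gene-by-sample, assumed already normalized within
platform (RMA/quantile for arrays, log-scale counts for RNA-seq). Gene
symbols are uppercased and whitespace-stripped at ingestion so that
cross-platform harmonization happens in a single symbol space. Rows with
any missing value are dropped (and counted); the package does not impute.
Probe-level data are collapsed to one row per symbol by keeping the probe
with the largest across-sample interquartile range, ties broken by file
order for determinism. Per-sample robust scaling uses
`(x − median) / (MAD · 1.4826)`; the 1.4826 consistency constant makes the
MAD comparable to a normal sd and the operation idempotent. A sample with
zero MAD cannot be scaled and is an error rather than silently passed
through. Per-gene median centering is applied before contrast GSEA only.
For count data a log2-CPM transform with pseudo-count 0.5 (the common
voom-style offset) stands in for a full precision-weighted pipeline;
mean-variance weights are out of scope.

## ssGSEA

For a sample with `N` genes ranked by decreasing expression (ties broken
by gene id), the enrichment score of a set `S` is

    ES = Σ_k [ P_in(k) − P_out(k) ],
    P_in(k)  = Σ_{i≤k, i∈S} r_i^α / Σ_{i∈S} r_i^α,
    P_out(k) = #{i≤k, i∉S} / (N − |S|),

with rank values `r_i = N, N−1, …, 1` and weight exponent `α = 0.25`. Only
ranks enter, so the score is invariant under any strictly monotone
per-sample transform (in particular per-sample MAD scaling). No cross-sample
rescaling is applied at this stage; axis scores are standardized later.
Pathway axes (three ERK1/2 sets, three AKT sets) are combined by
z-scoring each set's score across samples (population sd) and averaging;
zero-variance sets are excluded with a warning.

The gene sets themselves are configuration inputs (GMT): the MSigDB
collections used for the ERK and AKT axes and the published
stromal/immune/cell-type signatures are licensed content and are not
redistributed. Tests and the analysis scripts use the generator's
synthetic stand-in sets. `write_gmt` stores a `role:` tag in the otherwise
unused description field so role assignments survive a round-trip.

## Tumor purity

Stromal and immune scores are ssGSEA scores of the two ESTIMATE-style
signatures; their sum maps to purity through the published cosine
calibration `purity = cos(0.6049872018 + 0.0001467884 · score)`. Arguments
beyond π leave the calibrated domain and yield undefined purity (flagged);
negative cosines are clamped to 0 and flagged. The >60% gate is a strict
inequality, reading the inclusion criterion literally. The same formula is
applied to all platforms; whether that is appropriate for non-array data
is a documented uncertainty of the original procedure, so the output
table carries flags rather than silently mixing scales.

## CTLA-4 adjustment and cluster assignment

Adjusted CTLA-4 is the residual of an OLS fit of CTLA-4 expression on an
intercept, the ESTIMATE score, and the CD4/CD8 infiltration scores. The
model formula `CTLA4 ~ Est + CD4*CD8` is read in the usual model-formula
sense — main effects plus interaction (`covariate_mode =
"interaction_expansion"`); a product-only mode is retained as an option.
Constant covariates are absorbed by the intercept; designs with condition
number above 1e10 are rejected as collinear. Adjustment, infiltration
scores, and all median splits are computed on the purity-gated cohort,
since stratification in the source procedure happens after the gate.
Median dichotomization sends strictly-above-median samples to High;
exact-median ties go Low, so the two groups can differ by at most the
number of tied samples. Cluster codes read (CTLA-4 status, pathway
status); the activated-like phenotype is asymmetric by construction — HH
on the ERK axis (pathway engaged) and HL on the AKT axis (pathway
down-modulated).

## GSEA

The two-phenotype test ranks genes by signal-to-noise
`(μ₁ − μ₀) / (s₁ + s₀)` with each group sd floored at 20% of the absolute
group mean (and at 1e-8), then forms the weighted Kolmogorov–Smirnov
running sum with hit weight `|metric|^p / Σ|metric|^p` (p = 1) and miss
weight `1/(N − |S|)`; ES is the signed maximum deviation. The null
permutes phenotype labels: exhaustively when the number of distinct
assignments is at most `n_perm` (e.g. all 70 assignments of 4-vs-4),
otherwise by seeded sampling with an add-one correction so sampled p-values
are never exactly zero. The nominal p is two-sided
(`|ES_null| ≥ |ES_obs|`); NES divides ES by the mean |null ES| of the same
sign; FDR is the standard same-sign normalized-null ratio, capped at 1.
Sets are reported unthresholded; the conventional FDR < 0.25 cut is applied
by the callers that summarize results.

## Signature scores

Two scoring modes are assigned signature-by-signature, following how each
score is defined in the literature: plain mean expression (cytolytic
activity = mean of GZMA and PRF1; tumor-inflammation, proliferation,
tissue-resident-memory and anti-CTLA-4 immune scores) and ssGSEA
(cell-type panels). Mean-mode scores are linear in expression and
insensitive to gene order; missing signature genes are tolerated with a
logged count, a fully absent signature is an error. Cluster comparisons
use the two-sided Wilcoxon rank-sum test against the HH reference cluster
with BH adjustment across the compared clusters.

## Deconvolution

Bulk mixtures are regressed on an LM22-like gene-by-celltype reference
with linear-kernel ν-SVR over the grid ν ∈ {0.25, 0.5, 0.75} (C = 1).
Mixture vector and reference matrix are z-scored over the shared genes
first, so fractions are invariant to the mixture's scale. Negative
coefficients are truncated at zero and the rest renormalized to a simplex;
the ν with the lowest reconstruction RMSE wins. Significance uses one
shared permutation null per run: random mixtures resampled (with
replacement) from the dataset's own expression values are deconvolved
identically, and a sample's p is the fraction of null fit correlations
reaching its observed one. Relative fractions only; absolute-mode scoring
and batch correction are out of scope. At least 50% of reference genes
must be measured.

## Responder model

A linear-kernel SVM (C = 1) on standardized immune-score features, with
seeded stratified 5-fold cross-validation reported at training time.
Kernel and regularization are the smallest-assumption configuration for a
method described only as "an SVM"; all knobs are arguments. Training
labels are an input table. Predicted-responder enrichment across clusters
uses Fisher's exact test on 2×2 responder-by-cluster tables with BH
adjustment across contrasts; proportions are exact count ratios.

## Exact statistics

2×2 Fisher tests use the hypergeometric formulation (scipy); r×c tables
use a hand-implemented Freeman–Halton enumeration over all tables with the
observed margins, summing probabilities no greater than the observed
table's (relative tolerance 1e-7 for float ties), with the grand total
capped at 500 — beyond that the chi-square test is the intended tool. The
two routes agree to ~1e-12 on 2×2 tables and are kept separate so each can
check the other. The Wilcoxon test is exact (full enumeration) for
combined n ≤ 20 without ties, otherwise a tie-corrected normal
approximation with continuity correction. BH adjustment and Spearman
correlation delegate to statsmodels/scipy.

In the packaged 50-patient count tables, the stage association is tested
with chi-square on the collapsed (TC0 vs TC1–TC3) 3×2 table and the binary
covariates with Fisher's exact test, matching how each covariate was
analyzed in the source cohort.

## Synthetic cohort generator

Expression is `purity · tumor + (1 − purity) · Σ_k f_k · immune_k + ε`,
with gene profiles drawn N(0, 1) on the log scale, Dirichlet(1) cell-type
fractions, uniform purity on [0.30, 0.95], and i.i.d. Gaussian noise
(sd 1). Planted structure, with defaults chosen so each stage's signal is
identifiable while staying within realistic log-expression ranges:

* **CTLA-4**: a tumor-intrinsic bimodal level at ±1.5 around the cohort
  center plus the gene's own noise draw, added on top of the T-cell
  contribution from the immune compartment. The ground-truth CTLA-4 status
  is the median side of the *realized* tumor-intrinsic level — exactly the
  quantity the immune-adjustment regression is meant to isolate — so label
  recovery measures adjustment quality rather than re-measuring Gaussian
  overlap of the planted draw itself.
* **Pathways**: every gene of an axis set shifts by ±1 per the planted
  High/Low label (separation 2), which the three-set ssGSEA average
  recovers nearly perfectly.
* **Purity**: the stromal/immune signature genes are elevated by a
  per-sample intensity calibrated (by monotone interpolation on a small
  intensity grid) so that the noiseless profile's ESTIMATE score inverts
  to the planted purity through the published cosine constants. This
  mirrors how those constants were calibrated to real cohorts, and makes
  the >60% gate testable against truth: residual disagreement comes from
  measurement noise only. With 6,000 genes and 150-gene signatures the
  achievable score range comfortably covers the purity interval.
* **Cell types / deconvolution**: 30-gene marker blocks at strength 5,
  scaled by each sample's absolute cell-type fraction; the signature
  matrix returned to the caller is the profile matrix restricted to the
  marker union, so it is well conditioned.
* **Responders**: a 30-gene immune-score block shifted by +2 in planted
  responders; the training table is produced by generating a separate
  cohort from the same family and computing the actual pipeline features,
  so feature scales match at prediction time.
* **Clinical tables**: categorical TC0–TC3 scores with configurable
  marginals and binary covariates with planted odds ratios relative to the
  CTLA-4-negative stratum.

Everything derives from a single seed and is bit-reproducible. What the
generator does **not** emulate: gene–gene correlation beyond the block
structure, platform/batch effects, heavy-tailed or count noise, spatially
varying stromal composition (stromal and immune content co-vary with
1 − purity by construction), and any real marker-gene identities. Passing
recovery tests therefore demonstrates internal consistency of the pipeline
under its own assumptions, not performance on real cohorts.

## Problem sizes and determinism

The analysis scripts and acceptance checks use a 400-sample, 6,000-gene
cohort (the default config), 30 benchmark mixtures for deconvolution, 1,000
replicates for type-I calibration, and exhaustive 70-assignment nulls for
the 4-vs-4 GSEA oracle — sizes at which every planted signal is clearly
resolvable while a full run stays in the seconds-to-minutes range on one
CPU. All stochastic stages take explicit seeds; permutation nulls switch
to exhaustive enumeration automatically when feasible.

## Known limitations

* The cosine purity calibration is taken as published; no re-derivation
  from copy-number data is attempted, and its transfer across platforms is
  flagged, not resolved.
* Cluster counts in the source cohort carry internal inconsistencies
  (cluster sizes that do not sum to the stated cohort size); nothing in
  this package depends on resolving them, and reproducing those external
  cohort-level counts requires the original downloads, which are out of
  scope.
* The responder model's clinical validity is not claimed; it is a
  reproduction of a modeling step, validated only on planted structure.
* ssGSEA scores here use the rank-weight running-sum form without a final
  cohort-wide rescaling; absolute score magnitudes are therefore not
  comparable across matrices with different gene counts.
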