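# Methods

This note documents the models and procedures implemented in
`ecprograms`, the conventions chosen where the methodology is genuinely
open, and what the synthetic benchmarks do and do not establish.

## Problem setting

Single-nucleus RNA-seq of tumor specimens captures endothelial cells
(ECs) whose transcriptional states mix continuously: a nucleus is better
described by a weighted combination of gene expression *programs* than by
a single discrete label. The pipeline discovers such programs by
consensus non-negative matrix factorization (cNMF), annotates them
against reference signatures, tests their association with treatment at
the patient level, characterizes them by mixed-effects differential
expression, and scores them in bulk cohorts for survival analysis. The
emulated cohort structure is 37 patients in three arms — untreated
(n = 18), chemoradiation (CRT, n = 14) and chemoradiation plus losartan
(CRTL, n = 5) — with treated patients stratified into low-dose
(31–39 GyE, n = 11; 7 photon / 4 proton) and high-dose photon
(55–59 GyE, n = 8) radiotherapy subgroups.

## Statistical primitives (`stats`)

All tests are implemented so that a brute-force oracle can verify them
exactly.

* **Two-sided hypergeometric overlap.** For gene sets A, B in a universe
  of size N, the p-value is `min(1, 2 * min(lower tail, upper tail))` of
  Hypergeom(N, |A|, |B|) at the observed overlap. Doubling the smaller
  tail is a deliberate convention: it is simple, conservative, and
  enumerable; the universe should be the set of genes that could have
  been tested (we default to the analyzed matrix's genes, not the
  genome, so that overlap probabilities condition on detectable genes).
* **Mann–Whitney U.** Midrank tie handling. Exact two-sided p by
  enumeration of all group labelings when the pooled sample size is
  ≤ 12 and the data are tie-free (the exact branch stays enumerable in
  tests); otherwise a normal approximation with tie-corrected variance
  and continuity correction. Complete ties return p = 1.
* **Wilcoxon signed-rank.** Zero differences are dropped (Wilcoxon's
  convention); all-zero input returns p = 1 with a degeneracy flag
  rather than an error. Exact sign-assignment enumeration for ≤ 12
  nonzero pairs, else normal approximation on the rank sum. The test
  requires explicit index pairing: when two groups are supplied without
  a stated pairing key (as in paired in-vitro panels where only group
  sizes are reported), the caller must make the pairing explicit.
* **Multiplicity.** Benjamini–Hochberg step-up (default FDR 0.1) and
  Bonferroni, implemented from their definitions and cross-checked
  against `statsmodels` in the tests. Every reported family of tests in
  the pipeline carries an adjustment; no raw-p-only outputs exist.

## Consensus NMF (`cnmf`)

**Preparation.** Counts are CP10K-normalized and log1p-transformed per
nucleus, restricted to the `n_hvg` highest-variance genes (default
1,500), scaled to unit variance per gene, and clipped at zero. The
normalization fed to NMF is a convention of this package; the retained
per-gene scale factors are kept so that rate-space profiles (e.g.
planted ground-truth spectra) can be mapped into the same feature space
for comparison.

**Replicates.** Frobenius NMF (`sklearn`, multiplicative updates) is
repeated `n_replicates` times (default 50; benchmarks use 15–20 for
desk-scale runtime) from random nonnegative initializations seeded
`base_seed + i`. The random usage matrix induces the initial spectra
through the data (`H0 ∝ W0ᵀM`), which makes each replicate exactly
equivariant under gene permutations. Spectra rows are L1-normalized with
the scale absorbed into usages. Replicates that stop at `max_iter` are
kept but flagged.

**Consensus.** All replicate spectra rows are pooled; rows whose mean
Euclidean distance to their `outlier_knn` nearest neighbors (default
30% of the pool) exceeds the `outlier_quantile` (default 0.9) threshold
are discarded; the survivors are k-means clustered (k-means++, fixed
seed) into k clusters summarized by the component-wise **median**
(robust to residual outliers), renormalized to the simplex. *Stability*
is the mean silhouette of that clustering (clusters that receive fewer
than two components are excluded with a warning). Usages are refit by
per-nucleus nonnegative least squares on the consensus spectra and row
normalized; the reconstruction error is the Frobenius error of the
unnormalized refit.

**Choosing k.** Stability and error are min–max normalized over the
grid and k maximizes `stability − λ·error` (λ = 1). The full
diagnostics table is always returned: the selection is a default, not a
verdict, and a user can legitimately override it for parsimony or
biological coherence.

**Annotation and assignment.** Each program is summarized by its 200
highest-weight genes (ties broken lexicographically) and tested against
reference signatures or GMT pathway collections with the hypergeometric
overlap test, BH-adjusted across the table. The state/lineage split of
programs is user-supplied annotation, not automatic. Per-nucleus labels
are the argmax of usage restricted to each program class, with ties
going to the lowest program index and flagged.

## Mixed-effects Poisson differential expression (`de`)

For each gene, nuclei assigned to a program are compared with all other
EC nuclei under

```
log E[y] = β₀ + β·group + covariates + b_patient + offset,   b ~ N(0, σ²)
```

with treatment arm, sex and three principal components (computed on the
EC-only normalized matrix, deterministic sign convention) as fixed
covariates and the log-normalized total UMI count — `log(total /
median total)` — as the offset. The model is fit by maximum likelihood
with a **Laplace approximation** for the one-dimensional random
intercept: fixed effects and intercept modes are maximized jointly by
penalized IRLS, and the variance is profiled by bounded scalar
optimization of the Laplace marginal likelihood. Laplace (rather than
adaptive quadrature) is accurate for random intercepts and testable
against the σ = 0 GLM limit, which the tests verify against
`statsmodels` to machine precision when the variance is pinned.
Inference on β is Wald; p-values are Bonferroni-adjusted across tested
genes (matching the beta/SE reporting style). Genes expressed in fewer
than 1% of nuclei are skipped (degenerate fits); genes that fail to
converge or show separation are kept with an infinite-SE sentinel and a
flag rather than dropped.

## Patient-level associations (`associations`)

Per-patient program proportions (fractions of EC nuclei per program,
simplex within the lineage class and within the state class) are
compared between strata — arms, dose groups, modalities — with
two-sided Mann–Whitney U tests, BH-corrected per stratification family
(FDR 0.1). Quartile analyses rank patients by their mean usage weight of
a program (the patient-level "program expression"; the aggregation
convention is this package's choice) with ties broken by patient ID, cut
floor(n/4) patients per tail, compare responses by Mann–Whitney U, and
report the ratio of means as fold change (an infinite sentinel marks a
zero bottom-quartile mean). Fold changes are ratios of means; medians
are not used. Stromal-to-EC ratios divide per-patient stromal cell-type
counts by EC counts (patients without ECs are excluded with a warning).
A leave-patients-out harness reruns any association analysis with a
chosen patient subset removed, mirroring influential-patient
sensitivity checks. Targeted-panel scores are means over the panel genes
overlapping each program's top-200 list, compared between paired
conditions by Wilcoxon signed-rank with Bonferroni correction.

## Bulk analysis (`bulk`)

**Deconvolution.** No specific algorithm is dictated by the problem, so
the default is deliberately the simplest oracle-checkable choice:
per-type scores are marker-gene means of log1p expression, z-scored per
type across samples, min-shifted to nonnegative, and normalized to the
simplex per sample. When type proportions are exchangeable and marker
response is near-linear, the min-shifted z-scores are approximately
proportional to the true fractions (the synthetic benchmark operates in
this regime and achieves mean absolute error ≈ 0.01 at 200 samples).
With strongly saturating marker response the estimates remain monotone
per type but the simplex renormalization distorts absolute levels — a
known limitation. An NNLS-on-signature-matrix variant is available
behind `method="nnls"`. The shipped marker table stores the symbol
"CSM1" verbatim from its source with a validation warning, as it is not
a standard HGNC symbol.

**Program scoring.** Bulk program score = sum of expression over the
program's top-200 genes present in the matrix (≥ 10 required),
z-normalized within each cohort independently to absorb batch effects.
This treats total bulk expression of the program genes as a proxy for
the endothelial-compartment signal; the EC-attributed component is not
separable without a reference profile, so non-endothelial cells
expressing program genes can confound bulk scores — a documented
approximation.

**Survival.** Multivariable Cox regression (lifelines; Efron tie
handling, Wald confidence intervals) on age, sex, grade, stage (ordinal
integers) and the program z-scores, run separately for lineage and state
program sets and for each endpoint (overall survival, time to
progression). Metastatic samples are excluded by a clinical flag.
Guards: ≥ 10 events (configurable for worked examples) and no constant
covariates. Nodal status is compared with per-program Mann–Whitney U
tests, BH across programs.

## Synthetic data (`simulate`)

The generators are pure functions of their configuration (which carries
the seed); identical configurations give byte-identical outputs.

* **Single-nucleus counts.** Counts are
  `Poisson(L_c · exp(b_patient) · usage_c @ spectra)` with lognormal
  library sizes (median ≈ 1,500 UMIs over 1,500 genes), Gaussian patient
  effects (SD 0.3) supplying extra-Poisson variation while keeping the
  Poisson GLMM well-posed, and planted spectra = gamma background plus
  30 exclusive high-weight marker genes per program (plus shared EC
  identity genes). Usages follow an arm-dependent Dirichlet mixture: a
  nucleus draws its dominant program from the arm's prevalence vector,
  then its usage row from `Dirichlet(0.25 + 6·onehot)`, so the argmax
  label almost always equals the drawn program. Default prevalences
  up-weight the reactive program (0.10 → 0.35) and deplete the
  capillary-like program under treatment, with an additional
  lymphatic-like depletion under losartan. Dose/modality subgroups are
  assigned deterministically in roster order so stratified analyses are
  reproducible. Negative-binomial overdispersion, ambient RNA, doublets
  and batch effects are deliberately not modeled.
* **Bulk cohorts.** Expression is a linear mixture of 10 cell-type
  profiles with exclusive markers (moderate magnitude, keeping
  marker-mean deconvolution near-linear), plus an endothelial program
  component proportional to the sample's endothelial fraction and
  per-program activity. Survival times are exponential with hazard
  `h₀·exp(Σ β_p z_p)` on the within-cohort z-scores of the true program
  signal (default β = log 2 on the lymphatic-like program), with
  independent exponential censoring (~20%). Nodal-positive samples
  receive a +0.5 SD shift of the lymphatic-like signal. Two cohort
  labels exercise within-cohort z-normalization.
* **Paired panel.** Gene expression = baseline + pair-level random
  intercept + condition effect on designated signature genes + Gaussian
  noise, for 24 control/irradiated pairs.

Because usages, spectra and survival parameters are planted, every
downstream claim in the test suite is a *recovery* statement against
known truth. Passing these benchmarks shows the algorithms are correct
and calibrated under their own generative assumptions; it does not show
robustness to the overdispersion, contamination and annotation noise of
real tissue data.

## Benchmark problem sizes and numerical choices

The acceptance-scale benchmarks use ~3,000 nuclei × 1,500 genes with 20
NMF replicates over k = 4..10 and five simulation seeds; association
power uses 100 simulated cohorts with per-nucleus truth-derived labels;
the GLMM benchmarks use 40 patients × 200 nuclei with 50 planted and
500 null gene fits; bulk benchmarks use 200–300 samples. These sizes
were chosen to make the recovery targets statistically sharp on a single
desktop core. Numerical conventions: NMF multiplicative updates with
tolerance 5e-4 and max 200 iterations on float32 data; k-means with 10
restarts and a fixed seed; NNLS refits through the Cholesky factor of
the spectra Gram matrix; IRLS tolerance 1e-8 with the random-intercept
variance profiled on a log scale in [1e-8, 25]; linear predictors
clipped at ±30 to prevent overflow (separation then surfaces as a
flagged fit, not an exception).
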