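# Methods

## Model and estimation

The package models 15 regional imaging indicators (five bilateral regions ×
three modalities) and four episodic-memory scores with a
multitrait–multimethod confirmatory factor structure. Traits are regional
integrity factors — hippocampus, parahippocampal gyrus, precuneus, and one
merged prefrontal factor carrying the six medio-orbitofrontal and
dorsolateral indicators (the two frontal regions share too much variance to
sustain separate factors; the unmerged variant is constructible through the
spec API and demonstrates the failure as an inadmissible correlation).
Method factors for VBM, MT and MD are orthogonal to the traits, correlated
among themselves, and loaded by every indicator of their modality. Residual
covariances are free for the VBM pairs of neighbouring regions
(medio-orbitofrontal–dorsolateral; hippocampus–parahippocampal).
Identification fixes one loading per factor to 1: the VBM indicator for
traits (medio-orbitofrontal for the merged prefrontal factor — either
frontal VBM indicator is statistically equivalent), the precuneus indicator
for methods, and the verbal-learning score for the memory factor (any task
would do).

Models compile to RAM matrices: directed coefficients `A`, symmetric
(co)variances `S`, means `M`, observed-variable filter `F`, with
`Sigma = F (I-A)^{-1} S (I-A)^{-T} F'`. The mean structure is saturated in
every model (one free mean per observed variable), so model degrees of
freedom count covariance moments only: `p(p+1)/2` minus unique free
covariance-structure parameters. This convention reproduces the dfs of all
four published model variants (64, 73, 120, 123). In multigroup models the
general count (covariance + mean moments minus all free parameters,
including means) is used; it reduces to the same convention when means are
saturated per group.

The likelihood is full-information ML over missingness patterns. Rows are
grouped by observed-column mask; each pattern contributes
`-n/2 [k ln 2π + ln|Σ_o| + tr(Σ_o⁻¹ C) + d'Σ_o⁻¹ d]` via its sufficient
statistics (count, mean, ML scatter). A brute-force row-by-row density sum
serves as the test oracle for this grouping. Optimization is L-BFGS-B with
an analytic gradient assembled from per-pattern weight matrices lifted to
the full RAM space; the gradient is verified against central finite
differences in a property test. An analytic gradient was chosen over pure
numerical differencing because the inference simulations need on the order
of a thousand fits and the equivalence checks need log-likelihood agreement
at 1e-6, which finite-difference noise does not reliably deliver. After the
first convergence the optimizer is restarted up to three times (restarting
resets the curvature approximation and reliably gains the last ~1e-7 of
log-likelihood). Convergence requires the optimizer's relative-reduction
criterion or a gradient max-norm below 1e-4; non-convergence is reported in
the result, never raised during estimation.

`chi2 = 2(l_saturated − l_model)`. The saturated model (free means,
unrestricted covariance) is fitted by EM for incomplete multivariate-normal
data; a direct-optimization route (Cholesky-parameterized covariance)
exists solely as a cross-check and is tested to agree to 1e-6. The baseline
model (free means and variances, zero covariances) has a closed form per
column. CFI uses `1 − max(χ²_m−df_m,0)/max(χ²_b−df_b, χ²_m−df_m, 0)`; RMSEA
uses `sqrt(max(χ²_m−df_m,0)/(df_m·n))` with denominator `n` (flag
`rmsea_denominator="n-1"` switches); SRMR is the RMS of standardized
residual covariance moments, lower triangle including the diagonal, mean
residuals excluded by default since means are saturated. Standard errors
invert the observed information (central differences of the analytic
gradient); Wald tests are two-sided normal; no multiple-testing correction
is applied anywhere. Negative free variances — observed residuals or
latent factors — are flagged as Heywood conditions; `heywood_refit=True`
refits with flagged *residuals* fixed to zero (the published remedy), while
latent-variance flags are reported only, and standardization returns NaN
for entries involving a negative implied variance rather than failing.

The MD medio-orbitofrontal residual deserves a note: the original analysis
estimated it slightly negative and fixed it to zero in all subsequent
models. That constraint is part of the published specifications (and of the
df arithmetic 73/120/123), so the builders default to it; against the
synthetic generator, whose residual there is a regular positive value, the
constraint is a misspecification, and recovery-oriented analyses should
pass `fix_md_mofc_residual=False`.

## Synthetic generator

The generator is multivariate normal — the FIML likelihood assumes
normality and the published skewness/kurtosis are near-normal, so nothing
beyond normality is emulated. Defaults encode the study conditions: 1522
participants, 333 with the MR block; trait-factor correlations from the
published factor table (e.g. r(HC,PHG)=0.84), method-factor correlations
(0.25, −0.53, −0.77); memory–trait correlations 0.24/0.33/0.27/0.16 and
zero memory–method correlations; standardized covariate effects from the
published covariate table (age→HC −0.28, education→EM 0.29, per-unit female
advantages 0.31–0.69), plus the age–method associations (−0.16, −0.29,
0.40). Standardized loadings are regular values inside the published ranges
(traits 0.30–0.75 absolute, methods 0.35–0.55, memory 0.46–0.56); MD
indicators load negatively (higher integrity ⇒ lower diffusivity). Exact
loading values are configuration defaults, not claims about the study.
Residual variances close each indicator's variance to the analysis scale
(mean 5, SD 2); the two neighbouring-VBM residual correlations default to
0.30 and 0.25.

Covariates enter the latent layer centered, and the latent residual
covariance is set to (total factor correlation − covariate-induced part),
so the configured factor correlations are *total* correlations and the
measurement and age-covariance models' orthogonality assumptions hold
exactly in the population. One consequence: the covariate-adjusted model
fixes *residual* trait–method covariances to zero, which under this
calibration is mildly misspecified (shared covariate effects induce
nonzero residual trait–method covariance), so its standardized covariate
paths carry a small systematic offset relative to the generating effects;
the age-covariance parameterization is exact and recovers them cleanly. The
implied memory R² on the four trait factors is then c'Φ⁻¹c ≈ 0.136,
consistent with the published 12.5% given that the printed correlations are
rounded.

Missingness: exactly `n_total − n_mr` rows lose the whole MR block, chosen
without replacement with sex-dependent weights calibrated so the MR
subsample is ~38% female against ~51% overall — this realizes the observed
selectivity while remaining missing-at-random (selection depends only on
observed sex). Within MR rows the VBM/MT/MD blocks are masked independently
with observation probabilities 330/333, 197/333, 274/333; memory scores are
masked per column at 1500/1522. Covariates are generated complete (the
published per-variable Ns vary; modelling that adds nothing to the design
the pipeline exercises). An affine raw-scale emitter maps columns onto the
published means/SDs and can mix in an intracranial-volume component
(default 9% of raw VBM variance, ICV ~ N(1450, 150²) ml) for exercising the
ANCOVA adjustment.

What passing tests on this generator do *not* show: robustness to
non-normal indicators, to missingness that depends on unobserved values, to
the measurement heterogeneity of real scanners, or to the true
(unpublished, unrounded) parameter values.

## Preparation operators

MTR = (noMT − MT)/noMT with an explicit zero-denominator error. ICV
adjustment subtracts the reference-sample OLS slope times (ICV − reference
mean), making adjusted volumes exactly orthogonal to ICV on the reference
sample. Outlier screening runs on complete cases of an explicit column
list, compares squared robust Mahalanobis distances to the χ²(k) quantile
at 1 − 1e-4, and uses scikit-learn's minimum-covariance-determinant
estimator with a fixed random state — the original analysis used a
minimum-volume-ellipsoid fit, but the two agree in the gross-outlier regime
screened here, and MCD is the maintained, deterministic choice. Note the
χ² calibration of MCD distances is anti-conservative when the complete-case
count is small relative to the dimension (~5× columns); the pipeline's
default sizes stay clear of that regime. Rescaling is a per-column affine
map to mean 5 / SD 2 (sample SD, ddof = 1) over non-missing cells —
idempotent, correlation-preserving, χ²-invariant. Selectivity is
(mean_total − mean_sub)/SD_total; skewness is moment-based and kurtosis is
plain (normal ≈ 3), matching descriptive-table conventions. The pipeline
screens the memory block and the full modelled MR block (the original
screened "12 MR variables" without naming them; the operator takes any
column list), excludes flagged rows, rescales, fits the requested models,
and writes study-style tables plus a JSON manifest (seed, versions,
exclusion accounting).

## Numerical choices and limitations

Starting values: free means at observed column means, observed variances at
half the column variance, latent variances at half the mean observed
variance, loadings at ±1 with MD sign hints, covariances and regressions at
0. L-BFGS-B runs with ftol 1e-15, gtol 1e-8, up to 10 000 iterations.
EM for the saturated model iterates to relative log-likelihood change
1e-10 (cap 5000 iterations). Ties in the age median split go to the lower
group. The invariance ladder follows the standard sequence — configural,
metric (loadings equated), scalar (intercepts equated, latent means freed
in non-reference groups); the exact parameterization of the original
supplementary multigroup analysis is not published, so this standard
sequence is the package's choice.

Problem sizes in the test suite and acceptance script (5000 for recovery,
20 000 for fit-index and association checks, 300–500 replicates at n = 300
for calibration) were chosen to keep Monte-Carlo error well inside the
assertion tolerances on a single CPU. Not implemented: robust/categorical
estimators, bootstrap standard errors, Bayesian estimation, modification
indices, exploratory factor analysis, longitudinal or non-normal
generation, and any voxel-level image processing — inputs are ROI-level
tables by design.
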