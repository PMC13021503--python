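# Methods

## The model

Each zygosity group contributes an iid sample of stacked pair vectors
(twin 1's k traits followed by twin 2's). Under the classical twin model
the pair covariance is

    Sigma_z = | P    R_z |        P   = A + C + E
              | R_z  P   |        R_MZ = A + C,   R_DZ = 0.5 A + C

with A, C, E the additive-genetic, shared-environmental and
unique-environmental component covariances. The mean model is one grand
mean per trait, shared across twins and zygosity groups: the pipeline fits
age-residualized traits whose means are ~0, and nothing in the published
material this package emulates specifies a richer means structure. The
-2 log-likelihood is the usual two-group multivariate-normal expression;
for complete pairs it depends on the data only through each group's size,
mean vector and (MLE-denominator) covariance, which is what makes the
profile-CI and replicate studies cheap. Incomplete pairs can be included
through a full-information path that groups pairs by missingness pattern
and marginalizes the unobserved coordinates; the default is complete-pairs
analysis, and the saturated model (free means and unstructured covariance
per group, closed form at the sample moments) is defined for complete
pairs only.

Parameterizations:

- univariate: component variances (va, vc, ve) >= 0 with ve floored at a
  tiny positive value — the unique environment absorbs measurement error
  and must stay positive; standardized shares are a2 = va/(va+vc+ve) etc.
  Non-negative variances are equivalent to non-negative path coefficients
  (a = sqrt(va)).
- multivariate: A = X Xᵀ, C = Y Yᵀ, E = Z Zᵀ with lower-triangular factors,
  diagonals constrained non-negative (E's strictly positive). The
  factorization is a parameterization, not a causal ordering; implied
  components and every correlation derived from them are invariant to trait
  order (tested to 1e-4), so bivariate fits order traits alphabetically.

Traits are internally centred and scaled to unit pooled SD before
optimization and results are mapped back; reported -2lnL values include
the Jacobian constant so saturated and structured fits are comparable on
the original scale. Standardized components are invariant to affine
rescaling of the data (contract: 1e-8; see Numerical choices).

## Estimation and inference

Fits use L-BFGS-B from a moment-estimator start (double-entered co-twin
moment blocks give A0 = 2(M - D), C0 = 2D - M, E0 = P - M, PSD-projected)
plus jittered restarts (five for univariate, three for Cholesky fits,
seeded). The univariate complete-pairs path supplies exact analytic
gradients and finishes with a few damped Newton steps, pinning the optimum
far below reporting precision. Convergence is flagged from the optimizer
status and the projected gradient.

Model comparison is by likelihood-ratio test, chi2 = Delta(-2lnL) with
df = Delta(number of parameters) against the plain chi-square reference;
for one-df boundary tests (AE vs ACE) the 50:50 chi2(0)/chi2(1) mixture
p-value is reported alongside, since the plain reference is conservative
at a variance boundary.

95% CIs are profile-likelihood intervals: the set of component values whose
profiled -2lnL lies within chi2(1, 0.95) = 3.84 of the minimum. Profiling a
standardized share t fixes, e.g., va = t/(1-t) (vc + ve) and re-optimizes
everything else; profiling a bivariate component correlation fixes the
correlation and re-optimizes the two component SDs and all other
parameters. Bounds stuck at the parameter boundary are reported as exactly
0, 1 (or +-1 for correlations) with a boundary flag. If the profile fails
to bracket, a 1000-replicate parametric-bootstrap percentile interval is
used and the fallback is logged. Empirical coverage of the a2 profile CI
at the emulated study's intake-male size (252 MZ + 124 DZ pairs, generating
a2 = 0.78) is ~95% (recomputed by `scripts/acceptance.py`).

Co-twin correlations are computed by double entry (each pair contributes
both orderings), removing the arbitrary twin labelling, with Fisher-z CIs
on the number of pairs (not the doubled count). The closed-form moment
estimator a2 = 2(r_MZ - r_DZ), c2 = 2 r_DZ - r_MZ serves as an independent
oracle: on data whose group moments exactly equal the implied moments the
ML fit must agree with it (tested to 1e-3; they differ at O(n^-1/2)
otherwise because ML pools variances across groups while the moment
estimator standardizes per group).

The pairwise correlation pipeline fits the AE model first and confirms with
ACE, reporting both r_A values and their difference: when the true c2 is
small, r_C is essentially unidentified at twin-study sample sizes — its
profile CI typically spans [-0.9, 0.9] or wider (recomputed by the
acceptance script) — while r_A barely moves between the two models.

## The simulator

`simulate_cohort` draws each pair's stacked trait vector from a zero-mean
multivariate normal with the implied pair covariance, then adds per-sex
intercepts and linear age effects, and finally exponentiates designated
log-normal (adiposity-type) traits — so the modelled (log) scale carries
the normal structure the likelihood assumes, making recovery tests exact in
expectation. Ages are drawn uniformly within each wave's printed per-sex
range (only means and ranges are published). Multi-wave designs draw one
latent vector per family across all (trait, wave) combinations, so
longitudinal genetic correlations come from the same machinery
(`trait_waves` on the truth); a truth without wave tags redraws waves
independently. Missingness is off by default; an optional
missing-completely-at-random rate exercises incomplete-pair handling.
Identical seed, design and truth give a byte-identical CSV.

What the simulator does **not** emulate: non-normal residual structure,
assortative mating, gene-environment correlation or interaction,
sex-limitation of genetic effects (sexes differ only in means/slopes and
in which preset truth is used), selective attrition (follow-up families
are a nested subset per cell), and measurement-protocol artifacts. Passing
recovery tests therefore demonstrates correctness of the estimators under
the model's own assumptions, not robustness to their violation in real
anthropometric data.

### Presets

The emulated study's printed tables ship as presets: per-trait descriptive
statistics (mean, SD), standardized a2/c2/e2 per sex and wave, and
cross-wave phenotypic/genetic/environmental correlations. Univariate
truths use unit phenotypic variance (all reported quantities are
standardized; a `scaled` option restores the printed mean/SD).
Cross-wave truths stack one trait at two waves: per-wave shares from the
univariate table, r_A and r_E from the cross-wave table, and r_C solved
from the phenotypic identity
r_P = sqrt(a2 a2') r_A + sqrt(c2 c2') r_C + sqrt(e2 e2') r_E so that the
implied trait correlation matches the printed one (clipped to [-1, 1];
set to 0 when either c2 is 0). Age slopes are not published, so preset
truths default to zero slopes — the generating SD then equals the printed
SD, which is what the descriptive-recovery checks assume; users can supply
realistic growth slopes per sex when age structure matters.

## Factor analysis

`principal_factor` is iterated principal-axis factoring: communalities
start at squared multiple correlations, the reduced correlation matrix is
eigendecomposed, loadings come from the top eigenpairs (eigenvalues
clipped at 0), and the cycle repeats until communalities change by < 1e-6
(max 200 iterations). Heywood cases clip the offending communality at 1
and flag the solution. `varimax` is the orthogonal Kaiser-normalized
rotation (SVD-based iteration on row-normalized loadings), which leaves
communalities and the reproduced correlation matrix unchanged; it matches
R's `stats::varimax` on block-structured examples and attains at least the
criterion of statsmodels' GPA rotation, which can stall on such examples.
Columns are signed so the largest-magnitude loading is positive and
ordered by explained sum of squares. The default of three factors follows
the linear / volume / craniofacial structure typical of adolescent
anthropometric batteries; an eigenvalue rule is deliberately not the
default because retention rules are study-specific. The correlation matrix
is computed on individual-level rows, so twin clustering inflates the
effective n: loadings are unbiased but their sampling error is understated.

## Numerical choices

- Natural log for the log transform; the base cancels in correlations and
  standardized components. BMI is computed from raw weight/height first and
  then logged (BMI is itself a log-listed trait).
- Residualization is OLS on intercept + exact age within each (sex, wave)
  stratum, complete cases per trait; strata under 3 rows error out.
  Residuals are not re-standardized — components are standardized at the
  modelling stage. Residualization is idempotent (1e-10).
- Optimizer tolerances: ftol 1e-15 / gtol 1e-9 (univariate, analytic
  gradient, Newton polish to |g| ~1e-10) and ftol 1e-13 (Cholesky, numeric
  gradient). The scale-invariance contract (identical standardized
  components to 1e-8 under data rescaling) is met by the polished
  univariate path.
- Profile root-finding uses Brent's method between the estimate and the
  boundary, warm-started from the full fit; component shares are capped at
  1 - 1e-6 during profiling because the e2 floor forbids exactly 1.
- Degenerate inputs: non-PSD component matrices are rejected at
  construction; exactly collinear trait pairs are rejected as
  ill-conditioned before fitting (an exactly singular phenotypic
  covariance has no finite-likelihood fit); zero-variance components make
  the corresponding correlation undefined (flagged, never fabricated);
  |r| at 1 is capped and boundary-flagged.
- Pipeline outputs pin CSV floats to 6 significant digits for byte-stable
  reruns, with a full-precision JSON sidecar; every configured stratum
  appears in the manifest as done or failed, and per-pair fit failures
  never abort the rest of a correlation matrix.

## Problem sizes used by the shipped checks

Recovery runs use 5,000 pairs per zygosity per cohort, averaging the
estimator over 5 (univariate) or 3 (cross-wave) independent replicate
cohorts: the averaged estimate isolates estimator accuracy (MC standard
error ~0.008) from single-draw noise (~0.018 at that n). Coverage uses 500
replicates at the emulated intake-male size; factor-structure recovery
uses 100 replicate cohorts at that size with planted within-block
component correlations of 0.8 against 0.2 between blocks; the
consistency grid uses 20,000 pairs per zygosity.

## Known limitations

- No dominance (ADE), sex-limitation, independent/common-pathway, simplex
  or direction-of-causation models; no ordinal/threshold traits.
- The full k-trait joint Cholesky is supported but the pipeline default is
  pairwise bivariate fits: study-scale data cannot identify a 20x20 joint
  model, and the published matrices this package emulates are pairwise.
- FIML covers structured models only; the saturated reference (and hence
  LRTs against it) requires complete pairs.
- Bootstrap CIs resample from the fitted model (parametric); no
  nonparametric pair resampling.
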