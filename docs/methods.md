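# Methods

## Indices

All indices are computed from measured height, weight, waist and hip
circumference. Cohort files carry cm/kg; ABSI and BRI convert to meters
internally, matching each formula's conventional units, while WHtR and
WHR are unit-free ratios computed in cm.

* BMI = weight / height² (kg/m²).
* WHtR = WC / height; WHR = WC / hip.
* ABSI = WC / (BMI^(2/3) · √height) with WC and height in meters — an
  allometric standardization of waist for overall size; pediatric values
  sit around 0.07–0.09, so determinant-model coefficients are also
  reported on a ×10³ display scale.
* BRI = 364.2 − 365.5·√(1 − ((WC/2π) / (0.5·height))²). The argument of
  the root is the squared complement of the eccentricity of an ellipse
  with minor radius WC/2π and major radius height/2. The index is
  bounded: −1.3 in the thin-body limit, 364.2 when WC = π·height
  (eccentricity zero). WC > π·height is geometrically impossible and is
  rejected as an implausible measurement rather than clipped. Circulating
  renderings of this formula are frequently garbled by typesetting; the
  implementation uses the canonical closed form above, which reproduces
  the expected pediatric range (roughly 1–4) where literal readings of
  corrupted variants do not.

## Weight status

Classification is against an *external* sex × age BMI percentile table
(columns sex, age_lo, age_hi, p5, p85, p95; half-open 1-year age bins by
default). Bands are lower-inclusive, upper-exclusive: wasting < P5 ≤
normal < P85 ≤ overweight < P95 ≤ obesity. National references differ by
country and era, so the table is an input, not a constant; no LMS
smoothing is applied — references are consumed, not fitted.

## CMRI standardization

CMRI z = z(WC) + z(SBP) + z(DBP) + z(GLU) + z(TG) − z(HDL-C). Component
means and SDs are estimated per (sex, age cell) on the **reference
population**: subjects with BMI in [P5, P95), i.e. the normal-weight and
overweight classes. Choices that the composite's affine invariance does
not fix, and their defaults:

* age cells: 1-year bins (configurable width). Cells below `min_cell_n`
  (default 10) are pooled left-to-right with the adjacent bin, with a
  warning, to avoid unstable SDs; a zero-variance cell is an error.
* SDs use the n−1 (sample) denominator.
* WC is standardized in cm; any affine rescaling is absorbed by the
  z-score.
* missing components: complete-case exclusion with a logged count.
* high risk: CMRI z ≥ 1 (inclusive) — one reference SD above the mean.
* the `wc_omitted` variant removes z(WC) from the sum (the waist z is
  still reported), for analyses where waist also enters the exposure
  index under study.

Within the reference population the per-cell z-scores have mean 0 and
SD 1 to numerical precision; this is asserted in the test suite.

## Quantile regression and reference tables

Determinant models regress BRI or ABSI on a pubertal indicator
(reference: prepubertal) and weight-status indicators (reference:
wasting), per sex, at τ ∈ {0.05, 0.25, 0.50, 0.75, 0.95}. Coefficients
minimize the check loss ρ_τ(u) = u·(τ − 1{u<0}) via statsmodels'
iteratively reweighted least-squares solver (iteration cap 10,000,
coefficient tolerance 1e-8; for discrete data the minimizer need not be
unique and the solver's converged point is reported). 95% CIs use a
seeded nonparametric bootstrap (percentile method, B = 1000 by default;
B = 0 skips CIs); significance is read strictly from whether the CI
excludes zero. A rank-deficient design — e.g. an absent weight-status
level — raises an error naming the degenerate column rather than
silently dropping it. The test suite validates the fitter against an
exhaustive grid search of the pinball loss on small instances.

Percentile reference tables are built on **normal-weight subjects
only** — BRI stratified by sex × pubertal group, ABSI by sex — as
empirical quantiles with linear interpolation between order statistics
(numpy's default, the "type 7" rule; no rule is canonical, this one is
stated). The published-style tables print P5–P95; P85 is computed with
the same machinery and stored alongside because the screening module
uses it as a cutoff level. Whether such tables should instead be
evaluated from the fitted quantile-regression models is genuinely open;
the empirical stratified computation is the primary path here because it
is reproducible and matches the printed table structure, and a
model-based evaluation can be composed from `fit_determinant_models` if
wanted. Non-crossing of the percentile levels is asserted.

## Quartile logistic association

Within-sex quartiles use type-7 cutpoints with lower-inclusive bands
(value = P25 → Q2, value = P75 → Q4). Q2 is the reference group — Q1
mixes in underweight children and is a poor "low-risk" baseline. The
logistic model is maximum-likelihood with Q1/Q3/Q4 indicators plus age
(linear in years; no spline, as no functional form is established) and a
pubertal indicator; models are fitted per sex, which together with the
pubertal covariate realizes "adjusted for sex and pubertal stage".
Wald 95% CIs and p-values are reported (the standard reporting style for
ORs); weight status is deliberately not in the adjustment set. Complete
or quasi-complete separation is detected (fitted probabilities pinned at
0/1 or |β| > 15) and flagged with an infinite/zero OR sentinel and a
warning; `ridge > 0` requests an L2-stabilized refit instead.

## Screening

Each screen classifies positive when index ≥ cutoff (inclusive, matching
"≥ P75th"-style rules). BRI cutoffs are stratum-specific (sex × pubertal
group, from the normal-weight reference tables); WHtR/WHR/BMI cutoffs
are within-sex empirical percentiles of the analysis cohort. For a
single-cutoff test the ROC polygon has one interior vertex, giving the
exact identities J = se + sp − 1 and AUC = (se + sp)/2, which hold for
every emitted row by construction and are asserted. AUC CIs use the
Hanley–McNeil closed-form SE (deterministic; DeLong adds nothing for a
binary predictor), truncated to [0, 1]; the p-value is the two-sided
normal test of AUC = 0.5 with the same SE, displayed as "<0.01" below
that floor. Continuous-threshold ROC optimization is out of scope: the
design question is how fixed percentile cutoffs perform.

## Synthetic cohort generator

The generator emulates a school-based cross-sectional survey: ~55/45
boys/girls; ages uniform on [6, 18) truncated to 0.1-year resolution (a
neutral choice — only coarse age bands are ever reported for such
surveys); pubertal probability expit(slope·(age − midpoint)) with
midpoints 9.0 y (girls) and 10.3 y (boys) and slope 1.2/y, giving
age-integrated pubertal fractions ≈ 0.75 and 0.64; Tanner stage uniform
on {2..5} within pubertal subjects (downstream models use only the
binary/3-level groupings); weight-status mix 4% wasting / 72.5% normal /
11.5% overweight / 12% obesity.

Design choices worth knowing:

* **Exactly consistent references.** A latent N(0,1) adiposity score is
  mapped through a piecewise-linear percentile distortion so the target
  class masses land on the P5/P85/P95 bands of the parametric BMI
  baseline (normal, piecewise-constant mean/SD over 1-year bins).
  `derive_bmi_reference` exports exactly that baseline's percentiles, so
  classifying a generated cohort reproduces the drawn classes exactly
  and class frequencies are binomially distributed around their targets.
* **Homoscedastic waist model.** Waist is modelled on the WHtR scale:
  base ratio 0.405 + 0.013·(BMI − age-bin median) − 0.012·pubertal +
  0.004·male + N(0, 0.022). Because BRI is a monotone function of WHtR
  alone, configured effects act as clean location shifts at every
  quantile and a zero coefficient means a truly null effect — cm-scale
  residuals would leak stature into the BRI noise scale.
* **Exact ground-truth shifts.** `effect_overrides` impose additive
  shifts on the BRI scale by inverting the index to a new waist
  circumference, so recovery tests compare against an exact truth.
* **Biomarkers.** Linear in the standardized WHtR deviation ("wc z"),
  with Gaussian noise on the natural scale (log scale for TG, which is
  right-skewed in practice; this also keeps values positive without
  rejection sampling) and physiologic floors; DBP is capped 2 mmHg below
  SBP. The HDL slope is constrained negative. Slopes (SBP 3.0, DBP 1.8,
  GLU 0.065, log-TG 0.10, HDL −0.05 per wc-z unit) were calibrated once
  so that ≈40% of a default cohort reaches CMRI z ≥ 1 with a steep
  monotone gradient across weight-status classes (≈3% of wasting to
  ≈85% of obese subjects in a default run), the regime the analysis
  modules assume.
* A single RNG stream ordered by subject index makes output bitwise
  reproducible for identical (config, seed); reproducibility across
  different n is not promised.

What the generator does **not** emulate: real growth curves or national
BMI standards, longitudinal trajectories, measurement error, the true
covariance structure among biomarkers beyond the single shared adiposity
driver (stratum-level biomarker means/SDs are not published, so defaults
are calibrated only to coarse marginals), or ethnic/secular variation.
Passing tests therefore demonstrate the *statistical machinery* —
standardization exactness, estimator consistency, recovery of known
effects, metric identities — not that any particular published
population value generalizes.

## Problem sizes

Shared test cohorts use n = 4,000 (seeded); recovery checks use
n = 5,000 with B = 200 bootstrap replicates; null-coverage checks use
n = 20,000 logistic fits and 10 replicate simulations of n = 500 for
quantile CI coverage. These sizes put Monte-Carlo error well inside the
asserted tolerances while keeping the whole suite fast on one CPU.

## Known limitations

* Bootstrap percentile CIs are first-order; rank-inversion CIs for
  quantile regression are not implemented.
* Hanley–McNeil assumes the binormal-ish variance approximation; for
  very small strata an exact method would be preferable.
* The screening module evaluates fixed percentile cutoffs only.
* Separation handling flags rather than penalizes by default; the ridge
  refit trades bias for stability and is opt-in.
* Age enters the logistic models linearly; strongly non-linear age
  effects would call for splines.
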