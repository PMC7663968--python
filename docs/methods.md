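# Methods

This note records the statistical procedures, the synthetic-data
generator's design, and the numerical choices behind `ecofit`, in the
spirit of a model-documentation page: everything here is computed by the
package's code and exercised by its tests; no empirical claim is made that
the tests or `scripts/acceptance.py` do not themselves reproduce.

## 1. Morphometrics

Five linear measurements (wing, tarsus, culmen, bill width and depth at
the nares; mm) and mass (g) are taken per individual; juveniles are
excluded from every analysis. Three ratios summarise shape:

* tarsus-to-wing = tarsus / wing (dimensionless),
* horizontal bill aspect = culmen / bill width (dimensionless),
* bill slenderness = culmen / bill cross-sectional area (1/mm).

The bill cross-section is approximated as an ellipse,
A = π · (width/2) · (depth/2). A rectangular width × depth alternative is
selectable (`area_formula="rectangle"`); only the ordering of species
along the slenderness axis matters for the models' signs, and the two
formulas are proportional, so the choice rescales coefficients without
changing conclusions. Ratios are computed **per individual and then
averaged** within species × site (mean of ratios, not ratio of means);
a regression test pins this order.

The morphospace is a PCA over individuals on the raw measurements:
centered, **not** variance-standardized by default (a config flag enables
correlation-matrix PCA; this changes centroid distances and is therefore
surfaced prominently). Mass is excluded from the PCA by default — it is
modelled as its own predictor — and can be appended by flag. All
components are retained, so the PCA is a pure rotation and centroid
distances equal distances on the centered raw data (tested identity).
Species-centroid Euclidean distances are computed within each site by
default; a pooled-across-sites grouping is available, since per-site and
pooled centroids answer slightly different questions.

## 2. Foraging variables

Observed heights are divided by the mean canopy height of the observation
point; values above 1 are legitimate (emergent trees). Behavior frequency
distributions per species × site are normalised by **total flag
occurrences**: events can carry several simultaneous behavior flags, and
occurrence normalisation is the convention that always yields a proper
probability distribution for the PS index. A per-event normalisation
(rows may exceed 1) is available for sensitivity analysis but never feeds
PS. Flock observations count once, not once per bird, because heights and
behaviors are recorded per observation event. Species × site groups with
zero foraging events have no defined distribution and are excluded from
PS with a warning rather than imputed.

## 3. Proportional similarity

PS(p, q) = Σ min(pᵢ, qᵢ) over an identical ordered category set.
Percent-scaled profiles (summing to 100, the EltonTraits convention) are
detected and rescaled; after conversion, profiles must sum to 1 within
1e−6 (integer-percent rounding is tolerated and renormalised away so the
L1 identity holds exactly). Category mismatches are hard errors naming
the offending labels. The identity PS = 1 − ½‖p − q‖₁ and the
monotonicity of PS under mixing are both tested.

## 4. Incumbent communities and establishment features

For each non-native introduction, the incumbent community at its first
introduction year Y is {species s ≠ focal : native(s) or first-year(s) ≤ Y}
minus extirpated species. **Extirpation boundary:** a species whose
extirpation (last-report) year equals Y is still incumbent — being
reported in Y implies presence in Y. The strict convention (absent from
year Y on) is a config switch; both are pinned by a hand-traced
six-species regression test. Same-year introductions count as incumbent
for each other ("before or during the year").

Feature rows carry incumbent richness, the number of distinct
introduction years (propagule-pressure proxy), and the focal species'
mean diet and foraging-stratum PS against the profiled incumbents.
Species lacking niche profiles count toward richness (configurable) but
never enter PS averages. An empty incumbent set yields a flagged row with
undefined PS, excluded before model fitting. Exclusion modes: game-bird
species (introduced for hunting; establishment confounded with stocking)
are dropped in the `no_gamebirds` variant; single-individual
introductions are dropped in both variants by default (switchable — the
choice is genuinely ambiguous, so both interpretations are implemented).

## 5. The model suite

* **Behavior GLMMs** (binomial, logit): per-event 0/1 response, predictors
  the site-averaged ratios, crossed random intercepts for site and
  species. Eight literature-derived predictions are registered; the three
  foraging behaviors use the four frugivore species only (the
  insectivorous outlier rarely forages), movement/location/height models
  use all five. The gleaning model carries bill slenderness in place of
  the strongly collinear horizontal aspect ratio.
* **Height LMMs** (gaussian, REML) for relative maximum and minimum
  heights, same random-effects structure.
* **PS ~ D_E** (quasibinomial GLM, logit link): PS of each within-site
  species pair on the centroid distance; dispersion estimated by Pearson
  X² after the fit (so a degenerate constant response cannot break the
  IRLS), t statistics with residual df = n − 2. A community-wide variant
  pairs diet-profile PS with pooled centroid distances.
* **Establishment GLMM** (binomial): establishment 0/1 on richness,
  introduction years, mean PS_diet, mean PS_for; taxonomic family random
  intercept; singleton families are retained.

**Mass scale.** Mass enters all models in kilograms. Species means are
tens of grams, so gram-scale logit coefficients would be ~1000-fold
smaller and numerically awkward; the kg convention puts them on the same
order as the ratio coefficients.

**Estimation.** The binomial GLMM is fit by Laplace-approximated ML
(`ecofit.mixed.BinomialMixedModel`): penalized IRLS jointly over fixed
effects and spherical random effects at fixed SDs, the Laplace correction
−½ log det(Λ'Z'WZΛ + I) at the conditional mode, and bounded Nelder-Mead
over the SDs. Fixed effects sit at the joint penalized mode (as in
glmmTMB-style Laplace) rather than being profiled in the outer
optimization as lme4 does; on a frozen fixture the two agree to ~1%
on estimates and ~4 decimals on the random-effect SDs, and the
cross-check test allows 5–10% for this implementation difference. Wald
SEs come from the fixed-effects block of the inverse penalized Fisher
information at the mode — the same conditional-on-variance covariance
lme4 reports. Setting every SD to 0 reproduces the plain GLM to machine
precision (tested limit identity). Statistics are labelled by family:
Wald z for binomial mixed models, t for gaussian.

Gaussian LMMs are estimated by statsmodels `MixedLM` (crossed random
intercepts via variance components, REML), then **polished** by
Nelder-Mead on an exact Woodbury-based restricted likelihood: the
statsmodels optimizer can stall measurably short of the REML optimum on
crossed structures, and the polished variances feed both the GLS
estimates and the Satterthwaite machinery. Satterthwaite df are computed
from finite-difference gradients of Var(β̂ⱼ; θ) and the inverse
finite-difference Hessian of the restricted likelihood; when a variance
sits on the boundary or the Hessian is not invertible the df fall back to
residual df with a note (the report marks this). Degrees of freedom of
this kind are approximation-dependent and should be read as such.

Non-convergence and quasi-separation (|logit estimate| > 50) are flagged
on the result object, never silently dropped. No multiple-testing
correction is applied (α = 0.05 throughout). Predictors enter
untransformed and uncentered; estimates are therefore on the raw ratio /
kg / PS scales.

## 6. The synthetic-data generator

The generator emulates the statistical structure of the four field
tables, not any real species:

* **Morphology:** multivariate normal per species (6 traits), negative
  draws **resampled** (not truncated) so the distributional label stays
  honest; the LLN test accounts for the slight upward shift this induces
  when means sit near zero. Default species means span a small gleaner to
  a larger insectivorous outlier (wing 57–95 mm, mass 10–40 g), with a
  fixed diagonal covariance (~3% CV). Default 20 individuals per
  species × site.
* **Observations:** per species × site cell, each behavior/movement flag
  is Bernoulli with logit = intercept + slope × (cell-level ratio), so
  events can carry several flags at once, exactly as the analysis
  assumes. Default intercepts put event frequencies in a realistic band
  (gleaning ~0.3, flycatching ~0.15, ground ~0.05) and default slopes
  carry the literature-predicted signs at the magnitude scale of the
  fitted models (+16 gleaning, −29 flycatching, −24 hanging on
  tarsus-to-wing). Locations come from a two-stage Bernoulli
  (periphery, then ground vs. interior). Relative heights are normal
  around an affine function of species mass (slope +12.4 per kg) with
  site- and species-level random intercepts (SD 0.08 each) and
  multiplied by a per-point canopy height (~N(12, 2.5²) m, floored at
  5 m), so raw and canopy heights are both emitted. Default 35 events
  per cell, matching the order of the field effort (~700 events).
* **Niche profiles:** Dirichlet draws scaled to percentages (10 diet
  categories, 7 strata; concentration 1.0), certainty grade "A".
* **Invasion history:** 126 introductions over 1850–1990 on top of 12
  natives, 35 families of which 3 are game-bird families, 5%
  single-individual introductions. Introduction years are drawn
  **without replacement**: a same-year tie would make the sequential
  establishment draw circular (a tied species' incumbency would depend on
  an outcome not yet drawn); the analysis path still handles ties in real
  data. Species are processed in calendar order; richness and mean PS
  features are computed with the *same* `assembly`/`similarity` code the
  analysis uses (a shared-code oracle test asserts exact equality), and
  establishment is Bernoulli on logit = 3.6 − 0.028·richness +
  0.013·years − 6.649·PS_diet + 1.131·PS_for plus a N(0, 0.5²) family
  intercept — the coefficient scale of the fitted establishment model,
  with the intercept placed to give a realistic (~1/3–1/2)
  establishment rate. Failed introductions get an extirpation year 0–10
  years after arrival.

All randomness flows from a single config seed through per-stage
`default_rng([seed, stage])` streams; fixing the seed fixes every table
byte-for-byte.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about field data: measurement error and observer bias,
phylogenetic correlation of traits and niches (profiles are exchangeable
Dirichlet draws), spatial structure within sites, temporal/seasonal
variation, taxonomic structure in introduction effort, and the
EltonTraits certainty-grade heterogeneity (all synthetic profiles are
grade A). Recovery results certify the estimators under the generator's
assumptions, not the field conclusions themselves.

## 7. Experiment sizes and numerical settings

The recovery and calibration experiments
(`ecofit.experiments`, re-run by `scripts/acceptance.py`) use 100
replicates for the two slope-recovery checks (establishment: 300
introductions, slope −8, family SD 0.5; behavior: 5 × 4 × 250 events,
slope +16) and 500 replicates for the type-I calibration at the default
35-events-per-cell effort — sizes at which Monte-Carlo error on the
reported rates is a few percent and a full run takes minutes on one CPU.
Inner IRLS converges on a 1e−10 relative penalized-deviance change with
step halving; the outer Nelder-Mead uses xatol 1e−4 on SDs bounded in
[0, 10]. PS normalisation tolerance is 1e−6 after percent conversion.
Ties in min() need no handling (the sum is total); degenerate inputs
(zero covariance, constant traits, empty incumbent sets, zero foraging
events, constant PS) are covered by explicit tests.

## 8. Known limitations

* Satterthwaite df via finite differences can be unavailable near
  variance boundaries (reported with a note, residual-df fallback).
* The Laplace approximation is least accurate for few groups with large
  variances; the lme4 cross-check bounds the discrepancy only on the
  fixture's regime (4–5 levels per factor, moderate SDs).
* The quasibinomial PS ~ D_E model treats pairwise similarities as
  independent observations, as the original analysis design does; the
  shared-species dependence between pairs is not modelled.
* `mean_ps_to_set` averages in sorted-species order for bit-level
  reproducibility; changing the order would perturb results only at
  floating-point level.
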