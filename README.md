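# ecofit

Ecomorphology and invasion-history analysis for novel bird communities.

Oceanic islands such as O'ahu now host bird communities assembled almost
entirely from introduced species. Two questions follow for community
ecologists. First, do the classic form–function relationships of
native-dominated avifaunas — bill shape predicting diet, limb proportions
predicting movement and foraging stratum — survive in a community whose
members share no evolutionary history? Second, did *ecological fitting*
shape the community's assembly: were introductions more likely to establish
when their ecological niche was distinct from the species already present?

`ecofit` implements the full analysis pipeline for both questions as a
tested, reusable library with a command-line front end, together with a
synthetic-data generator that reproduces the statistical structure of each
input table with known ground truth, so every stage has a
parameter-recovery or exact-oracle test without any external data.

## The statistics at the core

**Proportional similarity.** Niche overlap between two resource-use
distributions *p* and *q* over the same categories (diet items, foraging
strata, or observed behaviors):

    PS = Σᵢ min(pᵢ, qᵢ)  =  1 − ½ Σᵢ |pᵢ − qᵢ|

PS is 1 for identical distributions and 0 for disjoint ones; the L1
identity on the right serves as an independent test oracle.

**Morphological ratios.** From five linear measurements plus mass:
tarsus-to-wing ratio (hopping/understory vs. flight-based foraging),
horizontal bill aspect (culmen / bill width at the nares), and bill
slenderness (culmen / elliptical bill cross-section at the nares, 1/mm;
larger = longer, thinner bill). Ratios are computed per individual, then
averaged per species × site. A PCA over individuals (centered, unscaled by
default) defines the morphospace; Euclidean distances between species
centroids (D_E) quantify morphological similarity.

**The model suite.**

* Behavior models: binomial GLMMs of per-event presence/absence (gleaning,
  flycatching, frugivory, hanging, hopping, plant location) on the
  site-averaged ratios, with crossed random intercepts for site and
  species. Fitted by Laplace-approximated maximum likelihood
  (`ecofit.mixed`, cross-validated against `lme4::glmer`).
* Height models: gaussian mixed models (REML) of relative foraging height
  (observed height / mean canopy height of the point), with Satterthwaite
  denominator degrees of freedom.
* Similarity vs. distance: quasibinomial GLM of pairwise behavioral PS on
  pairwise centroid distance D_E.
* Establishment: binomial GLMM of establishment success on mean diet PS
  and mean foraging-stratum PS against the incumbent community at the
  introduction year, incumbent richness, and the number of introduction
  years (propagule-pressure proxy), with a taxonomic-family random
  intercept; run with and without game-bird species.

The incumbent community at year *Y* is every species that is native or was
first introduced in or before *Y* and not yet extirpated (a species last
reported in *Y* still counts for year-*Y* introductions; the strict
alternative is a config switch).

## Worked example

```python
from ecofit import proportional_similarity, RunConfig, run_pipeline

proportional_similarity((0.6, 0.3, 0.1), (0.2, 0.5, 0.3))
# 0.6  (= min(.6,.2) + min(.3,.5) + min(.1,.3))

res = run_pipeline(RunConfig(outdir="demo_run", seed=42))
coef = res["coefficients"].set_index(["model", "term"])
```

The default configuration simulates the study conditions (5 focal species
at 4 sites; 126 introductions on top of 12 natives) and fits the full
suite. Selected coefficients from the run above:

```
P2_gleaning          tarsus_to_wing      est=16.409  se=2.524  p=0.0000
P4_frugivory         bill_slenderness    est=-6.257  se=1.498  p=0.0000
establishment_all    mean_ps_diet        est=-6.469  se=4.874  p=0.1844
ps_vs_distance_focal euclidean_distance  est=-0.075  se=0.009  p=0.0000
```

Each line is a fixed-effect estimate on the logit scale with its Wald SE:
longer-tarsused species glean more (generator truth +16), robust-billed
species eat more fruit (truth −5), similarity falls with morphospace
distance, and diet-distinct introductions establish more readily (truth
−6.649; at n = 123 introductions a single replicate is noisy — the
recovery experiments below quantify this). The same run is available from
the shell:

```sh
ecofit run --seed 42 --outdir demo_run
```

The bundle contains the four input tables, all intermediate tables
(ratios, PCA scores, distances, behavior distributions, PS tables,
establishment features, a per-introduction incumbent audit), coefficient
tables, a text report, and a provenance record; identical seeds give
byte-identical bundles.

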