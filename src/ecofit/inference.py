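"""The model suite: behavior ~ morphology GLMMs, relative-height linear
mixed models, the niche-similarity ~ morphospace-distance quasibinomial
GLM, and the establishment GLMM.

Conventions shared across models:

* predictors are the site-averaged morphological ratios, entered
  untransformed; mass enters in kilograms (species-mean masses are tens of
  grams, so gram-scale coefficients would be microscopically small);
* binomial mixed models report Wald z statistics, gaussian mixed models
  report t statistics with Satterthwaite denominator df, and the
  quasibinomial GLM reports t statistics with residual df (n - p);
* no multiple-testing correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import t as t_dist

from .mixed import BinomialMixedModel, indicator_matrix, satterthwaite_df
from .mixed import reml_refine as mixed_reml_refine


@dataclass(frozen=True)
class ModelSpec:
    """One registered model of the ecomorphology suite."""

    prediction: int                 # literature-derived prediction number
    response: str
    predictors: tuple
    family: str                     # binomial | gaussian
    excludes_insectivore: bool      # True -> 4-species foraging models
    n_species: int

    @property
    def name(self) -> str:
        return f"P{self.prediction}_{self.response}"


#: the literature-derived prediction suite: response, predictors, family.
#: Foraging behaviors (gleaning, flycatching, frugivory) use the four
#: frugivore species only — the insectivorous outlier species rarely
#: forages and enters only the movement/height/location models (5 species).
#: Bill slenderness stands in for the (collinear) horizontal aspect ratio
#: in the gleaning model.
MODEL_REGISTRY: tuple[ModelSpec, ...] = (
    ModelSpec(1, "rel_max_height", ("tarsus_to_wing", "mass_kg"), "gaussian", False, 5),
    ModelSpec(1, "rel_min_height", ("tarsus_to_wing", "mass_kg"), "gaussian", False, 5),
    ModelSpec(2, "gleaning", ("bill_slenderness", "tarsus_to_wing"), "binomial", True, 4),
    ModelSpec(3, "flycatching", ("horizontal_bill_aspect", "tarsus_to_wing"), "binomial", True, 4),
    ModelSpec(4, "frugivory", ("bill_slenderness", "mass_kg"), "binomial", True, 4),
    ModelSpec(5, "hanging", ("tarsus_to_wing", "mass_kg"), "binomial", False, 5),
    ModelSpec(6, "hop", ("tarsus_to_wing", "mass_kg"), "binomial", False, 5),
    ModelSpec(7, "in_periphery", ("tarsus_to_wing", "mass_kg"), "binomial", False, 5),
    ModelSpec(7, "in_interior", ("tarsus_to_wing", "mass_kg"), "binomial", False, 5),
    ModelSpec(8, "on_ground", ("tarsus_to_wing", "mass_kg"), "binomial", False, 5),
)


@dataclass
class FitResult:
    """Coefficient table plus fit metadata, one per fitted model."""

    model: str
    family: str
    terms: pd.DataFrame     # term, estimate, se, statistic, df, p_value
    n_obs: int
    n_groups: dict = field(default_factory=dict)
    converged: bool = True
    note: str = ""

    def to_frame(self) -> pd.DataFrame:
        out = self.terms.copy()
        out.insert(0, "model", self.model)
        out["family"] = self.family
        out["n_obs"] = self.n_obs
        out["converged"] = self.converged
        return out

    def term(self, name: str) -> pd.Series:
        hit = self.terms[self.terms["term"] == name]
        if hit.empty:
            raise KeyError(name)
        return hit.iloc[0]


def _join_predictors(response: pd.DataFrame, ratios: pd.DataFrame,
                     predictors) -> pd.DataFrame:
    rt = ratios.copy()
    rt["mass_kg"] = rt["mass_mean"] / 1000.0
    cols = ["species", "site"] + list(predictors)
    df = response.merge(rt[cols], on=["species", "site"], how="inner")
    if df.empty:
        raise ValueError("no overlap between responses and ratio table")
    return df


def fit_behavior_model(response: pd.DataFrame, ratios: pd.DataFrame,
                       predictors, model_name: str = "behavior",
                       exclude_species=(), fix_sd: dict | None = None) -> FitResult:
    """Binomial GLMM: per-event behavior ~ site-averaged ratios, with
    random intercepts for site and species.

    ``response`` holds one row per event (``species, site, y``);
    ``exclude_species`` removes species (e.g. the rarely-foraging
    insectivore) before fitting.
    """
    resp = response[~response["species"].isin(set(exclude_species))]
    df = _join_predictors(resp, ratios, predictors)
    if df["site"].nunique() < 2 or df["species"].nunique() < 2:
        raise ValueError("behavior GLMM needs >= 2 sites and >= 2 species")
    X = np.column_stack([np.ones(len(df))] +
                        [df[p].to_numpy(float) for p in predictors])
    model = BinomialMixedModel(
        df["y"].to_numpy(), X,
        groups={"site": df["site"].to_numpy(), "species": df["species"].to_numpy()},
        xnames=["(Intercept)"] + list(predictors))
    fit = model.fit(fix_sd=fix_sd)
    terms = fit.summary_frame()
    terms.insert(4, "df", np.nan)
    return FitResult(model=model_name, family="binomial", terms=terms,
                     n_obs=fit.n_obs, n_groups=fit.n_groups,
                     converged=fit.converged, note=fit.note)


def fit_height_model(heights: pd.DataFrame, ratios: pd.DataFrame,
                     response: str, predictors=("tarsus_to_wing", "mass_kg"),
                     model_name: str | None = None) -> FitResult:
    """Gaussian LMM (REML): relative height ~ ratios, random intercepts for
    site and species (crossed). Fits one of ``rel_max_height`` /
    ``rel_min_height``; t statistics use Satterthwaite df where the
    variance estimates are interior, otherwise residual df with a note.
    """
    if response not in ("rel_max_height", "rel_min_height"):
        raise ValueError(f"unknown height response {response!r}")
    df = _join_predictors(heights.rename(columns={response: "y"}), ratios,
                          predictors)
    formula = "y ~ " + " + ".join(predictors)
    note = ""
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(formula, df, groups=np.ones(len(df)),
                            re_formula="0",
                            vc_formula={"site": "0 + C(site)",
                                        "species": "0 + C(species)"})
        res = model.fit(reml=True)
        if any("Converg" in str(w.message) or "boundary" in str(w.message).lower()
               for w in caught):
            note = "variance estimate near boundary; fit close to plain LM"
    # polish the variance estimate on the restricted likelihood (the
    # statsmodels optimizer can stall short of the optimum on crossed
    # variance-component structures), then GLS estimates at the optimum
    vc_names = model.exog_vc.names
    vcomp = {nm: v for nm, v in zip(vc_names, res.vcomp)}
    Z_list = [indicator_matrix(df["site"]), indicator_matrix(df["species"])]
    X = np.column_stack([np.ones(len(df))] +
                        [df[p].to_numpy(float) for p in predictors])
    yv = df["y"].to_numpy(float)
    var_comps, var_resid, est, se, _ = mixed_reml_refine(
        yv, X, Z_list, [vcomp.get("site", 0.0), vcomp.get("species", 0.0)],
        res.scale)
    dfs = satterthwaite_df(yv, X, Z_list, var_comps, var_resid)
    resid_df = len(df) - X.shape[1]
    dfs = np.where(np.isfinite(dfs) & (dfs > 0) & (dfs <= 10 * len(df)),
                   dfs, np.nan)
    if np.isnan(dfs).any():
        note = (note + "; " if note else "") + \
            "Satterthwaite df unavailable for some terms; residual df used"
        dfs = np.where(np.isnan(dfs), resid_df, dfs)
    stat = est / se
    pvals = 2 * t_dist.sf(np.abs(stat), dfs)
    terms = pd.DataFrame({
        "term": ["(Intercept)"] + list(predictors),
        "estimate": est, "se": se, "statistic": stat, "df": dfs,
        "p_value": pvals,
    })
    return FitResult(model=model_name or f"P1_{response}", family="gaussian",
                     terms=terms, n_obs=len(df),
                     n_groups={"site": df["site"].nunique(),
                               "species": df["species"].nunique()},
                     converged=res.converged, note=note)


def fit_ps_vs_distance(pairs: pd.DataFrame, ps_col: str = "ps",
                       distance_col: str = "euclidean_distance",
                       model_name: str = "ps_vs_distance") -> FitResult:
    """Quasibinomial GLM (logit link, Pearson-X2 dispersion) of pairwise
    niche similarity on morphospace centroid distance.

    One row per species pair; t statistics with residual df = n - 2.
    """
    df = pairs.dropna(subset=[ps_col, distance_col])
    if len(df) < 3:
        raise ValueError(f"need >= 3 (ps, distance) pairs, got {len(df)}")
    y = df[ps_col].to_numpy(float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("PS values outside [0, 1]")
    X = sm.add_constant(df[distance_col].to_numpy(float))
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    resid_df = len(df) - 2
    # quasibinomial: point estimates as binomial, SEs scaled by the Pearson
    # dispersion (estimated after the fit so a perfectly constant response
    # does not break the IRLS loop)
    dispersion = float(res.pearson_chi2) / resid_df
    se = res.bse * np.sqrt(dispersion)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, res.params / se, np.nan)
    pvals = 2 * t_dist.sf(np.abs(stat), resid_df)
    terms = pd.DataFrame({
        "term": ["(Intercept)", distance_col],
        "estimate": res.params, "se": se, "statistic": stat,
        "df": float(resid_df), "p_value": pvals,
    })
    return FitResult(model=model_name, family="quasibinomial", terms=terms,
                     n_obs=len(df), converged=res.converged,
                     note=f"dispersion={dispersion:.4g}")


ESTABLISHMENT_PREDICTORS = ("incumbent_richness", "n_introduction_years",
                            "mean_ps_diet", "mean_ps_for")


def fit_establishment_model(features: pd.DataFrame,
                            predictors=ESTABLISHMENT_PREDICTORS,
                            model_name: str = "establishment",
                            fix_sd: dict | None = None) -> FitResult:
    """Binomial GLMM of establishment success on niche-distinctiveness and
    propagule-pressure features, with a taxonomic-family random intercept.

    Expects an already-filtered feature table (see
    :func:`ecofit.assembly.apply_exclusions`); rows with missing features
    are dropped. Families represented by a single species are retained.
    """
    df = features.dropna(subset=list(predictors)).reset_index(drop=True)
    if df.empty:
        raise ValueError("no complete feature rows to fit")
    X = np.column_stack([np.ones(len(df))] +
                        [df[p].to_numpy(float) for p in predictors])
    model = BinomialMixedModel(
        df["established"].astype(float).to_numpy(), X,
        groups={"family": df["family"].to_numpy()},
        xnames=["(Intercept)"] + list(predictors))
    fit = model.fit(fix_sd=fix_sd)
    terms = fit.summary_frame()
    terms.insert(4, "df", np.nan)
    return FitResult(model=model_name, family="binomial", terms=terms,
                     n_obs=fit.n_obs, n_groups=fit.n_groups,
                     converged=fit.converged, note=fit.note)


def fit_registry(responses: dict[str, pd.DataFrame], heights: pd.DataFrame,
                 ratios: pd.DataFrame, insectivore_species=()) -> list[FitResult]:
    """Fit every registered model of the suite and return the results in
    registry order."""
    out = []
    for spec in MODEL_REGISTRY:
        excl = tuple(insectivore_species) if spec.excludes_insectivore else ()
        if spec.family == "gaussian":
            out.append(fit_height_model(heights, ratios, spec.response,
                                        spec.predictors, model_name=spec.name))
        else:
            out.append(fit_behavior_model(responses[spec.response], ratios,
                                          spec.predictors, model_name=spec.name,
                                          exclude_species=excl))
    return out
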