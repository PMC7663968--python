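"""The model suite: registry contract, per-family fitting behaviour,
recovery smoke checks."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from ecofit import foraging, morphometrics, simulate
from ecofit.inference import (MODEL_REGISTRY, fit_behavior_model,
                              fit_establishment_model, fit_height_model,
                              fit_ps_vs_distance)
from ecofit.simulate import LogisticCoef, SimConfig


def test_registry_covers_every_prediction():
    preds = sorted({s.prediction for s in MODEL_REGISTRY})
    assert preds == list(range(1, 9))
    for spec in MODEL_REGISTRY:
        if spec.response in ("gleaning", "flycatching", "frugivory"):
            # foraging behaviors exclude the rarely-foraging insectivore
            assert spec.excludes_insectivore and spec.n_species == 4
        else:
            assert not spec.excludes_insectivore and spec.n_species == 5
        assert spec.family == ("gaussian" if "height" in spec.response
                               else "binomial")
    # the gleaning model substitutes bill slenderness for the collinear
    # horizontal aspect ratio
    glean = [s for s in MODEL_REGISTRY if s.response == "gleaning"][0]
    assert "bill_slenderness" in glean.predictors
    assert "horizontal_bill_aspect" not in glean.predictors


@pytest.fixture(scope="module")
def behavior_data():
    cfg = SimConfig(seed=17, n_obs_per_species_site=120)
    cfg.behavior_coefs = dict(cfg.behavior_coefs)
    cfg.behavior_coefs["gleaning"] = LogisticCoef(-5.1, 16.0, "tarsus_to_wing")
    morpho = simulate.simulate_morphology(cfg)
    ratios = morphometrics.compute_ratios(morpho)
    events = simulate.simulate_observations(cfg, ratios)
    responses = foraging.response_vectors(events)
    heights = foraging.relative_heights(events)
    return cfg, ratios, responses, heights


def test_behavior_slope_sign_recovered(behavior_data):
    cfg, ratios, responses, _ = behavior_data
    fit = fit_behavior_model(responses["gleaning"], ratios,
                             ("tarsus_to_wing",))
    slope = fit.term("tarsus_to_wing")
    assert slope["estimate"] > 0
    assert abs(slope["estimate"] - 16.0) < 3 * slope["se"]
    assert fit.n_groups == {"site": 4, "species": 5}


def test_insectivore_exclusion_reduces_species(behavior_data):
    cfg, ratios, responses, _ = behavior_data
    fit = fit_behavior_model(responses["gleaning"], ratios,
                             ("tarsus_to_wing",),
                             exclude_species=(cfg.insectivore,))
    assert fit.n_groups["species"] == 4


def test_behavior_model_input_guards(behavior_data):
    _, ratios, responses, _ = behavior_data
    one_site = responses["gleaning"].query("site == 'S01'")
    with pytest.raises(ValueError, match=">= 2 sites"):
        fit_behavior_model(one_site, ratios, ("tarsus_to_wing",))
    with pytest.raises(ValueError, match="no overlap"):
        fit_behavior_model(responses["gleaning"].assign(species="nope"),
                           ratios, ("tarsus_to_wing",))


def test_height_model_recovers_mass_sign(behavior_data):
    _, ratios, _, heights = behavior_data
    for resp in ("rel_max_height", "rel_min_height"):
        fit = fit_height_model(heights, ratios, resp)
        mass = fit.term("mass_kg")
        assert mass["estimate"] > 0      # heavier species forage higher
        assert np.isfinite(mass["df"]) and mass["df"] > 0
    with pytest.raises(ValueError, match="height response"):
        fit_height_model(heights, ratios, "height")


def test_height_model_zero_variance_degrades_to_lm():
    cfg = SimConfig(seed=23, height_site_sd=0.0, height_species_sd=0.0,
                    n_obs_per_species_site=60)
    morpho = simulate.simulate_morphology(cfg)
    ratios = morphometrics.compute_ratios(morpho)
    events = simulate.simulate_observations(cfg, ratios)
    heights = foraging.relative_heights(events)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_height_model(heights, ratios, "rel_max_height")
    import statsmodels.api as sm
    df = heights.merge(ratios.assign(mass_kg=ratios.mass_mean / 1000)[
        ["species", "site", "tarsus_to_wing", "mass_kg"]],
        on=["species", "site"])
    X = sm.add_constant(df[["tarsus_to_wing", "mass_kg"]].to_numpy())
    ols = sm.OLS(df["rel_max_height"].to_numpy(), X).fit()
    # with (near-)zero group variances the GLS estimate approaches OLS
    np.testing.assert_allclose(fit.terms["estimate"].to_numpy(),
                               ols.params, rtol=0.05, atol=0.02)


def _ps_distance_data(rng, n=40, a=2.0, b=0.5):
    d = rng.uniform(0, 6, n)
    mu = expit(a - b * d)
    ps = np.clip(mu + rng.normal(0, 0.05, n), 0.01, 0.99)
    return pd.DataFrame({"ps": ps, "euclidean_distance": d})


def test_quasibinomial_recovery_and_df():
    rng = np.random.default_rng(31)
    df = _ps_distance_data(rng)
    fit = fit_ps_vs_distance(df)
    slope = fit.term("euclidean_distance")
    assert slope["estimate"] < 0
    assert abs(slope["estimate"] - (-0.5)) < 3 * slope["se"]
    assert slope["df"] == len(df) - 2     # residual df rule
    assert fit.family == "quasibinomial"


def test_quasibinomial_constant_response():
    df = pd.DataFrame({"ps": [0.5] * 20,
                       "euclidean_distance": np.linspace(0, 5, 20)})
    fit = fit_ps_vs_distance(df)
    assert fit.term("euclidean_distance")["estimate"] == pytest.approx(0, abs=1e-8)
    assert float(fit.note.split("=")[1]) == pytest.approx(0, abs=1e-12)
    with pytest.raises(ValueError, match=">= 3"):
        fit_ps_vs_distance(df.iloc[:2])
    with pytest.raises(ValueError, match="outside"):
        fit_ps_vs_distance(df.assign(ps=1.5))


def test_establishment_modes_drop_exact_counts(small_sim):
    from ecofit import assembly
    feats = small_sim["truth"]["features"]
    filt_all = assembly.apply_exclusions(feats, mode="all",
                                         drop_single_individual=False)
    filt_ng = assembly.apply_exclusions(feats, mode="no_gamebirds",
                                        drop_single_individual=False)
    n_game = int(feats["game_bird"].sum())
    fit_all = fit_establishment_model(filt_all)
    fit_ng = fit_establishment_model(filt_ng)
    assert fit_all.n_obs - fit_ng.n_obs == n_game
    assert "family" in fit_all.n_groups
    with pytest.raises(ValueError, match="no complete"):
        fit_establishment_model(feats.assign(mean_ps_diet=np.nan))
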