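"""Synthetic-data generator: determinism, degenerate cases, link checks,
and the shared-code feature oracle."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ecofit import assembly, ingest, morphometrics, similarity, simulate
from ecofit.simulate import LogisticCoef, SimConfig


def test_fixed_seed_fixes_every_table(small_sim):
    cfg = small_sim["cfg"]
    morpho2 = simulate.simulate_morphology(cfg)
    pd.testing.assert_frame_equal(small_sim["morpho"], morpho2)
    ratios2 = morphometrics.compute_ratios(morpho2)
    events2 = simulate.simulate_observations(cfg, ratios2)
    pd.testing.assert_frame_equal(small_sim["events"], events2)
    intro2, profiles2, truth2 = simulate.simulate_invasion_history(cfg)
    pd.testing.assert_frame_equal(small_sim["intro"], intro2)
    pd.testing.assert_frame_equal(small_sim["profiles"], profiles2)
    pd.testing.assert_frame_equal(small_sim["truth"]["features"],
                                  truth2["features"])


def test_zero_covariance_gives_species_means():
    cfg = SimConfig(seed=1, morpho_cov=np.zeros((6, 6)),
                    n_individuals_per_species_site=3, n_sites=2)
    out = simulate.simulate_morphology(cfg)
    for sp, mean in cfg.morpho_means.items():
        sub = out[out.species == sp]
        traits = sub[["wing_length", "tarsus_length", "culmen_length",
                      "bill_width_nares", "bill_depth_nares", "mass"]]
        assert np.allclose(traits.to_numpy(), np.asarray(mean), atol=0)


def test_measurements_strictly_positive_and_lln():
    means = {"tiny": (2.0, 2.0, 2.0, 2.0, 2.0, 2.0)}  # heavy truncation risk
    cfg = SimConfig(seed=3, morpho_means=means, n_sites=1,
                    n_individuals_per_species_site=2000,
                    morpho_cov=np.diag([1.0, 0.25, 0.25, 0.25, 0.25, 0.25]))
    out = simulate.simulate_morphology(cfg)
    assert (out[["wing_length", "mass"]] > 0).all().all()
    # resampling truncates the left tail, so the mean sits slightly above
    # the configured value; allow 3 SE around the truncated-normal mean
    w = out["wing_length"]
    se = w.std(ddof=1) / np.sqrt(len(w))
    from scipy.stats import truncnorm
    tmean = truncnorm.mean(-2.0, np.inf, loc=2.0, scale=1.0)
    assert abs(w.mean() - tmean) < 3 * se


def test_non_psd_covariance_rejected():
    bad = -np.eye(6)
    with pytest.raises(ValueError, match="positive semi-definite"):
        SimConfig(seed=0, morpho_cov=bad).validate()


def test_unknown_behavior_name_rejected(small_sim):
    cfg = SimConfig(seed=0)
    cfg.behavior_coefs = dict(cfg.behavior_coefs)
    cfg.behavior_coefs["burrowing"] = LogisticCoef(0.0, 0.0)
    with pytest.raises(ValueError, match="burrowing"):
        simulate.simulate_observations(cfg, small_sim["ratios"])


def test_null_logit_gives_half_frequency():
    cfg = SimConfig(seed=4, n_sites=1, n_obs_per_species_site=1000)
    cfg.behavior_coefs = dict(cfg.behavior_coefs)
    cfg.behavior_coefs["gleaning"] = LogisticCoef(0.0, 0.0)
    ratios = morphometrics.compute_ratios(simulate.simulate_morphology(cfg))
    ev = simulate.simulate_observations(cfg, ratios)
    freq = ev["gleaning"].mean()
    n = len(ev)
    assert abs(freq - 0.5) < 3 * np.sqrt(0.25 / n)


def test_monotone_link_orders_species():
    means = {"lowratio": (100.0, 20.0, 10.0, 4.0, 4.0, 20.0),   # t:w = 0.2
             "highratio": (100.0, 40.0, 10.0, 4.0, 4.0, 20.0)}  # t:w = 0.4
    cfg = SimConfig(seed=6, morpho_means=means, n_sites=1,
                    n_obs_per_species_site=5000)
    cfg.behavior_coefs = dict(cfg.behavior_coefs)
    cfg.behavior_coefs["gleaning"] = LogisticCoef(-3.0, 10.0, "tarsus_to_wing")
    ratios = morphometrics.compute_ratios(simulate.simulate_morphology(cfg))
    ev = simulate.simulate_observations(cfg, ratios)
    freq = ev.groupby("species")["gleaning"].mean()
    assert freq["highratio"] > freq["lowratio"]


def test_emitted_heights_consistent_with_canopy(small_sim):
    ev = small_sim["events"]
    assert (ev["min_height"] <= ev["max_height"] + 1e-12).all()
    assert (ev["canopy_height_mean"] > 0).all()
    rel = ev["max_height"] / ev["canopy_height_mean"]
    assert (rel > 0).all()


def test_invasion_requires_two_species():
    cfg = SimConfig(seed=0, n_introduced=1, n_native=0)
    with pytest.raises(ValueError, match="two species"):
        simulate.simulate_invasion_history(cfg)


def test_identical_profiles_give_unit_ps():
    cfg = SimConfig(seed=8, n_introduced=20, n_native=3,
                    n_diet_categories=1, n_strata_categories=1,
                    timeline_span=(1900, 1950))
    intro, profiles, truth = simulate.simulate_invasion_history(cfg)
    feats = truth["features"]
    assert np.allclose(feats["mean_ps_diet"], 1.0)
    assert np.allclose(feats["mean_ps_for"], 1.0)


def test_simulator_features_match_analysis_path(small_sim):
    """Shared-code oracle: rebuilding features from the emitted tables
    reproduces the simulator's internal features exactly."""
    ps_tables = {
        kind: similarity.pairwise_ps(
            ingest.profile_matrix(small_sim["profiles"], kind), kind=kind)
        for kind in ("diet", "foraging_stratum")
    }
    rebuilt = assembly.build_features(small_sim["intro"], ps_tables,
                                      boundary="inclusive")
    truth = small_sim["truth"]["features"]
    merged = rebuilt.merge(truth, on="species", suffixes=("", "_sim"))
    assert len(merged) == len(truth)
    for col in ("incumbent_richness", "n_introduction_years",
                "mean_ps_diet", "mean_ps_for", "established"):
        np.testing.assert_array_equal(merged[col].to_numpy(),
                                      merged[f"{col}_sim"].to_numpy())


def test_null_psdiet_slope_covers_zero():
    """With beta_PSdiet = 0 and no family effect, establishment is
    unrelated to diet similarity: the logistic slope CI covers 0."""
    cfg = SimConfig(seed=9, n_introduced=500, n_native=12, family_sd=0.0,
                    estab_coefs=(0.0, 0.0, 0.0, 0.0, 0.0),
                    timeline_span=(1400, 1999))
    _, _, truth = simulate.simulate_invasion_history(cfg)
    f = truth["features"].dropna(subset=["mean_ps_diet"])
    X = sm.add_constant(f["mean_ps_diet"].to_numpy())
    res = sm.GLM(f["established"].astype(float).to_numpy(), X,
                 family=sm.families.Binomial()).fit()
    lo, hi = res.conf_int()[1]
    assert lo <= 0.0 <= hi
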