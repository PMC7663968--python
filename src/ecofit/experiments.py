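"""Simulation experiments that characterise the estimators: parameter
recovery, type-I calibration, limit identities, and reproducibility.

Each experiment fixes its study conditions (sample sizes, true effect
sizes on the scale of the reported models) and varies only the seed, so
repeated runs quantify the sampling behaviour of the pipeline's own
estimators against the generator's known truth.
"""

from __future__ import annotations

import hashlib
import tempfile
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from . import foraging, morphometrics, simulate
from .inference import fit_behavior_model, fit_establishment_model
from .mixed import BinomialMixedModel
from .pipeline import RunConfig, run_pipeline
from .similarity import proportional_similarity
from .simulate import LogisticCoef, SimConfig


def _rep_seed(seed: int, rep: int) -> int:
    return (seed * 10_007 + rep) % (2 ** 31 - 1)


def ps_l1_identity(n_pairs: int = 1000, seed: int = 0) -> float:
    """Max |PS - (1 - L1/2)| over random distribution pairs (exact identity;
    should sit at floating-point noise)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_pairs):
        k = int(rng.integers(2, 12))
        p = rng.dirichlet(np.ones(k))
        q = rng.dirichlet(np.ones(k))
        ps = proportional_similarity(p, q)
        worst = max(worst, abs(ps - (1.0 - 0.5 * np.abs(p - q).sum())))
    return worst


def establishment_recovery(n_reps: int = 100, seed: int = 0,
                           beta_ps_diet: float = -8.0,
                           family_sd: float = 0.5,
                           n_introduced: int = 300) -> dict:
    """Recover the diet-similarity slope of the establishment GLMM.

    Per replicate: a fresh invasion history (300 introductions, 12 native
    incumbents, diet-PS slope on the magnitude scale of the reported
    establishment model, family random-intercept SD 0.5), the full
    four-predictor fit, and a check whether the estimate is negative and
    the truth falls inside its 95% Wald CI.
    """
    z = norm.ppf(0.975)
    ok = sign = 0
    ests = []
    for rep in range(n_reps):
        cfg = SimConfig(seed=_rep_seed(seed, rep), n_introduced=n_introduced,
                        n_native=12, timeline_span=(1600, 1999),
                        estab_coefs=(4.1, 0.0, 0.0, beta_ps_diet, 0.0),
                        family_sd=family_sd, single_individual_rate=0.0)
        _, _, truth = simulate.simulate_invasion_history(cfg)
        fit = fit_establishment_model(truth["features"])
        t = fit.term("mean_ps_diet")
        est, se = t["estimate"], t["se"]
        ests.append(est)
        covered = (est - z * se) <= beta_ps_diet <= (est + z * se)
        if est < 0 and covered:
            ok += 1
        if est < 0:
            sign += 1
    return {"n_reps": n_reps, "recovered": ok, "negative_sign": sign,
            "mean_estimate": float(np.mean(ests)), "truth": beta_ps_diet}


def behavior_recovery(n_reps: int = 100, seed: int = 0,
                      slope: float = 16.0,
                      n_obs_per_cell: int = 250) -> dict:
    """Recover the tarsus-to-wing gleaning slope of the behavior GLMM
    (5 species x 4 sites x 250 events per cell)."""
    z = norm.ppf(0.975)
    ok = sign = 0
    ests = []
    for rep in range(n_reps):
        cfg = SimConfig(seed=_rep_seed(seed, rep),
                        n_obs_per_species_site=n_obs_per_cell)
        cfg.behavior_coefs = dict(cfg.behavior_coefs)
        cfg.behavior_coefs["gleaning"] = LogisticCoef(
            -slope * 0.28, slope, "tarsus_to_wing")
        morpho = simulate.simulate_morphology(cfg)
        ratios = morphometrics.compute_ratios(morpho)
        events = simulate.simulate_observations(cfg, ratios)
        resp = foraging.response_vectors(events, responses=("gleaning",))
        fit = fit_behavior_model(resp["gleaning"], ratios, ("tarsus_to_wing",))
        t = fit.term("tarsus_to_wing")
        est, se = t["estimate"], t["se"]
        ests.append(est)
        if est > 0 and (est - z * se) <= slope <= (est + z * se):
            ok += 1
        if est > 0:
            sign += 1
    return {"n_reps": n_reps, "recovered": ok, "positive_sign": sign,
            "mean_estimate": float(np.mean(ests)), "truth": slope}


def type1_calibration(n_reps: int = 500, seed: int = 0,
                      alpha: float = 0.05) -> dict:
    """Rejection rate of the slope Wald test when every behavior slope is
    zero (events iid Bernoulli(1/2) regardless of morphology)."""
    rejections = 0
    for rep in range(n_reps):
        cfg = SimConfig(seed=_rep_seed(seed, rep))
        cfg.behavior_coefs = dict(cfg.behavior_coefs)
        cfg.behavior_coefs["gleaning"] = LogisticCoef(0.0, 0.0)
        morpho = simulate.simulate_morphology(cfg)
        ratios = morphometrics.compute_ratios(morpho)
        events = simulate.simulate_observations(cfg, ratios)
        resp = foraging.response_vectors(events, responses=("gleaning",))
        fit = fit_behavior_model(resp["gleaning"], ratios, ("tarsus_to_wing",))
        if fit.term("tarsus_to_wing")["p_value"] < alpha:
            rejections += 1
    return {"n_reps": n_reps, "rejections": rejections,
            "rate": rejections / n_reps, "nominal": alpha}


def glm_limit_difference(seed: int = 0, n: int = 800) -> dict:
    """Max |GLMM(sd=0) - GLM| over estimates and SEs on one simulated
    behavior dataset (limit identity)."""
    rng = np.random.default_rng(seed)
    site = rng.integers(0, 4, n)
    sp = rng.integers(0, 5, n)
    x = np.array([0.30, 0.34, 0.23, 0.24, 0.28])[sp] + 0.015 * site
    eta = -3.0 + 10.0 * x
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    X = np.column_stack([np.ones(n), x])
    model = BinomialMixedModel(y, X, {"site": site.astype(str),
                                      "species": sp.astype(str)})
    fit0 = model.fit(fix_sd={"site": 0.0, "species": 0.0})
    glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    return {"max_param_diff": float(np.max(np.abs(fit0.params - glm.params))),
            "max_se_diff": float(np.max(np.abs(fit0.se - glm.bse))),
            "n": n}


def bundle_determinism(seed: int = 0, workdir=None) -> bool:
    """Run the reduced pipeline twice with one seed: byte-identical bundles?"""
    sim_kwargs = dict(n_individuals_per_species_site=8,
                      n_obs_per_species_site=20, n_introduced=40, n_native=6,
                      timeline_span=(1900, 1980))

    def digest(outdir: Path) -> dict:
        return {p.relative_to(outdir).as_posix():
                hashlib.sha256(p.read_bytes()).hexdigest()
                for p in sorted(outdir.rglob("*")) if p.is_file()}

    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            run_pipeline(RunConfig(outdir=f"{tmp}/a", seed=seed,
                                   sim=SimConfig(**sim_kwargs)))
            run_pipeline(RunConfig(outdir=f"{tmp}/b", seed=seed,
                                   sim=SimConfig(**sim_kwargs)))
        return digest(Path(tmp) / "a") == digest(Path(tmp) / "b")
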