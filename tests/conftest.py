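"""Shared fixtures: a hand-traced six-species introduction timeline and a
small synthetic study."""

import numpy as np
import pandas as pd
import pytest

from ecofit import similarity, ingest
from ecofit.simulate import SimConfig


def _intro_row(species, family, native=False, game=False, years=(),
               ext=np.nan, established=False, single=False):
    years = frozenset(years)
    return {
        "species": species, "family": family, "native": native,
        "game_bird": game, "introduction_years": years,
        "first_introduction_year": float(min(years)) if years else np.nan,
        "extirpation_year": ext, "established": established,
        "single_individual": single,
    }


@pytest.fixture(scope="session")
def toy_history():
    """Six species: two natives plus four introductions with hand-computable
    incumbent sets and PS features.

    Timeline: A introduced 1900 (established, two introduction years);
    B 1905 (failed, extirpated 1910, single individual); C and D both 1910
    (C failed and extirpated 1912, game bird; D established). The C/D tie
    exercises the same-year inclusion rule, and B's extirpation in C's and
    D's introduction year exercises the boundary convention.
    """
    intro = pd.DataFrame([
        _intro_row("N1", "FamN", native=True, established=True),
        _intro_row("N2", "FamN", native=True, established=True),
        _intro_row("A", "Fam1", years=(1900, 1905), established=True),
        _intro_row("B", "Fam2", years=(1905,), ext=1910.0, single=True),
        _intro_row("C", "Fam3", years=(1910,), ext=1912.0, game=True),
        _intro_row("D", "Fam1", years=(1910,), established=True),
    ])
    diet = {  # three diet categories, percents
        "N1": (100, 0, 0), "N2": (0, 100, 0), "A": (50, 50, 0),
        "B": (0, 0, 100), "C": (25, 25, 50), "D": (60, 20, 20),
    }
    strata = {  # two foraging strata
        "N1": (50, 50), "N2": (100, 0), "A": (0, 100),
        "B": (50, 50), "C": (80, 20), "D": (30, 70),
    }
    rows = []
    for sp, v in diet.items():
        rows += [(sp, "diet", f"c{i+1}", p, "A") for i, p in enumerate(v)]
    for sp, v in strata.items():
        rows += [(sp, "foraging_stratum", f"s{i+1}", p, "A")
                 for i, p in enumerate(v)]
    profiles = pd.DataFrame(rows, columns=list(ingest.PROFILE_COLUMNS))
    ps_tables = {
        kind: similarity.pairwise_ps(ingest.profile_matrix(profiles, kind),
                                     kind=kind)
        for kind in ("diet", "foraging_stratum")
    }
    # hand-computed expectations: species -> (richness, n_years, psd, psf)
    expected = {
        "inclusive": {
            "A": (2, 2, 0.5, 0.25),
            "B": (3, 1, 0.0, 2.0 / 3.0),
            "C": (5, 1, 0.43, 0.58),
            "D": (5, 1, 0.47, 0.62),
        },
        "strict": {
            "A": (2, 2, 0.5, 0.25),
            "B": (3, 1, 0.0, 2.0 / 3.0),
            "C": (4, 1, 0.4125, 0.55),
            "D": (4, 1, 0.5375, 0.575),
        },
    }
    return {"intro": intro, "profiles": profiles, "ps_tables": ps_tables,
            "expected": expected}


@pytest.fixture(scope="session")
def small_sim():
    """A reduced synthetic study shared by read-only tests."""
    from ecofit import simulate, morphometrics
    cfg = SimConfig(seed=11, n_individuals_per_species_site=8,
                    n_obs_per_species_site=15, n_introduced=40, n_native=5,
                    timeline_span=(1900, 1980))
    morpho = simulate.simulate_morphology(cfg)
    ratios = morphometrics.compute_ratios(morpho)
    events = simulate.simulate_observations(cfg, ratios)
    intro, profiles, truth = simulate.simulate_invasion_history(cfg)
    return {"cfg": cfg, "morpho": morpho, "ratios": ratios, "events": events,
            "intro": intro, "profiles": profiles, "truth": truth}
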