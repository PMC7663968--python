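"""Time-resolved incumbent-community reconstruction and the establishment
feature table.

The incumbent community at an introduction year Y is every species that is
native or was first introduced in or before Y and had not yet been
extirpated. The extirpation boundary is inclusive by default: a species
whose last report (extirpation year) is Y is still counted as present for
introductions in year Y, because "last reported in Y" implies presence
during Y. The strict alternative (extirpated species absent from year Y on)
is selectable and pinned by a regression test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .similarity import mean_ps_to_set, ps_lookup


def incumbent_community(records: pd.DataFrame, year,
                        focal=None, boundary: str = "inclusive") -> set:
    """Species present on the island in ``year``, excluding ``focal``.

    Parameters
    ----------
    records
        Introduction table (see :mod:`ecofit.ingest`): needs ``species``,
        ``native``, ``first_introduction_year``, ``extirpation_year``.
    boundary
        ``"inclusive"`` — a species with extirpation_year == year is still
        incumbent; ``"strict"`` — it is not.
    """
    if boundary not in ("inclusive", "strict"):
        raise ValueError(f"unknown extirpation boundary {boundary!r}")
    present = records["native"] | (records["first_introduction_year"] <= year)
    ext = records["extirpation_year"]
    if boundary == "inclusive":
        gone = ext.notna() & (ext < year)
    else:
        gone = ext.notna() & (ext <= year)
    out = set(records.loc[present & ~gone, "species"])
    out.discard(focal)
    return out


def build_features(records: pd.DataFrame,
                   ps_tables: dict[str, pd.DataFrame],
                   boundary: str = "inclusive",
                   count_unprofiled_richness: bool = True) -> pd.DataFrame:
    """One feature row per non-native introduction.

    ``ps_tables`` maps profile kind (``"diet"``, ``"foraging_stratum"``) to
    a pairwise-PS table from :func:`ecofit.similarity.pairwise_ps`. Species
    lacking a niche profile never enter PS averages but, by default, still
    count toward incumbent richness. A focal species facing an empty
    incumbent set gets NaN PS features and ``excluded_empty_incumbents``
    set — the row is emitted, exclusion happens downstream.
    """
    profiled = {
        kind: set(tab["species_a"]) | set(tab["species_b"])
        for kind, tab in ps_tables.items()
    }
    luts = {kind: ps_lookup(tab) for kind, tab in ps_tables.items()}
    rows = []
    intro = records[~records["native"]]
    for rec in intro.itertuples(index=False):
        year = rec.first_introduction_year
        if pd.isna(year):
            continue
        inc = incumbent_community(records, year, focal=rec.species,
                                  boundary=boundary)
        if count_unprofiled_richness:
            richness = len(inc)
        else:
            any_prof = set().union(*profiled.values()) if profiled else set()
            richness = len(inc & any_prof)
        feats = {}
        for kind in ps_tables:
            comp = inc & profiled[kind]
            if comp and rec.species in profiled[kind]:
                feats[kind] = mean_ps_to_set(rec.species, comp, luts[kind])
            else:
                feats[kind] = np.nan
        rows.append({
            "species": rec.species,
            "family": rec.family,
            "intro_year": int(year),
            "incumbent_richness": richness,
            "n_introduction_years": len(rec.introduction_years),
            "mean_ps_diet": feats.get("diet", np.nan),
            "mean_ps_for": feats.get("foraging_stratum", np.nan),
            "established": bool(rec.established),
            "game_bird": bool(rec.game_bird),
            "single_individual": bool(rec.single_individual),
            "excluded_empty_incumbents": len(inc) == 0,
        })
    return pd.DataFrame(rows)


def apply_exclusions(features: pd.DataFrame, mode: str = "all",
                     drop_single_individual: bool = True) -> pd.DataFrame:
    """Row filters ahead of the establishment model.

    ``mode="all"`` keeps every introduction; ``mode="no_gamebirds"`` also
    drops flagged game-bird species (introduced for hunting, whose success
    reflects stocking effort rather than ecology). Single-individual
    introductions are dropped in both modes by default. Rows flagged for an
    empty incumbent set are always dropped.
    """
    if mode not in ("all", "no_gamebirds"):
        raise ValueError(f"unknown exclusion mode {mode!r}")
    keep = ~features["excluded_empty_incumbents"]
    if drop_single_individual:
        keep &= ~features["single_individual"]
    if mode == "no_gamebirds":
        keep &= ~features["game_bird"]
    out = features[keep].reset_index(drop=True)
    if out.empty:
        raise ValueError("exclusions removed every introduction record")
    return out


def timeline_audit(records: pd.DataFrame, boundary: str = "inclusive") -> pd.DataFrame:
    """Per focal introduction: the sorted incumbent species list (for
    manual verification of the reconstruction)."""
    rows = []
    for rec in records[~records["native"]].itertuples(index=False):
        if pd.isna(rec.first_introduction_year):
            continue
        inc = incumbent_community(records, rec.first_introduction_year,
                                  focal=rec.species, boundary=boundary)
        rows.append({"species": rec.species,
                     "intro_year": int(rec.first_introduction_year),
                     "incumbents": ";".join(sorted(inc))})
    return pd.DataFrame(rows)
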