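"""Foraging-observation variables: relative heights, behavior frequency
distributions, and per-event binary response vectors.

Each observation event can carry several simultaneous presence/absence
flags (a bird may glean and eat fruit within one observation), so the
behavior frequency distribution offers two normalisations:

* ``"occurrence"`` (default) — frequency of behavior b = flagged
  occurrences of b / total flag occurrences, which always yields a proper
  distribution suitable for the proportional-similarity index;
* ``"event"`` — per-event fractions (rows may sum to more than 1; kept for
  sensitivity analyses, not used by the PS path).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

FORAGING_BEHAVIORS = ("gleaning", "flycatching", "nectarivory", "frugivory")
MOVEMENTS = ("hop", "walk", "flight", "hanging")
LOCATIONS = ("interior", "periphery", "ground")

#: responses modelled downstream: behaviors, movements and location indicators
RESPONSES = FORAGING_BEHAVIORS + MOVEMENTS + ("in_interior", "in_periphery",
                                              "on_ground")


def relative_heights(events: pd.DataFrame) -> pd.DataFrame:
    """Observed heights divided by the mean canopy height of the point.

    Values above 1 are legitimate (emergent trees). Events with a missing
    or non-positive canopy height are excluded with a warning.
    """
    ok = events["canopy_height_mean"].notna() & (events["canopy_height_mean"] > 0)
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} events dropped: missing/invalid canopy height",
            stacklevel=2,
        )
    df = events[ok]
    out = df[["species", "site"]].copy()
    out["rel_max_height"] = df["max_height"] / df["canopy_height_mean"]
    out["rel_min_height"] = df["min_height"] / df["canopy_height_mean"]
    return out.reset_index(drop=True)


def behavior_distribution(events: pd.DataFrame,
                          pooling: str = "species_site",
                          normalization: str = "occurrence") -> pd.DataFrame:
    """Relative frequency distribution of foraging behaviors per group.

    Groups are species x site (default) or species pooled across sites.
    Only events with at least one foraging flag contribute; a group with
    zero foraging events is excluded with a warning (it has no defined
    distribution and cannot enter a PS comparison).
    """
    if pooling == "species_site":
        keys = ["species", "site"]
    elif pooling == "species":
        keys = ["species"]
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    if normalization not in ("occurrence", "event"):
        raise ValueError(f"unknown normalization {normalization!r}")

    flags = events[list(FORAGING_BEHAVIORS)].astype(int)
    foraging = flags.sum(axis=1) > 0
    df = pd.concat([events[keys], flags], axis=1)[foraging]

    silent = (events[keys].drop_duplicates().merge(
        df[keys].drop_duplicates(), how="left", on=keys, indicator=True))
    silent = silent[silent["_merge"] == "left_only"][keys]
    if len(silent):
        warnings.warn(
            "groups with no foraging events excluded from behavior "
            f"distributions: {[tuple(r) for r in silent.to_numpy()]}",
            stacklevel=2,
        )

    grp = df.groupby(keys, sort=True)
    counts = grp[list(FORAGING_BEHAVIORS)].sum()
    n_events = grp.size().rename("n_events")
    if normalization == "occurrence":
        freqs = counts.div(counts.sum(axis=1), axis=0)
    else:
        freqs = counts.div(n_events, axis=0)
    out = freqs.join(n_events).reset_index()
    if pooling == "species":
        out.insert(1, "site", "pooled")
    return out


def distribution_matrix(dist: pd.DataFrame, site=None) -> pd.DataFrame:
    """Wide species-by-behavior matrix from a behavior_distribution table."""
    df = dist if site is None else dist[dist["site"] == site]
    return df.set_index("species")[list(FORAGING_BEHAVIORS)]


def response_vectors(events: pd.DataFrame,
                     responses=RESPONSES) -> dict[str, pd.DataFrame]:
    """Per-event 0/1 response tables for each modelled behavior.

    Returns a mapping response name -> DataFrame(species, site, y). The
    three location indicators are mutually exclusive recodings of the
    ``location`` field; events with location ``unknown`` are dropped from
    those three responses only.
    """
    if events.empty:
        raise ValueError("no observation events: cannot build responses")
    out: dict[str, pd.DataFrame] = {}
    loc_map = {"in_interior": "interior", "in_periphery": "periphery",
               "on_ground": "ground"}
    for name in responses:
        if name in loc_map:
            known = events["location"].isin(LOCATIONS)
            df = events[known]
            y = (df["location"] == loc_map[name]).astype(int)
        else:
            df = events
            y = events[name].astype(int)
        out[name] = pd.DataFrame({
            "species": df["species"].to_numpy(),
            "site": df["site"].to_numpy(),
            "y": y.to_numpy(),
        })
    return out
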