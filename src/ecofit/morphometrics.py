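"""Morphological ratios, the individual-level PCA morphospace, and
species-centroid Euclidean distances.

Three bespoke ratios summarise bird external morphology:

* ``tarsus_to_wing`` — tarsus length / wing length (hopping/understory vs
  flight-based foraging).
* ``horizontal_bill_aspect`` — culmen length / bill width at the nares.
* ``bill_slenderness`` — culmen length / bill cross-sectional area at the
  nares (1/mm); larger values mean a longer, thinner bill. The cross
  section is approximated as an ellipse with the measured width and depth
  as axes (a rectangular width*depth approximation is selectable; only the
  relative ordering across species matters for the downstream models).

Ratios are computed per individual and then averaged per species x site;
juveniles are excluded throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

#: the five linear measurements (mm); mass (g) is carried separately
TRAITS = ("wing_length", "tarsus_length", "culmen_length",
          "bill_width_nares", "bill_depth_nares")


def bill_cross_section(width: np.ndarray, depth: np.ndarray,
                       formula: str = "ellipse") -> np.ndarray:
    """Bill cross-sectional area at the nares, mm^2."""
    width = np.asarray(width, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if formula == "ellipse":
        return math.pi * (width / 2.0) * (depth / 2.0)
    if formula == "rectangle":
        return width * depth
    raise ValueError(f"unknown area formula {formula!r}")


def individual_ratios(records: pd.DataFrame,
                      area_formula: str = "ellipse") -> pd.DataFrame:
    """Per-individual ratio table (adults only)."""
    df = records.copy()
    if "age_class" in df.columns:
        df = df[df["age_class"] != "juvenile"]
    out = df[["species", "site"]].copy()
    out["tarsus_to_wing"] = df["tarsus_length"] / df["wing_length"]
    out["horizontal_bill_aspect"] = df["culmen_length"] / df["bill_width_nares"]
    area = bill_cross_section(df["bill_width_nares"], df["bill_depth_nares"],
                              area_formula)
    out["bill_slenderness"] = df["culmen_length"] / area
    out["mass"] = df.get("mass")
    return out


def compute_ratios(records: pd.DataFrame,
                   area_formula: str = "ellipse") -> pd.DataFrame:
    """Site-averaged morphological ratios per species.

    Ratios are formed per individual first and the individual ratios are
    then averaged within each species x site cell (mean of ratios, not
    ratio of means). Cells with no adult individuals are omitted with a
    warning. Returns columns ``species, site, tarsus_to_wing,
    horizontal_bill_aspect, bill_slenderness, mass_mean, n_individuals``.
    """
    indiv = individual_ratios(records, area_formula=area_formula)
    indiv = indiv.dropna(subset=["tarsus_to_wing", "horizontal_bill_aspect",
                                 "bill_slenderness"])
    if indiv.empty:
        raise ValueError("no adult individuals with complete measurements")
    all_cells = {(s, t) for s, t in zip(records["species"], records["site"])}
    grp = indiv.groupby(["species", "site"], sort=True)
    out = grp.agg(
        tarsus_to_wing=("tarsus_to_wing", "mean"),
        horizontal_bill_aspect=("horizontal_bill_aspect", "mean"),
        bill_slenderness=("bill_slenderness", "mean"),
        mass_mean=("mass", "mean"),
        n_individuals=("tarsus_to_wing", "size"),
    ).reset_index()
    missing = all_cells - {(s, t) for s, t in zip(out["species"], out["site"])}
    if missing:
        warnings.warn(
            f"species x site cells with no usable adults omitted: {sorted(missing)}",
            stacklevel=2,
        )
    return out


@dataclass
class MorphospaceResult:
    """Individual-level PCA of the raw measurements."""

    scores: pd.DataFrame          # species, site + PC1..PCk per individual
    loadings: pd.DataFrame        # traits x components
    explained_variance_ratio: np.ndarray
    traits: tuple = field(default=TRAITS)
    standardized: bool = False

    @property
    def n_components(self) -> int:
        return len(self.explained_variance_ratio)


def pca_morphospace(records: pd.DataFrame,
                    traits=TRAITS,
                    standardize: bool = False,
                    include_mass: bool = False) -> MorphospaceResult:
    """PCA over individuals on the raw measurements.

    The measurements are centered but, by default, not rescaled ("raw"
    morphospace); set ``standardize=True`` for a correlation-matrix PCA.
    Mass is excluded by default (it is modelled separately from the five
    linear measurements); ``include_mass=True`` appends it. Constant trait
    columns are dropped with a warning. All components are retained.
    """
    use = list(traits) + (["mass"] if include_mass else [])
    df = records.copy()
    if "age_class" in df.columns:
        df = df[df["age_class"] != "juvenile"]
    df = df.dropna(subset=use)
    if len(df) < 2:
        raise ValueError("PCA needs at least two complete individuals")
    X = df[use].to_numpy(dtype=float)
    keep = X.std(axis=0) > 0
    if not keep.all():
        dropped = [t for t, k in zip(use, keep) if not k]
        warnings.warn(f"constant trait columns dropped from PCA: {dropped}",
                      stacklevel=2)
        use = [t for t, k in zip(use, keep) if k]
        X = X[:, keep]
    if standardize:
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    score_df = df[["species", "site"]].reset_index(drop=True)
    if "individual_id" in df.columns:
        score_df.insert(0, "individual_id", df["individual_id"].to_numpy())
    score_df = pd.concat([score_df, pd.DataFrame(scores, columns=cols)], axis=1)
    loadings = pd.DataFrame(pca.components_.T, index=use, columns=cols)
    return MorphospaceResult(scores=score_df, loadings=loadings,
                             explained_variance_ratio=pca.explained_variance_ratio_,
                             traits=tuple(use), standardized=standardize)


def centroid_distances(scores: pd.DataFrame, per_site: bool = True) -> pd.DataFrame:
    """Euclidean distances between species centroids in the morphospace.

    Centroids are the per-group means of the PCA scores; with
    ``per_site=True`` (default) groups are species x site and distances are
    taken between species within each site, otherwise species are pooled
    across sites and the ``site`` column is the sentinel ``"pooled"``.
    A site holding a single species simply yields no pairs.
    """
    pc_cols = [c for c in scores.columns if c.startswith("PC")]
    if not pc_cols:
        raise ValueError("no PC columns in scores table")
    keys = ["species", "site"] if per_site else ["species"]
    cent = scores.groupby(keys, sort=True)[pc_cols].mean().reset_index()
    rows = []
    if per_site:
        site_iter = [(s, g) for s, g in cent.groupby("site", sort=True)]
    else:
        site_iter = [("pooled", cent)]
    for site, g in site_iter:
        sp = g["species"].to_numpy()
        M = g[pc_cols].to_numpy()
        for i in range(len(sp)):
            for j in range(i + 1, len(sp)):
                d = float(np.linalg.norm(M[i] - M[j]))
                rows.append((sp[i], sp[j], site, d))
    return pd.DataFrame(rows, columns=["species_a", "species_b", "site",
                                       "euclidean_distance"])
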