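"""Ratios, PCA morphospace, and centroid distances."""

import math

import numpy as np
import pandas as pd
import pytest

from ecofit.morphometrics import (centroid_distances, compute_ratios,
                                  individual_ratios, pca_morphospace)


def _records(rows):
    cols = ["species", "site", "individual_id", "wing_length", "tarsus_length",
            "culmen_length", "bill_width_nares", "bill_depth_nares", "mass",
            "age_class"]
    return pd.DataFrame(rows, columns=cols)


ONE_BIRD = _records([("sp", "s1", "i1", 20.0, 20.0, 10.0, 4.0, 4.0, 15.0,
                      "adult")])


def test_ratio_hand_examples():
    out = compute_ratios(ONE_BIRD)
    row = out.iloc[0]
    assert row["tarsus_to_wing"] == pytest.approx(1.0)
    assert row["horizontal_bill_aspect"] == pytest.approx(2.5)
    # elliptical cross-section: pi * 2 * 2 mm^2
    assert row["bill_slenderness"] == pytest.approx(10.0 / (math.pi * 4.0),
                                                    abs=1e-9)
    rect = compute_ratios(ONE_BIRD, area_formula="rectangle").iloc[0]
    assert rect["bill_slenderness"] == pytest.approx(10.0 / 16.0)
    with pytest.raises(ValueError):
        compute_ratios(ONE_BIRD, area_formula="cylinder")


def test_aspect_ratio_scale_invariance():
    base = individual_ratios(ONE_BIRD).iloc[0]["horizontal_bill_aspect"]
    scaled = ONE_BIRD.copy()
    scaled[["culmen_length", "bill_width_nares"]] *= 3.7
    assert individual_ratios(scaled).iloc[0]["horizontal_bill_aspect"] == \
        pytest.approx(base, rel=1e-12)


def test_mean_of_ratios_not_ratio_of_means():
    """Averaging order is pinned: ratios per individual, then averaged."""
    rec = _records([
        ("sp", "s1", "i1", 20.0, 10.0, 10.0, 4.0, 4.0, 10.0, "adult"),
        ("sp", "s1", "i2", 30.0, 30.0, 10.0, 4.0, 4.0, 10.0, "adult"),
    ])
    out = compute_ratios(rec)
    # mean(0.5, 1.0) = 0.75; the ratio of means would be 40/50 = 0.8
    assert out.iloc[0]["tarsus_to_wing"] == pytest.approx(0.75)
    assert out.iloc[0]["n_individuals"] == 2


def test_juveniles_excluded_and_empty_cells_warn():
    rec = _records([
        ("sp", "s1", "i1", 20.0, 10.0, 10.0, 4.0, 4.0, 10.0, "adult"),
        ("sp", "s1", "i2", 20.0, 30.0, 10.0, 4.0, 4.0, 10.0, "juvenile"),
        ("sp", "s2", "i3", 20.0, 30.0, 10.0, 4.0, 4.0, 10.0, "juvenile"),
    ])
    with pytest.warns(UserWarning, match="no usable adults"):
        out = compute_ratios(rec)
    assert list(out["site"]) == ["s1"]
    assert out.iloc[0]["tarsus_to_wing"] == pytest.approx(0.5)


def _iso_records(n, rng, species="sp", site="s1"):
    X = rng.normal(size=(n, 5))
    df = pd.DataFrame(X + 20.0, columns=["wing_length", "tarsus_length",
                                         "culmen_length", "bill_width_nares",
                                         "bill_depth_nares"])
    df.insert(0, "species", species)
    df.insert(1, "site", site)
    df["mass"] = 10.0
    df["age_class"] = "adult"
    return df


def test_pca_rank_one_structure():
    rng = np.random.default_rng(0)
    df = _iso_records(100, rng)
    z = rng.normal(size=100)
    for c in ["wing_length", "tarsus_length", "culmen_length",
              "bill_width_nares", "bill_depth_nares"]:
        df[c] = 20.0 + z  # all traits perfectly correlated
    res = pca_morphospace(df)
    assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)


def test_pca_isotropic_variance_split():
    rng = np.random.default_rng(1)
    res = pca_morphospace(_iso_records(4000, rng))
    assert np.all(np.abs(res.explained_variance_ratio - 0.2) < 0.03)


def test_pca_duplicates_and_constant_column():
    rng = np.random.default_rng(2)
    df = _iso_records(30, rng)
    dup = pd.concat([df, df.iloc[[0]]], ignore_index=True)
    res = pca_morphospace(dup)
    pcs = res.scores.filter(like="PC").to_numpy()
    assert np.allclose(pcs[0], pcs[-1])
    df["wing_length"] = 25.0
    with pytest.warns(UserWarning, match="constant trait"):
        res2 = pca_morphospace(df)
    assert "wing_length" not in res2.loadings.index


def test_centroid_distance_examples():
    scores = pd.DataFrame({
        "species": ["a", "a", "b", "b", "c"],
        "site": ["s1"] * 5,
        "PC1": [0.0, 0.0, 3.0, 3.0, 0.0],
        "PC2": [0.0, 0.0, 4.0, 4.0, 0.0],
    })
    out = centroid_distances(scores)
    lut = {(r.species_a, r.species_b): r.euclidean_distance
           for r in out.itertuples()}
    assert lut[("a", "b")] == pytest.approx(5.0)   # 3-4-5 triangle
    assert lut[("a", "c")] == pytest.approx(0.0)   # identical centroids
    # single-species site yields no pairs, not an error
    lone = scores.assign(site="s2").iloc[:2]
    assert centroid_distances(lone).empty


def test_centroid_distances_match_brute_force():
    rng = np.random.default_rng(7)
    scores = pd.DataFrame({
        "species": rng.choice(list("abcde"), size=60),
        "site": rng.choice(["s1", "s2"], size=60),
        "PC1": rng.normal(size=60), "PC2": rng.normal(size=60),
        "PC3": rng.normal(size=60),
    })
    out = centroid_distances(scores)
    for r in out.itertuples():
        ca = scores[(scores.species == r.species_a) & (scores.site == r.site)][
            ["PC1", "PC2", "PC3"]].mean()
        cb = scores[(scores.species == r.species_b) & (scores.site == r.site)][
            ["PC1", "PC2", "PC3"]].mean()
        assert r.euclidean_distance == pytest.approx(
            float(np.sqrt(((ca - cb) ** 2).sum())), abs=1e-12)


def test_full_pca_distance_equals_raw_centered_distance():
    """With every component retained, PCA is a rotation: centroid distances
    equal those computed on the centered raw measurements."""
    rng = np.random.default_rng(4)
    df = pd.concat([_iso_records(40, rng, species=s) for s in "abc"],
                   ignore_index=True)
    res = pca_morphospace(df)
    pca_d = centroid_distances(res.scores)
    traits = list(res.traits)
    X = df[traits] - df[traits].mean()
    raw = pd.concat([df[["species", "site"]], X], axis=1)
    raw_cent = raw.groupby(["species", "site"])[traits].mean()
    for r in pca_d.itertuples():
        d_raw = float(np.linalg.norm(
            raw_cent.loc[(r.species_a, r.site)] -
            raw_cent.loc[(r.species_b, r.site)]))
        assert r.euclidean_distance == pytest.approx(d_raw, abs=1e-8)
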