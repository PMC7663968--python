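"""Proportional similarity (PS) between resource-use distributions.

PS(p, q) = sum_i min(p_i, q_i) over a shared, ordered category set. It equals
1 for identical distributions and 0 for distributions with disjoint support,
and is related to the L1 (total variation) distance by
``PS = 1 - 0.5 * sum_i |p_i - q_i|``.

Profiles may be supplied as proportions (summing to 1) or as percentages
(summing to 100, the EltonTraits convention); percentages are detected and
rescaled before any comparison.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

#: absolute tolerance on "sums to one" after percent conversion
NORMALIZATION_TOL = 1e-6


def _as_distribution(values, name: str = "distribution") -> np.ndarray:
    """Coerce to a 1-D probability vector; accepts percent inputs (sum ~100)."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} has negative or non-finite entries")
    total = arr.sum()
    if abs(total - 100.0) <= 0.5:  # EltonTraits-style integer percentages
        arr = arr / 100.0
        total = arr.sum()
    if abs(total - 1.0) > max(NORMALIZATION_TOL, 0.005):
        raise ValueError(
            f"{name} does not sum to 1 (or 100): total={total!r}"
        )
    # remove the residual rounding so downstream identities hold exactly
    return arr / total


def proportional_similarity(p, q, categories_p=None, categories_q=None) -> float:
    """PS = sum_i min(p_i, q_i) for two distributions over identical categories.

    Parameters
    ----------
    p, q
        Distributions (proportions or percentages) over the same ordered
        category set.
    categories_p, categories_q
        Optional category labels; if both given they must match exactly
        (same labels, same order), otherwise an error names the offenders.
    """
    if categories_p is not None and categories_q is not None:
        cp, cq = list(categories_p), list(categories_q)
        if cp != cq:
            extra = sorted(set(cp) ^ set(cq))
            raise ValueError(
                "category sets differ between the two profiles: "
                f"mismatched labels {extra or cp}"
            )
    pv = _as_distribution(p, "p")
    qv = _as_distribution(q, "q")
    if pv.shape != qv.shape:
        raise ValueError(
            f"profiles have different lengths: {pv.size} vs {qv.size}"
        )
    if np.array_equal(pv, qv):
        return 1.0
    return float(np.minimum(pv, qv).sum())


def pairwise_ps(profiles: pd.DataFrame, kind: str | None = None) -> pd.DataFrame:
    """All unordered species pairs' PS from a wide profile matrix.

    Parameters
    ----------
    profiles
        Wide matrix, index = species, columns = ordered categories; rows may
        be proportions or percentages. Requires >= 2 rows.
    kind
        Optional label copied into the output's ``kind`` column
        (e.g. ``"diet"``, ``"foraging_stratum"``, ``"behavior"``).

    Returns
    -------
    DataFrame with columns ``species_a, species_b, ps`` (plus ``kind``),
    one row per unordered pair, self-pairs omitted.
    """
    if profiles.shape[0] < 2:
        raise ValueError("need at least two profiles for pairwise PS")
    mat = np.vstack([
        _as_distribution(profiles.loc[sp].to_numpy(), f"profile[{sp}]")
        for sp in profiles.index
    ])
    species = list(profiles.index)
    ps_mat = np.minimum(mat[:, None, :], mat[None, :, :]).sum(axis=2)
    rows = []
    for i, j in itertools.combinations(range(len(species)), 2):
        rows.append((species[i], species[j], float(ps_mat[i, j])))
    out = pd.DataFrame(rows, columns=["species_a", "species_b", "ps"])
    if kind is not None:
        out["kind"] = kind
    return out


def ps_lookup(pairs: pd.DataFrame) -> dict:
    """Symmetric ``(a, b) -> ps`` lookup from a pairwise table (build once
    when averaging against many incumbent sets)."""
    lut: dict[tuple, float] = {}
    for a, b, v in zip(pairs["species_a"], pairs["species_b"], pairs["ps"]):
        lut[(a, b)] = v
        lut[(b, a)] = v
    return lut


def mean_ps_to_set(focal, others, pairs) -> float:
    """Arithmetic mean PS between ``focal`` and every species in ``others``.

    ``pairs`` is a pairwise table or a prebuilt :func:`ps_lookup` dict.
    ``others`` is iterated in sorted order so the floating-point sum is
    reproducible across call sites. The focal species never contributes to
    its own average; an empty incumbent set is an error (callers flag the
    row instead of averaging over nothing).
    """
    others = sorted(set(others) - {focal})
    if not others:
        raise ValueError(f"empty comparison set for species {focal!r}")
    lut = pairs if isinstance(pairs, dict) else ps_lookup(pairs)
    vals = []
    for sp in others:
        try:
            vals.append(lut[(focal, sp)])
        except KeyError:
            raise KeyError(f"no PS entry for pair ({focal!r}, {sp!r})") from None
    return float(np.mean(vals))
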