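"""Read, validate and write the four canonical input tables.

All tables are UTF-8 delimited text (comma by default, tab accepted). The
schemas:

``morphology``
    species, site, individual_id, wing_length, tarsus_length,
    culmen_length, bill_width_nares, bill_depth_nares, mass, age_class
``observations``
    species, site, point_id, max_height, min_height, canopy_height_mean,
    location, gleaning, flycatching, nectarivory, frugivory, hop, walk,
    flight, hanging, interaction_score, flock_size
``niche_profiles`` (long format)
    species, profile_kind, category, percent, certainty
``introductions``
    species, family, native, game_bird, introduction_years
    (semicolon-separated calendar years), extirpation_year, established,
    single_individual

Validation is row-level: invariant breaches are collected into a
:class:`ValidationReport` with line numbers; in strict mode (default) any
breach raises, in lenient mode offending rows are dropped and the report
is attached as ``df.attrs["validation"]``. A missing mandatory column is
always a hard schema error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MORPHO_COLUMNS = ("species", "site", "individual_id", "wing_length",
                  "tarsus_length", "culmen_length", "bill_width_nares",
                  "bill_depth_nares", "mass", "age_class")
OBS_FLAGS = ("gleaning", "flycatching", "nectarivory", "frugivory",
             "hop", "walk", "flight", "hanging")
OBS_COLUMNS = ("species", "site", "point_id", "max_height", "min_height",
               "canopy_height_mean", "location") + OBS_FLAGS + (
               "interaction_score", "flock_size")
PROFILE_COLUMNS = ("species", "profile_kind", "category", "percent", "certainty")
INTRO_COLUMNS = ("species", "family", "native", "game_bird",
                 "introduction_years", "extirpation_year", "established",
                 "single_individual")

MEASUREMENTS = ("wing_length", "tarsus_length", "culmen_length",
                "bill_width_nares", "bill_depth_nares", "mass")
AGE_CLASSES = ("adult", "juvenile", "unknown")
CERTAINTY_GRADES = ("A", "B", "C", "D1", "D2", "unknown")
PROFILE_SUM_TOL = 0.5


class SchemaError(ValueError):
    """Mandatory column missing or table unreadable."""


@dataclass
class ValidationReport:
    errors: list[tuple[int, str]] = field(default_factory=list)

    def add(self, line: int, message: str) -> None:
        self.errors.append((line, message))

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_if_failed(self) -> None:
        if self.errors:
            shown = "; ".join(f"line {ln}: {msg}" for ln, msg in self.errors[:10])
            more = "" if len(self.errors) <= 10 else f" (+{len(self.errors) - 10} more)"
            raise ValueError(f"validation failed: {shown}{more}")


def _read(path, columns, delimiter=None) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=delimiter, engine="python")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed file
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    return df


def _finish(df, bad_rows, report, strict):
    report_sorted = ValidationReport(sorted(report.errors))
    if strict:
        report_sorted.raise_if_failed()
    out = df[~df.index.isin(bad_rows)].reset_index(drop=True)
    out.attrs["validation"] = report_sorted
    return out


def read_morphology(path, strict: bool = True, delimiter=None) -> pd.DataFrame:
    df = _read(path, MORPHO_COLUMNS, delimiter)
    report, bad = ValidationReport(), set()
    for col in MEASUREMENTS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
        nonpos = df.index[df[col].notna() & (df[col] <= 0)]
        for i in nonpos:
            report.add(i + 2, f"non-positive {col} for {df.at[i, 'species']}")
            bad.add(i)
    df["age_class"] = df["age_class"].fillna("unknown")
    for i in df.index[~df["age_class"].isin(AGE_CLASSES)]:
        report.add(i + 2, f"unknown age_class {df.at[i, 'age_class']!r}")
        bad.add(i)
    return _finish(df, bad, report, strict)


def read_observations(path, strict: bool = True, delimiter=None) -> pd.DataFrame:
    df = _read(path, OBS_COLUMNS, delimiter)
    report, bad = ValidationReport(), set()
    for col in ("max_height", "min_height", "canopy_height_mean"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in OBS_FLAGS:
        df[col] = df[col].astype(float).astype(bool)
    swapped = df.index[df["min_height"] > df["max_height"]]
    for i in swapped:
        report.add(i + 2, "min_height exceeds max_height")
        bad.add(i)
    for i in df.index[df["canopy_height_mean"].notna()
                      & (df["canopy_height_mean"] <= 0)]:
        report.add(i + 2, "non-positive canopy_height_mean")
        bad.add(i)
    score = pd.to_numeric(df["interaction_score"], errors="coerce")
    for i in df.index[~score.isin([0, 1, 2, 3, 4])]:
        report.add(i + 2, f"interaction_score {df.at[i, 'interaction_score']!r} not in 0..4")
        bad.add(i)
    df["interaction_score"] = score
    flock = pd.to_numeric(df["flock_size"], errors="coerce")
    for i in df.index[flock.isna() | (flock < 1)]:
        report.add(i + 2, "flock_size must be a count >= 1")
        bad.add(i)
    df["flock_size"] = flock
    df["location"] = df["location"].fillna("unknown")
    return _finish(df, bad, report, strict)


def read_niche_profiles(path, strict: bool = True, delimiter=None,
                        min_certainty: str | None = None) -> pd.DataFrame:
    """Long-format profiles; checks per-(species, kind) percent sums and
    consistent category ordering within each profile kind.

    ``min_certainty`` optionally drops species whose grade is worse than
    the given one in the order A < B < C < D1 < D2 (low-certainty species
    are retained by default).
    """
    df = _read(path, PROFILE_COLUMNS, delimiter)
    report, bad = ValidationReport(), set()
    df["percent"] = pd.to_numeric(df["percent"], errors="coerce")
    for i in df.index[df["percent"].isna() | (df["percent"] < 0)]:
        report.add(i + 2, f"bad percent for {df.at[i, 'species']}")
        bad.add(i)
    df["certainty"] = df["certainty"].fillna("unknown")
    for (sp, kind), g in df.groupby(["species", "profile_kind"], sort=True):
        total = g["percent"].sum()
        if abs(total - 100.0) > PROFILE_SUM_TOL:
            report.add(int(g.index[0]) + 2,
                       f"{kind} profile of {sp} sums to {total:g}, not 100")
            bad.update(g.index)
    for kind, g in df.groupby("profile_kind", sort=True):
        orders = {sp: tuple(s["category"]) for sp, s in g.groupby("species", sort=True)}
        ref = next(iter(orders.values()), ())
        for sp, order in orders.items():
            if order != ref:
                report.add(int(g.index[0]) + 2,
                           f"category ordering of {sp} ({kind}) differs from "
                           "other species")
                bad.update(g.index[g["species"] == sp])
    out = _finish(df, bad, report, strict)
    if min_certainty is not None:
        rank = {g: r for r, g in enumerate(CERTAINTY_GRADES)}
        keep = out["certainty"].map(rank).fillna(len(rank)) <= rank[min_certainty]
        out = out[keep].reset_index(drop=True)
    return out


def read_introductions(path, strict: bool = True, delimiter=None) -> pd.DataFrame:
    df = _read(path, INTRO_COLUMNS, delimiter)
    report, bad = ValidationReport(), set()
    for col in ("native", "game_bird", "established", "single_individual"):
        df[col] = df[col].astype(float).astype(bool)
    years = []
    for i, raw in zip(df.index, df["introduction_years"]):
        if pd.isna(raw) or str(raw).strip() == "":
            years.append(frozenset())
            if not df.at[i, "native"]:
                report.add(i + 2, f"non-native {df.at[i, 'species']} lacks "
                                  "introduction years")
                bad.add(i)
            continue
        try:
            ys = frozenset(int(float(y)) for y in str(raw).split(";"))
        except ValueError:
            report.add(i + 2, f"unparsable introduction_years {raw!r}")
            bad.add(i)
            ys = frozenset()
        years.append(ys)
    df["introduction_years"] = years
    df["first_introduction_year"] = [min(y) if y else np.nan for y in years]
    df["extirpation_year"] = pd.to_numeric(df["extirpation_year"], errors="coerce")
    both = df["extirpation_year"].notna() & df["first_introduction_year"].notna()
    for i in df.index[both & (df["extirpation_year"]
                              < df["first_introduction_year"])]:
        report.add(i + 2, f"extirpation precedes introduction for "
                          f"{df.at[i, 'species']}")
        bad.add(i)
    return _finish(df, bad, report, strict)


def profile_matrix(profiles: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Wide species-by-category percent matrix for one profile kind,
    preserving the shared category order."""
    sub = profiles[profiles["profile_kind"] == kind]
    if sub.empty:
        raise ValueError(f"no profiles of kind {kind!r}")
    order = list(dict.fromkeys(sub["category"]))
    wide = sub.pivot(index="species", columns="category", values="percent")
    return wide[order]


# ---------------------------------------------------------------- writers

def write_morphology(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=list(MORPHO_COLUMNS))


def write_observations(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in OBS_FLAGS:
        out[col] = out[col].astype(int)
    out.to_csv(path, index=False, columns=list(OBS_COLUMNS))


def write_niche_profiles(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=list(PROFILE_COLUMNS))


def write_introductions(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["introduction_years"] = [
        ";".join(str(y) for y in sorted(ys)) for ys in out["introduction_years"]
    ]
    for col in ("native", "game_bird", "established", "single_individual"):
        out[col] = out[col].astype(int)
    ext = out["extirpation_year"]
    out["extirpation_year"] = ["" if pd.isna(v) else str(int(v)) for v in ext]
    out.to_csv(path, index=False, columns=list(INTRO_COLUMNS))
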