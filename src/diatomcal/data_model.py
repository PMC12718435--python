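"""Core data containers and preprocessing for community calibration sets.

The analysis operates on three aligned tables: a site x taxon valve-count
matrix, a site x variable environmental table, and (optionally) site
coordinates along the sampled transect.  Preprocessing follows the usual
calibration-set recipe: relative abundances, a rare-taxon cutoff, the
Hellinger transformation of the community matrix, and skewness-guarded
log10(x+1) transformation plus scaling of the environmental variables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

HABITS = ("benthic", "planktonic", "unknown")


class DataError(ValueError):
    """Raised when an input table violates a structural precondition."""


@dataclass
class CountMatrix:
    """Site x taxon valve counts with an optional per-taxon habit label.

    Parameters
    ----------
    counts
        DataFrame indexed by site identifier, columns are taxon codes,
        cells are non-negative integer valve counts.
    habit
        Series mapping taxon code to ``benthic`` / ``planktonic`` /
        ``unknown``.  Defaults to ``unknown`` for every taxon.
    """

    counts: pd.DataFrame
    habit: pd.Series | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates or c.columns.has_duplicates:
            raise DataError("duplicate site or taxon identifiers in count matrix")
        vals = c.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            bad = _first_non_numeric(c)
            raise DataError(f"non-numeric count cell at site {bad[0]!r}, taxon {bad[1]!r}")
        if np.any(vals < 0):
            raise DataError("negative counts")
        totals = vals.sum(axis=1)
        if np.any(totals <= 0):
            empty = list(c.index[totals <= 0])
            raise DataError(f"sites with zero total counts: {empty}")
        if self.habit is None:
            self.habit = pd.Series("unknown", index=c.columns)
        else:
            self.habit = self.habit.reindex(c.columns).fillna("unknown")
            bad_h = set(self.habit) - set(HABITS)
            if bad_h:
                raise DataError(f"unknown habit labels: {sorted(bad_h)}")

    @property
    def sites(self) -> list:
        return list(self.counts.index)

    @property
    def taxa(self) -> list:
        return list(self.counts.columns)

    def subset_habit(self, habit: str) -> "CountMatrix":
        """Restrict to taxa with the given habit label (e.g. ``benthic``)."""
        keep = self.habit[self.habit == habit].index
        if len(keep) == 0:
            raise DataError(f"no taxa with habit {habit!r}")
        return CountMatrix(self.counts[list(keep)], self.habit.loc[list(keep)])


@dataclass
class AbundanceMatrix:
    """Site x taxon proportions, optionally Hellinger-transformed."""

    values: pd.DataFrame
    transform_state: str = "none"  # none | hellinger

    def __post_init__(self) -> None:
        if self.transform_state not in ("none", "hellinger"):
            raise DataError(f"unknown transform_state {self.transform_state!r}")
        if np.any(self.values.to_numpy() < 0):
            raise DataError("negative abundances")

    @property
    def sites(self) -> list:
        return list(self.values.index)

    @property
    def taxa(self) -> list:
        return list(self.values.columns)


@dataclass
class EnvTable:
    """Site x environmental-variable measurements.

    ``transform_log`` records which variables have been log10(x+1)
    transformed; ``scaled`` records whether columns are centred/scaled.
    """

    values: pd.DataFrame
    transform_log: pd.Series | None = None
    scaled: bool = False

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            bad = self.values.columns[~np.isfinite(self.values.to_numpy(dtype=float)).all(axis=0)]
            raise DataError(f"non-finite environmental values in {list(bad)}")
        if self.transform_log is None:
            self.transform_log = pd.Series(False, index=self.values.columns)

    @property
    def sites(self) -> list:
        return list(self.values.index)

    @property
    def variables(self) -> list:
        return list(self.values.columns)


@dataclass
class SiteCoords:
    """Site coordinates: either lon/lat degrees or a linear transect km."""

    values: pd.DataFrame  # columns (lat, lon) or (km)
    crs_mode: str = "linear"  # lonlat | linear

    def __post_init__(self) -> None:
        if self.crs_mode not in ("lonlat", "linear"):
            raise DataError(f"unknown crs_mode {self.crs_mode!r}")
        if self.values.index.has_duplicates:
            raise DataError("duplicate sites in coordinates")
        if self.crs_mode == "lonlat":
            if not {"lat", "lon"} <= set(self.values.columns):
                raise DataError("lonlat coordinates require 'lat' and 'lon' columns")
            if np.any(np.abs(self.values["lat"].to_numpy()) > 90):
                raise DataError("latitude outside [-90, 90]")
        else:
            if "km" not in self.values.columns:
                raise DataError("linear coordinates require a 'km' column")

    @property
    def sites(self) -> list:
        return list(self.values.index)

    def distance_matrix(self) -> np.ndarray:
        """Pairwise site distances in km (haversine for lon/lat)."""
        if self.crs_mode == "linear":
            km = self.values["km"].to_numpy(dtype=float)
            return np.abs(km[:, None] - km[None, :])
        lat = np.radians(self.values["lat"].to_numpy(dtype=float))
        lon = np.radians(self.values["lon"].to_numpy(dtype=float))
        dlat = lat[:, None] - lat[None, :]
        dlon = lon[:, None] - lon[None, :]
        a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
        return 2 * 6371.0 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


@dataclass
class Dataset:
    """Aligned bundle of counts, environment and (optional) coordinates."""

    counts: CountMatrix
    env: EnvTable
    coords: SiteCoords | None = None

    def __post_init__(self) -> None:
        if self.counts.sites != self.env.sites:
            raise DataError("counts and env site orderings differ")
        if self.coords is not None and self.coords.sites != self.counts.sites:
            raise DataError("coords site ordering differs")

    @property
    def sites(self) -> list:
        return self.counts.sites


@dataclass
class RareTaxonReport:
    """Bookkeeping emitted by :func:`rare_taxon_filter`."""

    retained: list
    dropped: list
    min_pct: float
    min_occurrences: int
    fraction_of_valves: float  # share of total proportion mass retained


def _first_non_numeric(df: pd.DataFrame):
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            return df.index[bad][0], col
    return df.index[0], df.columns[0]


def _read_site_csv(path, name: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise DataError(f"{name} file {path} needs a site column plus data columns")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    return df


def load_dataset(count_path, env_path, coords_path=None, taxon_meta_path=None) -> Dataset:
    """Read the counts / environment / coordinates CSV trio into a Dataset.

    Sites are intersected across files (counts-file order is kept) and any
    sites missing from one of the tables are dropped with a logged warning.
    """
    counts_df = _read_site_csv(count_path, "counts")
    num = counts_df.apply(pd.to_numeric, errors="coerce")
    if num.isna().any().any():
        site, taxon = _first_non_numeric(counts_df)
        raise DataError(f"non-numeric count cell at site {site!r}, taxon {taxon!r} in {count_path}")
    counts_df = num

    env_df = _read_site_csv(env_path, "environment").apply(pd.to_numeric, errors="coerce")

    site_sets = [set(counts_df.index), set(env_df.index)]
    coords_df = None
    if coords_path is not None:
        coords_df = _read_site_csv(coords_path, "coordinates")
        site_sets.append(set(coords_df.index))
    common = set.intersection(*site_sets)
    if not common:
        raise DataError("no sites shared across input files")
    ordered = [s for s in counts_df.index if s in common]
    dropped = sorted(set.union(*site_sets) - common)
    if dropped:
        logger.warning("dropping %d site(s) absent from some input: %s", len(dropped), dropped)

    habit = None
    if taxon_meta_path is not None:
        meta = pd.read_csv(taxon_meta_path).set_index("taxon")
        habit = meta["habit"].astype(str)

    counts = CountMatrix(counts_df.loc[ordered], habit)
    env = EnvTable(env_df.loc[ordered])
    coords = None
    if coords_df is not None:
        mode = "lonlat" if {"lat", "lon"} <= set(coords_df.columns) else "linear"
        coords = SiteCoords(coords_df.loc[ordered], crs_mode=mode)
    return Dataset(counts, env, coords)


def save_dataset(dataset: Dataset, count_path, env_path, coords_path=None) -> None:
    """Write a Dataset back to the CSV dialects accepted by load_dataset."""
    dataset.counts.counts.rename_axis("site").to_csv(count_path)
    dataset.env.values.rename_axis("site").to_csv(env_path)
    if coords_path is not None and dataset.coords is not None:
        dataset.coords.values.rename_axis("site").to_csv(coords_path)


def relative_abundance(counts: CountMatrix) -> AbundanceMatrix:
    """Divide each site's counts by its total valve count."""
    vals = counts.counts.to_numpy(dtype=float)
    totals = vals.sum(axis=1)
    if np.any(totals <= 0):
        site = counts.counts.index[np.argmax(totals <= 0)]
        raise DataError(f"zero total count at site {site!r}")
    rel = pd.DataFrame(vals / totals[:, None], index=counts.counts.index, columns=counts.counts.columns)
    return AbundanceMatrix(rel, "none")


def rare_taxon_filter(
    rel: AbundanceMatrix,
    min_pct: float = 1.0,
    min_occurrences: int = 2,
    renormalize: bool = False,
) -> tuple[AbundanceMatrix, RareTaxonReport]:
    """Retain taxa reaching ``min_pct`` % relative abundance in at least
    ``min_occurrences`` sites.

    By default the surviving proportions are left as-is, so the report can
    state what share of the counted valves the retained taxa represent;
    with ``renormalize`` each row is rescaled to sum to 1 again (useful
    when a downstream method assumes constant site totals).
    """
    if rel.transform_state != "none":
        raise DataError("rare_taxon_filter expects untransformed proportions")
    vals = rel.values.to_numpy()
    hits = (vals >= min_pct / 100.0).sum(axis=0)
    keep = hits >= min_occurrences
    if not keep.any():
        raise DataError("rare-taxon filter removed every taxon")
    retained = [t for t, k in zip(rel.taxa, keep) if k]
    dropped = [t for t, k in zip(rel.taxa, keep) if not k]
    frac = float(vals[:, keep].sum() / vals.sum()) if vals.sum() > 0 else 0.0
    sub = rel.values[retained]
    if renormalize:
        sub = sub.div(sub.sum(axis=1), axis=0)
    out = AbundanceMatrix(sub, "none")
    report = RareTaxonReport(retained, dropped, min_pct, min_occurrences, frac)
    return out, report


def hellinger(rel: AbundanceMatrix) -> AbundanceMatrix:
    """Square root of row-renormalised proportions.

    Rows are renormalised first so that the transform is well defined even
    after an (un-renormalised) rare-taxon filter; each output row then has
    unit sum of squares.
    """
    if rel.transform_state != "none":
        raise DataError("matrix is already transformed")
    vals = rel.values.to_numpy(dtype=float)
    totals = vals.sum(axis=1)
    if np.any(totals <= 0):
        site = rel.values.index[np.argmax(totals <= 0)]
        raise DataError(f"zero-abundance row at site {site!r}")
    out = np.sqrt(vals / totals[:, None])
    return AbundanceMatrix(pd.DataFrame(out, index=rel.values.index, columns=rel.values.columns), "hellinger")


def skewness(x: np.ndarray) -> float:
    """Adjusted Fisher-Pearson sample skewness (bias-corrected)."""
    return float(stats.skew(np.asarray(x, dtype=float), bias=False))


def transform_env(env: EnvTable, skew_threshold: float = 1.0) -> EnvTable:
    """Log10(x+1)-transform skewed variables, then centre and scale all.

    A variable is log-transformed when its |sample skewness| exceeds
    ``skew_threshold``; every column is then scaled to mean 0, SD 1
    (sample SD, ddof=1).  Constant columns cannot be scaled and are fatal.
    """
    if env.scaled:
        raise DataError("environment table is already scaled")
    out = env.values.astype(float).copy()
    flags = pd.Series(False, index=out.columns)
    for var in out.columns:
        col = out[var].to_numpy()
        if np.ptp(col) > 0 and abs(skewness(col)) > skew_threshold:
            if np.any(col < 0):
                raise DataError(f"variable {var!r} is log-flagged but has negative values")
            out[var] = np.log10(col + 1.0)
            flags[var] = True
    for var in out.columns:
        col = out[var].to_numpy()
        sd = col.std(ddof=1)
        if sd == 0:
            raise DataError(f"variable {var!r} is constant; cannot scale")
        out[var] = (col - col.mean()) / sd
    return EnvTable(out, transform_log=flags, scaled=True)
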