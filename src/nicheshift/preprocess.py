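"""Occurrence-record cleaning and environmental extraction.

The cleaning chain mirrors standard practice for presence-only distribution
data: nearest-neighbour-distance thinning against spatial autocorrelation,
one record per climate grid cell, and a minimum sample size per range.
Thinning and deduplication act within species x status groups so the
native/non-native contrast is never eroded across groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import ClimateStack

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("species", "status", "lon", "lat")
STATUSES = ("native", "nonnative")


def validate_occurrences(occ: pd.DataFrame) -> pd.DataFrame:
    """Check schema and coordinate ranges of an occurrence table."""
    missing = [c for c in REQUIRED_COLUMNS if c not in occ.columns]
    if missing:
        raise ValueError(f"occurrence table missing columns: {missing}")
    bad_status = set(occ["status"]) - set(STATUSES)
    if bad_status:
        raise ValueError(f"unknown status values: {sorted(bad_status)}")
    if ((occ["lon"] < -180) | (occ["lon"] > 180)).any():
        raise ValueError("longitudes outside [-180, 180]")
    if ((occ["lat"] < -90) | (occ["lat"] > 90)).any():
        raise ValueError("latitudes outside [-90, 90]")
    return occ


@dataclass
class EnvMatrix:
    """Environmental values per occurrence row, parallel to the table.

    ``values`` has one column per retained layer and one row per surviving
    occurrence; ``index`` points back into the occurrence table.
    """

    values: np.ndarray
    index: pd.Index
    columns: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.isnan(self.values).any():
            raise ValueError("EnvMatrix must not contain nodata values")
        if self.values.shape[0] != len(self.index):
            raise ValueError("values and index lengths differ")

    def __len__(self) -> int:
        return self.values.shape[0]


def thin_nnd(occ: pd.DataFrame, min_dist: float = 0.02) -> pd.DataFrame:
    """Greedy nearest-neighbour-distance thinning.

    A point is kept iff its planar Euclidean distance in degrees to every
    previously kept point of the same species and status is strictly greater
    than ``min_dist`` (0.02 degrees is roughly 2 km). Keep-first in input
    order; idempotent.
    """
    if min_dist < 0:
        raise ValueError("min_dist must be non-negative")
    if occ.empty:
        return occ.copy()
    validate_occurrences(occ)
    keep_mask = np.zeros(len(occ), dtype=bool)
    xy_all = occ[["lon", "lat"]].to_numpy(dtype=float)
    codes, _ = pd.factorize(
        occ["species"].astype(str) + "\x00" + occ["status"].astype(str)
    )
    for g in np.unique(codes):
        gpos = np.flatnonzero(codes == g)
        kept: list[int] = []
        for p in gpos:
            if kept:
                d2 = np.sum((xy_all[kept] - xy_all[p]) ** 2, axis=1)
                if (d2 <= min_dist**2).any():
                    continue
            kept.append(p)
            keep_mask[p] = True
    log.info("thin_nnd: kept %d of %d records", int(keep_mask.sum()), len(occ))
    return occ[keep_mask]


def dedupe_grid_cells(occ: pd.DataFrame, stack: ClimateStack) -> pd.DataFrame:
    """Keep at most one record per species x status x raster cell.

    First record in input order wins. Points outside the raster extent are
    dropped (counted in the log).
    """
    if occ.empty:
        return occ.copy()
    validate_occurrences(occ)
    idx = stack.cell_indices(occ["lon"].to_numpy(), occ["lat"].to_numpy())
    inside = idx[:, 0] >= 0
    n_outside = int((~inside).sum())
    if n_outside:
        log.warning("dedupe_grid_cells: dropped %d points outside the raster extent", n_outside)
    sub = occ[inside].copy()
    sub["_row"] = idx[inside, 0]
    sub["_col"] = idx[inside, 1]
    sub = sub.drop_duplicates(subset=["species", "status", "_row", "_col"], keep="first")
    return sub.drop(columns=["_row", "_col"])


def filter_min_occurrences(
    occ: pd.DataFrame, min_n: int = 10
) -> tuple[pd.DataFrame, list[str]]:
    """Drop species lacking ``min_n`` records in the native OR non-native range.

    A species survives iff it has at least ``min_n`` native and at least
    ``min_n`` non-native records. Returns (filtered table, dropped species).
    """
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    if occ.empty:
        return occ.copy(), []
    counts = occ.groupby(["species", "status"]).size().unstack(fill_value=0)
    for s in STATUSES:
        if s not in counts:
            counts[s] = 0
    ok = counts[(counts["native"] >= min_n) & (counts["nonnative"] >= min_n)].index
    dropped = sorted(set(occ["species"]) - set(ok))
    if dropped:
        log.info("filter_min_occurrences: dropped %s", dropped)
    return occ[occ["species"].isin(ok)], dropped


def extract_env(occ: pd.DataFrame, stack: ClimateStack) -> tuple[EnvMatrix, pd.DataFrame]:
    """Nearest-cell environmental vectors for each occurrence.

    Rows that hit nodata cells (or fall outside the extent) are removed and
    counted. Returns the environment matrix and the matching subset of the
    occurrence table.
    """
    if occ.empty:
        raise ValueError("no occurrences to extract")
    vals = stack.values_at(occ["lon"].to_numpy(), occ["lat"].to_numpy())
    ok = ~np.isnan(vals).any(axis=1)
    if not ok.any():
        raise ValueError("every occurrence fell on nodata or outside the raster")
    n_bad = int((~ok).sum())
    if n_bad:
        log.warning("extract_env: dropped %d records on nodata cells", n_bad)
    sub = occ[ok]
    return EnvMatrix(vals[ok], sub.index, list(stack.layer_names)), sub


def clean_pipeline(
    occ: pd.DataFrame,
    stack: ClimateStack,
    min_dist: float = 0.02,
    min_n: int = 10,
    exclude: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full cleaning chain: exclusion list -> thin -> cell dedup -> min-n filter.

    ``exclude`` is an optional table of records to remove before cleaning
    (manual curation of dubious or indoor occurrences), matched exactly on
    species/status/lon/lat. Returns the cleaned table and a report of counts
    dropped per rule.
    """
    validate_occurrences(occ)
    report: dict = {"input": len(occ)}
    if exclude is not None and len(exclude):
        key = ["species", "status", "lon", "lat"]
        merged = occ.merge(exclude[key].drop_duplicates(), on=key, how="left", indicator=True)
        occ = occ[(merged["_merge"] == "left_only").to_numpy()]
        report["excluded_manual"] = report["input"] - len(occ)
    thinned = thin_nnd(occ, min_dist=min_dist)
    report["dropped_thinning"] = len(occ) - len(thinned)
    deduped = dedupe_grid_cells(thinned, stack)
    report["dropped_cell_duplicates"] = len(thinned) - len(deduped)
    filtered, dropped_species = filter_min_occurrences(deduped, min_n=min_n)
    report["dropped_min_occurrences"] = len(deduped) - len(filtered)
    report["dropped_species"] = dropped_species
    report["output"] = len(filtered)
    return filtered, report
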