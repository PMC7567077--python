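"""Geographic dispersion metrics: polygon richness, Rao entropy, grouping.

A species' range is summarised by the set of map polygons it occupies
(richness) and by Rao's quadratic entropy Q = sum_ij p_i p_j d_ij over the
great-circle distances between occupied polygon centroids — a joint
measure of how many and how far apart the occupied regions are. Clustering
species in this richness-diversity space yields regional, transcontinental
and global dispersion groups of increasing spread.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from sklearn.cluster import KMeans

from .synthetic import RangePolygons

log = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

DISPERSION_GROUPS = ("regional", "transcontinental", "global")


@dataclass
class DispersionRecord:
    species_id: str
    richness: int
    rao_total: float
    rao_native: float
    group: str | None = None


def occupied_polygons(
    occ: pd.DataFrame,
    polygons: RangePolygons,
    status_filter: str | None = None,
) -> tuple[set[str], int]:
    """Set of polygons containing at least one occurrence, and its size.

    Polygon boundaries count as inside. Occurrences falling in no polygon
    are logged and ignored.
    """
    if not polygons.polygon_ids:
        raise ValueError("polygon map is empty")
    sub = occ if status_filter is None else occ[occ["status"] == status_filter]
    if sub.empty:
        return set(), 0
    lon = sub["lon"].to_numpy(dtype=float)
    lat = sub["lat"].to_numpy(dtype=float)
    hit = np.zeros(len(sub), dtype=bool)
    occupied: set[str] = set()
    for pid, poly in zip(polygons.polygon_ids, polygons.polygons):
        inside = shapely.intersects_xy(poly, lon, lat)
        if inside.any():
            occupied.add(pid)
        hit |= inside
    n_orphan = int((~hit).sum())
    if n_orphan:
        log.warning("occupied_polygons: %d occurrences fall in no polygon", n_orphan)
    return occupied, len(occupied)


def haversine_km(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Great-circle distance matrix (km) between lon/lat point sets."""
    a = np.radians(np.atleast_2d(a))
    b = np.radians(np.atleast_2d(b))
    dlon = a[:, None, 0] - b[None, :, 0]
    dlat = a[:, None, 1] - b[None, :, 1]
    h = (
        np.sin(dlat / 2) ** 2
        + np.cos(a[:, None, 1]) * np.cos(b[None, :, 1]) * np.sin(dlon / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def rao_entropy(centroids: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Rao quadratic entropy Q = sum_ij p_i p_j d_ij over centroid distances.

    Distances are great-circle (haversine) in km; weights default to the
    uniform distribution over centroids and must sum to 1.
    """
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    n = len(centroids)
    if n == 0:
        raise ValueError("need at least one centroid")
    if weights is None:
        weights = np.full(n, 1.0 / n)
    else:
        weights = np.asarray(weights, dtype=float)
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
    if n == 1:
        return 0.0
    D = haversine_km(centroids, centroids)
    return float(weights @ D @ weights)


def classify_dispersion(
    records: list[tuple[float, float]] | np.ndarray,
    k: int = 3,
    seed: int | None = 0,
    n_init: int = 20,
) -> list[str]:
    """Cluster species in (richness, Rao) space into dispersion groups.

    Features are z-scored; k-means with ``n_init`` restarts and a fixed
    seed; clusters are named regional < transcontinental < global by
    ascending mean Rao entropy (generic ``group_i`` names for k != 3).
    """
    X = np.asarray(records, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("records must be (n, 2): richness and rao_total")
    if len(X) < k:
        raise ValueError(f"need at least k={k} records, got {len(X)}")
    sd = X.std(axis=0)
    Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    n_unique = len(np.unique(Z, axis=0))
    k_eff = min(k, n_unique)
    if k_eff < k:
        warnings.warn(
            f"only {n_unique} distinct records; using {k_eff} effective clusters"
        )
    km = KMeans(n_clusters=k_eff, n_init=n_init, random_state=seed)
    labels = km.fit_predict(Z)
    mean_rao = np.array([X[labels == c, 1].mean() for c in range(k_eff)])
    order = np.argsort(mean_rao)
    names = list(DISPERSION_GROUPS) if k == 3 else [f"group_{i}" for i in range(k)]
    rank = {c: r for r, c in enumerate(order)}
    return [names[rank[c]] for c in labels]
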