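"""Environmental niche axis and gridded occupancy densities.

For each species the climatic variables at native and non-native
occurrences are standardised and reduced by PCA; a between-class analysis
on the retained axes (native vs non-native as a priori classes) yields the
single direction separating the two ranges the most — for two classes this
is the unit vector along the difference of class centroids in score space.
Occurrence and climate-availability densities are then kernel-smoothed on a
common binned grid along that axis, and occupancy is corrected for
availability (z proportional to o/e), following the standard
environmental-space niche-comparison framework.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint
from sklearn.decomposition import PCA

from .grids import ClimateStack
from .preprocess import EnvMatrix

#: availability below this fraction of total mass counts as absent climate
EPS_AVAILABILITY = 1e-12


def silverman_1d(x: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth, 1.06 * SD * n^(-1/5)."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot pick a bandwidth for constant scores")
    return 1.06 * sd * len(x) ** (-0.2)


def gaussian_grid_density(points: np.ndarray, mids: np.ndarray, h: float) -> np.ndarray:
    """Gaussian KDE evaluated at bin midpoints, renormalised to sum 1.

    The kernel is truncated at the grid bounds simply by evaluating only at
    the midpoints and renormalising (no reflection).
    """
    t = (mids[None, :] - np.asarray(points, dtype=float)[:, None]) / h
    dens = np.exp(-0.5 * t * t).sum(axis=0)
    s = dens.sum()
    if s == 0:
        raise ValueError("density underflow: all mass outside the grid")
    return dens / s


@dataclass
class NicheAxis:
    """Standardisation + PCA loadings + between-class direction."""

    columns: list[str]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray  # (k, n_axes)
    bca_vector: np.ndarray  # (n_axes,)
    dropped_columns: list[str]
    n_bins: int = 100

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.bca_vector = np.asarray(self.bca_vector, dtype=float)
        if not np.isclose(np.linalg.norm(self.bca_vector), 1.0):
            raise ValueError("bca_vector must have unit norm")

    @property
    def direction(self) -> np.ndarray:
        """The axis expressed in standardised-variable space, (k,)."""
        return self.loadings @ self.bca_vector

    def to_json(self) -> str:
        return json.dumps(
            {
                "columns": self.columns,
                "means": self.means.tolist(),
                "sds": self.sds.tolist(),
                "loadings": self.loadings.tolist(),
                "bca_vector": self.bca_vector.tolist(),
                "dropped_columns": self.dropped_columns,
                "n_bins": self.n_bins,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "NicheAxis":
        d = json.loads(s)
        return cls(
            columns=d["columns"],
            means=np.array(d["means"]),
            sds=np.array(d["sds"]),
            loadings=np.array(d["loadings"]),
            bca_vector=np.array(d["bca_vector"]),
            dropped_columns=d["dropped_columns"],
            n_bins=d["n_bins"],
        )


def bca_direction(scores: np.ndarray, is_first_class: np.ndarray) -> np.ndarray:
    """Unit vector along the class-centroid difference in score space.

    Oriented so the first class projects at or below the second; falls back
    to the first principal axis when the centroids coincide.
    """
    a = scores[is_first_class].mean(axis=0)
    b = scores[~is_first_class].mean(axis=0)
    diff = b - a
    norm = np.linalg.norm(diff)
    if norm < 1e-12:
        warnings.warn("identical class centroids; between-class axis defaults to PC1")
        e1 = np.zeros(scores.shape[1])
        e1[0] = 1.0
        return e1
    return diff / norm


def fit_species_axis(
    env_native: EnvMatrix, env_nonnative: EnvMatrix, n_axes: int = 10
) -> NicheAxis:
    """Fit the species' niche axis: pooled standardisation, PCA, BCA.

    Variables are standardised over the pooled occurrences, the PCA is fit
    on the pooled standardised matrix, scores are truncated to the first
    ``n_axes`` components, and the between-class direction is taken along
    the native-to-non-native centroid difference, sign-fixed so the native
    centroid projects at or below the non-native one.
    """
    if env_native.columns != env_nonnative.columns:
        raise ValueError("native and non-native matrices must share columns")
    X = np.vstack([env_native.values, env_nonnative.values])
    n, k = X.shape
    if n <= n_axes:
        raise ValueError(f"need more than {n_axes} pooled occurrences, got {n}")

    sds = X.std(axis=0)
    keep = sds > 0
    dropped = [c for c, ok in zip(env_native.columns, keep) if not ok]
    if dropped:
        warnings.warn(f"dropping zero-variance variables: {dropped}")
    cols = [c for c, ok in zip(env_native.columns, keep) if ok]
    X = X[:, keep]
    means, sds = X.mean(axis=0), X.std(axis=0)
    Z = (X - means) / sds

    m = min(n_axes, Z.shape[1], n - 1)
    pca = PCA(n_components=m, svd_solver="full")
    scores = pca.fit_transform(Z)
    is_native = np.arange(n) < len(env_native)
    bca = bca_direction(scores, is_native)
    return NicheAxis(
        columns=cols,
        means=means,
        sds=sds,
        loadings=pca.components_.T,
        bca_vector=bca,
        dropped_columns=dropped,
    )


def project(env: EnvMatrix | np.ndarray, axis: NicheAxis) -> np.ndarray:
    """Project environmental vectors onto the species' niche axis."""
    if isinstance(env, EnvMatrix):
        if axis.dropped_columns:
            keep = [env.columns.index(c) for c in axis.columns]
            X = env.values[:, keep]
        else:
            if env.columns != axis.columns:
                raise ValueError("environment columns do not match the axis")
            X = env.values
    else:
        X = np.asarray(env, dtype=float)
        if X.shape[1] != len(axis.columns):
            raise ValueError("environment columns do not match the axis")
    Z = (X - axis.means) / axis.sds
    return Z @ axis.direction


@dataclass
class GridDensity:
    """Occurrence (o), availability (e) and corrected occupancy (z) per bin.

    All three sum to 1; z is 0 wherever availability is (numerically) 0,
    so the occupancy support never exceeds the climates actually available
    to the range.
    """

    edges: np.ndarray
    o: np.ndarray
    e: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        for name in ("o", "e", "z"):
            v = getattr(self, name)
            if (v < 0).any():
                raise ValueError(f"{name} has negative entries")
            if abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if (self.z[self.e == 0] != 0).any():
            raise ValueError("z must be 0 where availability is 0")

    @property
    def mids(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_mid": self.mids, "o": self.o, "e": self.e, "z": self.z})


def grid_density(
    scores_occ: np.ndarray,
    scores_bg: np.ndarray,
    n_bins: int = 100,
    bandwidth: float | None = None,
    bounds: tuple[float, float] | None = None,
    correct_availability: bool = True,
) -> GridDensity:
    """Kernel-smoothed densities of occurrences and availability on one grid.

    ``bounds`` should span the pooled background of both ranges so native
    and non-native grids coincide; they default to the min/max of
    ``scores_bg``. The availability density is additionally masked to the
    observed background score range: climates the background never reaches
    have e = 0 (and hence z = 0) even though the Gaussian kernel has
    infinite tails. With ``correct_availability=False`` z equals o on the
    background support (uncorrected occupancy).
    """
    scores_occ = np.asarray(scores_occ, dtype=float)
    scores_bg = np.asarray(scores_bg, dtype=float)
    if len(np.unique(scores_occ)) < 2:
        raise ValueError("need at least 2 distinct occurrence scores")
    if bounds is None:
        bounds = (scores_bg.min(), scores_bg.max())
    lo, hi = bounds
    if not hi > lo:
        raise ValueError("empty score bounds")
    edges = np.linspace(lo, hi, n_bins + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])

    h_occ = bandwidth if bandwidth is not None else silverman_1d(scores_occ)
    o = gaussian_grid_density(scores_occ, mids, h_occ)

    if len(np.unique(scores_bg)) < 2:
        raise ValueError("need at least 2 distinct background scores")
    h_bg = bandwidth if bandwidth is not None else silverman_1d(scores_bg)
    e = gaussian_grid_density(scores_bg, mids, h_bg)
    support = (mids >= scores_bg.min()) & (mids <= scores_bg.max())
    e = np.where(support, e, 0.0)
    if e.sum() == 0:
        raise ValueError("background support does not intersect the grid")
    e = e / e.sum()

    avail = e > EPS_AVAILABILITY
    if correct_availability:
        z = np.where(avail, o / np.where(avail, e, 1.0), 0.0)
    else:
        z = np.where(avail, o, 0.0)
    if z.sum() == 0:
        raise ValueError("occupancy has no mass on available climates")
    z = z / z.sum()
    return GridDensity(edges=edges, o=o, e=e, z=z)


def range_background_env(
    occ_lonlat: np.ndarray,
    stack: ClimateStack,
    buffer_cells: float = 1.0,
    mode: str = "hull",
) -> np.ndarray:
    """Environmental matrix of the background cells available to a range.

    ``mode='hull'`` (default): all valid raster cells whose centres fall in
    the convex hull of the range's occurrences buffered by ``buffer_cells``
    grid cells. ``mode='raster'``: every valid cell of the stack.
    """
    env, rows, cols = stack.env_table()
    if mode == "raster":
        return env
    if mode != "hull":
        raise ValueError(f"unknown background mode: {mode}")
    pts = np.asarray(occ_lonlat, dtype=float)
    hull = MultiPoint(pts).convex_hull.buffer(buffer_cells * stack.cell_size)
    centers = stack.cell_centers(rows, cols)
    inside = shapely.contains_xy(hull, centers[:, 0], centers[:, 1])
    if not inside.any():
        raise ValueError("no background cells inside the buffered hull")
    return env[inside]
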