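"""Seeded virtual-species fixtures: climate rasters, occurrences, polygons.

The generator emulates the inputs of a climatic niche-shift study without
any real-world data: spatially smooth, inter-correlated climate layers; a
virtual species whose occurrences are draws from a Gaussian suitability
surface in environment space; a non-native population with a controllable
niche-centroid displacement and a controllable fraction of occurrences in
climates absent from the native background; and a regular polygon
tessellation with known centroids.

All environment-space quantities (niche centre, breadth, shift) are in
standardised units: each layer is z-scored over the stack's valid cells, so
"1 unit" means one grid-wide standard deviation of that layer.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box, mapping, shape

from .grids import ClimateStack, DEFAULT_LAYER_NAMES, write_stack

Window = tuple[float, float, float, float]  # lon_min, lon_max, lat_min, lat_max


@dataclass
class VirtualSpeciesTruth:
    """Ground-truth parameters of one simulated species.

    ``niche_center``, ``niche_breadth`` and ``shift_delta`` live in
    standardised environment space (per-layer z-scores over the stack).
    ``target_expansion`` is the fraction of non-native occurrences forced
    into climates outside the native window's environmental envelope.
    """

    niche_center: np.ndarray
    niche_breadth: np.ndarray
    shift_delta: np.ndarray
    target_expansion: float
    seed: int

    def __post_init__(self) -> None:
        self.niche_center = np.atleast_1d(np.asarray(self.niche_center, dtype=float))
        self.niche_breadth = np.atleast_1d(np.asarray(self.niche_breadth, dtype=float))
        self.shift_delta = np.atleast_1d(np.asarray(self.shift_delta, dtype=float))
        if (self.niche_breadth <= 0).any():
            raise ValueError("niche breadths must be > 0")
        if not 0.0 <= self.target_expansion <= 1.0:
            raise ValueError("target_expansion must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "niche_center": self.niche_center.tolist(),
            "niche_breadth": self.niche_breadth.tolist(),
            "shift_delta": self.shift_delta.tolist(),
            "target_expansion": self.target_expansion,
            "seed": self.seed,
        }


@dataclass
class RangePolygons:
    """A tessellation of geographic polygons with ids and centroids."""

    polygon_ids: list[str]
    polygons: list[Polygon]
    centroids: np.ndarray  # (n, 2) lon/lat

    def __post_init__(self) -> None:
        if len(set(self.polygon_ids)) != len(self.polygon_ids):
            raise ValueError("polygon ids must be unique")
        self.centroids = np.asarray(self.centroids, dtype=float)

    def to_geojson(self) -> dict:
        return {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {"polygon_id": pid},
                    "geometry": mapping(poly),
                }
                for pid, poly in zip(self.polygon_ids, self.polygons)
            ],
        }

    @classmethod
    def from_geojson(cls, gj: dict) -> "RangePolygons":
        ids, polys, cents = [], [], []
        for feat in gj["features"]:
            poly = shape(feat["geometry"])
            ids.append(str(feat["properties"]["polygon_id"]))
            polys.append(poly)
            c = poly.centroid
            cents.append((c.x, c.y))
        return cls(ids, polys, np.array(cents))


# -- climate layers -------------------------------------------------------


def _mode_pool(k_max: int) -> list[tuple[int, int]]:
    """Distinct 2-D plane-wave modes; ±(kx,ky) pairs appear once."""
    pool = [(0, ky) for ky in range(1, k_max + 1)]
    pool += [(kx, ky) for kx in range(1, k_max + 1) for ky in range(-k_max, k_max + 1)]
    return pool


def _wave_field(u: np.ndarray, v: np.ndarray, modes, amps, phases) -> np.ndarray:
    f = np.zeros_like(u)
    for (kx, ky), a, ph in zip(modes, amps, phases):
        f += a * np.cos(2 * np.pi * (kx * u + ky * v) + ph)
    return f


def _standardize(f: np.ndarray) -> np.ndarray:
    return (f - f.mean()) / f.std()


def generate_climate_stack(
    n_layers: int = 17,
    n_rows: int = 50,
    n_cols: int = 50,
    *,
    x_origin: float = 0.0,
    y_origin: float = 50.0,
    cell_size: float = 1.0,
    correlation: float = 0.3,
    seed: int = 0,
    layer_names: list[str] | None = None,
    n_modes: int = 4,
    noise_sd: float = 0.05,
    gradient_weight: float = 4.0,
) -> ClimateStack:
    """Generate smooth, pairwise-correlated synthetic climate layers.

    Each layer is ``sqrt(c) * shared + sqrt(1-c) * own + noise`` where
    ``shared`` and ``own`` are unit-variance sums of low-frequency plane
    waves and ``c`` is the requested pairwise ``correlation``. The shared
    component carries a one-sided west-east ramp (zero over the western
    half, rising eastward, weighted ``gradient_weight`` times the shared
    waves): the eastern part of the domain then holds both climates that
    also occur in the west and genuinely novel ones, the way an invaded
    continent offers both analog and non-analog climates. At
    ``correlation=0`` the per-layer
    wave modes are drawn without replacement from a common pool, making
    layers mutually orthogonal up to the white-noise term.
    """
    if n_layers < 2:
        raise ValueError("need at least 2 layers")
    if n_rows < 2 or n_cols < 2:
        raise ValueError("degenerate grid: need at least 2 cells per side")
    if not 0.0 <= correlation < 1.0:
        raise ValueError("correlation must lie in [0, 1)")
    if layer_names is None:
        layer_names = (
            list(DEFAULT_LAYER_NAMES[:n_layers])
            if n_layers <= len(DEFAULT_LAYER_NAMES)
            else [f"env{i + 1}" for i in range(n_layers)]
        )
    if len(layer_names) != n_layers:
        raise ValueError("layer_names length must equal n_layers")

    rng = np.random.default_rng(seed)
    needed = (n_layers + 1) * n_modes
    k_max = 6
    while len(_mode_pool(k_max)) < needed:
        k_max += 1
    pool = _mode_pool(k_max)
    order = rng.permutation(len(pool))

    # fractional coordinates over the periodic domain
    u = (np.arange(n_cols) + 0.5)[None, :] / n_cols * np.ones((n_rows, 1))
    v = (np.arange(n_rows) + 0.5)[:, None] / n_rows * np.ones((1, n_cols))

    def draw_field(slot: int) -> np.ndarray:
        modes = [pool[order[slot * n_modes + j]] for j in range(n_modes)]
        amps = [1.0 / (1.0 + abs(kx) + abs(ky)) for kx, ky in modes]
        phases = rng.uniform(0, 2 * np.pi, size=n_modes)
        return _standardize(_wave_field(u, v, modes, amps, phases))

    # shared component: one-sided eastward ramp plus shared waves
    ramp = _standardize(np.maximum(0.0, u - 0.5))
    shared = _standardize(gradient_weight * ramp + draw_field(0))

    sc, so = np.sqrt(correlation), np.sqrt(1.0 - correlation)
    layers = np.empty((n_layers, n_rows, n_cols))
    for i in range(n_layers):
        f = sc * shared + so * draw_field(i + 1)
        f = f + noise_sd * rng.standard_normal((n_rows, n_cols))
        mu = rng.uniform(-5.0, 25.0)
        sigma = rng.uniform(1.0, 10.0)
        layers[i] = mu + sigma * f

    return ClimateStack(
        layer_names=list(layer_names),
        values=layers,
        x_origin=x_origin,
        y_origin=y_origin,
        cell_size=cell_size,
    )


# -- virtual species ------------------------------------------------------


def _window_cells(stack: ClimateStack, window: Window):
    """(rows, cols, centers) of valid cells whose centre lies in window."""
    env, rows, cols = stack.env_table()
    centers = stack.cell_centers(rows, cols)
    lo_x, hi_x, lo_y, hi_y = window
    inside = (
        (centers[:, 0] >= lo_x)
        & (centers[:, 0] <= hi_x)
        & (centers[:, 1] >= lo_y)
        & (centers[:, 1] <= hi_y)
    )
    return env[inside], rows[inside], cols[inside]


def _windows_disjoint(a: Window, b: Window) -> bool:
    return a[1] <= b[0] or b[1] <= a[0] or a[3] <= b[2] or b[3] <= a[2]


def generate_virtual_species(
    stack: ClimateStack,
    truth: VirtualSpeciesTruth,
    native_window: Window,
    nonnative_window: Window,
    n_native: int,
    n_nonnative: int,
    species_id: str = "virtual_sp",
) -> pd.DataFrame:
    """Sample native and non-native occurrences of a virtual species.

    Native points are drawn from cells in ``native_window`` with probability
    proportional to a Gaussian suitability
    ``exp(-0.5 * ||(x - center) / breadth||^2)`` of each cell's standardised
    environment ``x``. Non-native points come from ``nonnative_window`` with
    the centre displaced by ``truth.shift_delta``; a fraction
    ``truth.target_expansion`` of them is forced (by rejection against the
    native window's per-layer min/max environmental envelope) into climates
    absent from the native background, and the remainder into climates
    present in it. Deterministic for a fixed ``truth.seed``.
    """
    if n_native < 10 or n_nonnative < 10:
        raise ValueError("need at least 10 native and 10 non-native points")
    if not _windows_disjoint(native_window, nonnative_window):
        raise ValueError("native and non-native windows must be disjoint")

    env_all, _, _ = stack.env_table()
    mu = env_all.mean(axis=0)
    sd = env_all.std(axis=0)
    sd[sd == 0] = 1.0
    k = stack.n_layers
    center = np.broadcast_to(truth.niche_center, (k,)).astype(float)
    breadth = np.broadcast_to(truth.niche_breadth, (k,)).astype(float)
    delta = np.broadcast_to(truth.shift_delta, (k,)).astype(float)

    rng = np.random.default_rng(truth.seed)

    def sample_points(window, ctr, n, subset=None, label="", uniform=False):
        env, rows, cols = _window_cells(stack, window)
        if len(env) == 0:
            raise ValueError(f"{label or 'window'} contains no valid climate cells")
        z = (env - mu) / sd
        if subset is not None:
            if not subset.any():
                warnings.warn(
                    f"no {label} cells available; falling back to the whole window",
                    stacklevel=3,
                )
            else:
                z, rows, cols = z[subset], rows[subset], cols[subset]
        if uniform:
            w = np.ones(len(z))
        else:
            w = np.exp(-0.5 * np.sum(((z - ctr) / breadth) ** 2, axis=1))
            if w.sum() == 0:
                w = np.ones(len(z))
        idx = rng.choice(len(z), size=n, p=w / w.sum())
        jit = rng.uniform(0, stack.cell_size, size=(n, 2))
        d = stack.cell_size
        lon = stack.x_origin + cols[idx] * d + jit[:, 0]
        lat = stack.y_origin - (rows[idx] + 1) * d + jit[:, 1]
        return lon, lat

    nat_lon, nat_lat = sample_points(native_window, center, n_native, label="native")

    # native background envelope (standardised per-layer min/max box)
    nat_env, _, _ = _window_cells(stack, native_window)
    nat_z = (nat_env - mu) / sd
    env_lo, env_hi = nat_z.min(axis=0), nat_z.max(axis=0)

    non_env, _, _ = _window_cells(stack, nonnative_window)
    if len(non_env) == 0:
        raise ValueError("nonnative window contains no valid climate cells")
    non_z = (non_env - mu) / sd
    outside = ((non_z < env_lo) | (non_z > env_hi)).any(axis=1)

    n_exp = int(round(truth.target_expansion * n_nonnative))
    shifted = center + delta
    lon_parts, lat_parts = [], []
    if n_exp > 0:
        # a native-niche suitability surface carries no information about
        # non-analog climates, so novel-climate draws follow availability
        lo, la = sample_points(
            nonnative_window, shifted, n_exp, subset=outside,
            label="novel-climate", uniform=True,
        )
        lon_parts.append(lo)
        lat_parts.append(la)
    if n_nonnative - n_exp > 0:
        lo, la = sample_points(
            nonnative_window, shifted, n_nonnative - n_exp,
            subset=~outside, label="analog-climate",
        )
        lon_parts.append(lo)
        lat_parts.append(la)
    non_lon = np.concatenate(lon_parts)
    non_lat = np.concatenate(lat_parts)

    return pd.DataFrame(
        {
            "species": species_id,
            "status": ["native"] * n_native + ["nonnative"] * n_nonnative,
            "lon": np.concatenate([nat_lon, non_lon]),
            "lat": np.concatenate([nat_lat, non_lat]),
        }
    )


# -- polygons -------------------------------------------------------------


def generate_polygon_map(n_x: int, n_y: int, extent: Window) -> RangePolygons:
    """Regular ``n_x`` x ``n_y`` rectangular tessellation of ``extent``."""
    if n_x < 1 or n_y < 1:
        raise ValueError("n_x and n_y must be >= 1")
    lo_x, hi_x, lo_y, hi_y = extent
    if hi_x <= lo_x or hi_y <= lo_y:
        raise ValueError("empty extent")
    dx = (hi_x - lo_x) / n_x
    dy = (hi_y - lo_y) / n_y
    ids, polys, cents = [], [], []
    for j in range(n_y):
        for i in range(n_x):
            x0, y0 = lo_x + i * dx, lo_y + j * dy
            polys.append(box(x0, y0, x0 + dx, y0 + dy))
            cents.append((x0 + dx / 2, y0 + dy / 2))
            ids.append(f"P{j:03d}_{i:03d}")
    return RangePolygons(ids, polys, np.array(cents))


# -- fixture serialisation ------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture(
    out_dir: Path | str,
    stack: ClimateStack,
    occurrences: pd.DataFrame,
    polygons: RangePolygons,
    truth: VirtualSpeciesTruth | list[VirtualSpeciesTruth] | dict,
) -> dict:
    """Write a complete fixture (rasters, occurrences, polygons, truth).

    Returns a manifest mapping each written file name to its sha256; the
    manifest itself is also written as ``manifest.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = list(write_stack(stack, out_dir))

    occ_path = out_dir / "occurrences.csv"
    occurrences.to_csv(occ_path, index=False)
    files.append(occ_path)

    poly_path = out_dir / "polygons.geojson"
    poly_path.write_text(json.dumps(polygons.to_geojson()))
    files.append(poly_path)

    if isinstance(truth, VirtualSpeciesTruth):
        payload = truth.to_dict()
    elif isinstance(truth, list):
        payload = [t.to_dict() if isinstance(t, VirtualSpeciesTruth) else t for t in truth]
    else:
        payload = truth
    truth_path = out_dir / "truth.json"
    truth_path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    files.append(truth_path)

    manifest = {p.name: _sha256(p) for p in files}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
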