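"""Regular lon/lat raster stacks of bioclimatic layers.

A :class:`ClimateStack` holds co-registered environmental layers on a
north-up grid. Layer files are read and written as ESRI ASCII grids
(``.asc``), a plain-text raster format that round-trips float values
exactly when written at full precision.

Cell convention: column ``c`` spans ``[x0 + c*d, x0 + (c+1)*d)`` in
longitude and row ``r`` spans ``(y0 - (r+1)*d, y0 - r*d]`` in latitude,
where ``(x0, y0)`` is the north-west corner and ``d`` the cell size.
Points on the western/northern cell edge therefore belong to that cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: 17 of the 19 standard bioclimatic variables; BIO2 and BIO7 are linear
#: combinations of other layers and are conventionally excluded.
DEFAULT_LAYER_NAMES: tuple[str, ...] = tuple(
    ["bio1", "bio3", "bio4", "bio5", "bio6"] + [f"bio{i}" for i in range(8, 20)]
)

NODATA = -9999.0


@dataclass
class ClimateStack:
    """Co-registered environmental raster layers with shared geometry.

    Parameters
    ----------
    layer_names : list of str
        One label per layer.
    values : ndarray, shape (n_layers, n_rows, n_cols)
        Environmental values; ``nan`` marks nodata. All layers must share
        the same nodata mask.
    x_origin, y_origin : float
        Longitude of the west edge and latitude of the north edge (degrees).
    cell_size : float
        Cell side length in degrees; cells are square.
    """

    layer_names: list[str]
    values: np.ndarray
    x_origin: float
    y_origin: float
    cell_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must have shape (n_layers, n_rows, n_cols)")
        if len(self.layer_names) != self.values.shape[0]:
            raise ValueError("layer_names length does not match values")
        if len(self.layer_names) < 2:
            raise ValueError("a climate stack needs at least 2 layers")
        if len(set(self.layer_names)) != len(self.layer_names):
            raise ValueError("layer names must be unique")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        masks = np.isnan(self.values)
        if masks.any() and not (masks == masks[0]).all():
            raise ValueError("all layers must share an identical nodata mask")

    # -- geometry ---------------------------------------------------------

    @property
    def n_layers(self) -> int:
        return self.values.shape[0]

    @property
    def n_rows(self) -> int:
        return self.values.shape[1]

    @property
    def n_cols(self) -> int:
        return self.values.shape[2]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(lon_min, lon_max, lat_min, lat_max) of the grid."""
        return (
            self.x_origin,
            self.x_origin + self.n_cols * self.cell_size,
            self.y_origin - self.n_rows * self.cell_size,
            self.y_origin,
        )

    def cell_index(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Map a point to its (row, col) cell, or None outside the extent."""
        d = self.cell_size
        tx = (lon - self.x_origin) / d
        ty = (self.y_origin - lat) / d
        col = math.floor(tx)
        # latitude interval is half-open at the bottom: (y - d, y]
        row = math.ceil(ty) - 1 if ty > 0 else 0 if ty == 0 else -1
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return row, col
        return None

    def cell_indices(self, lons: np.ndarray, lats: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`cell_index`; returns (n, 2) with -1 outside."""
        lons = np.asarray(lons, dtype=float)
        lats = np.asarray(lats, dtype=float)
        d = self.cell_size
        col = np.floor((lons - self.x_origin) / d).astype(int)
        ty = (self.y_origin - lats) / d
        row = np.ceil(ty).astype(int) - 1
        row[ty == 0] = 0
        out = np.stack([row, col], axis=1)
        bad = (row < 0) | (row >= self.n_rows) | (col < 0) | (col >= self.n_cols)
        out[bad] = -1
        return out

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        d = self.cell_size
        return (self.x_origin + (col + 0.5) * d, self.y_origin - (row + 0.5) * d)

    # -- value access -----------------------------------------------------

    def values_at(self, lons: np.ndarray, lats: np.ndarray) -> np.ndarray:
        """Nearest-cell environmental vectors for points; nan where the
        point falls outside the extent or on a nodata cell."""
        idx = self.cell_indices(np.asarray(lons), np.asarray(lats))
        out = np.full((len(idx), self.n_layers), np.nan)
        ok = idx[:, 0] >= 0
        out[ok] = self.values[:, idx[ok, 0], idx[ok, 1]].T
        return out

    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.values[0])

    def env_table(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Environmental matrix over valid cells.

        Returns ``(env, rows, cols)`` where ``env`` has shape
        (n_valid_cells, n_layers).
        """
        rows, cols = np.nonzero(self.valid_mask())
        env = self.values[:, rows, cols].T
        return env, rows, cols

    def cell_centers(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        d = self.cell_size
        lon = self.x_origin + (np.asarray(cols) + 0.5) * d
        lat = self.y_origin - (np.asarray(rows) + 0.5) * d
        return np.stack([lon, lat], axis=1)


# -- ESRI ASCII grid I/O --------------------------------------------------


def write_ascii_grid(path: Path | str, grid: np.ndarray, x_origin: float,
                     y_llcorner: float, cell_size: float) -> None:
    grid = np.asarray(grid, dtype=float)
    out = np.where(np.isnan(grid), NODATA, grid)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.shape[1]}\n")
        fh.write(f"nrows {grid.shape[0]}\n")
        fh.write(f"xllcorner {float(x_origin):.17g}\n")
        fh.write(f"yllcorner {float(y_llcorner):.17g}\n")
        fh.write(f"cellsize {float(cell_size):.17g}\n")
        fh.write(f"NODATA_value {NODATA:.17g}\n")
        for r in range(grid.shape[0]):
            fh.write(" ".join(f"{v:.17g}" for v in out[r]) + "\n")


def read_ascii_grid(path: Path | str) -> tuple[np.ndarray, float, float, float]:
    """Read one ``.asc`` layer; returns (grid, x_origin, y_llcorner, cell_size)."""
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append(np.array(parts, dtype=float))
    grid = np.vstack(rows)
    if grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"grid shape mismatch in {path}")
    nodata = header.get("nodata_value", NODATA)
    grid[grid == nodata] = np.nan
    return grid, header["xllcorner"], header["yllcorner"], header["cellsize"]


def write_stack(stack: ClimateStack, out_dir: Path | str) -> list[Path]:
    """Write one ``.asc`` file per layer; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    y_ll = stack.y_origin - stack.n_rows * stack.cell_size
    paths = []
    for name, grid in zip(stack.layer_names, stack.values):
        p = out_dir / f"{name}.asc"
        write_ascii_grid(p, grid, stack.x_origin, y_ll, stack.cell_size)
        paths.append(p)
    return paths


def read_stack(paths: list[Path | str] | Path | str) -> ClimateStack:
    """Assemble a stack from ``.asc`` layer files (layer name = file stem).

    A directory may be given instead of a path list; all ``.asc`` files in
    it are read in sorted order.
    """
    if isinstance(paths, (str, Path)) and Path(paths).is_dir():
        paths = sorted(Path(paths).glob("*.asc"))
    paths = [Path(p) for p in paths]  # type: ignore[union-attr]
    if not paths:
        raise ValueError("no .asc layers found")
    names, grids = [], []
    geom = None
    for p in paths:
        grid, x0, yll, d = read_ascii_grid(p)
        g = (x0, yll, d, grid.shape)
        if geom is None:
            geom = g
        elif g != geom:
            raise ValueError(f"layer {p} geometry differs from the first layer")
        names.append(p.stem)
        grids.append(grid)
    x0, yll, d, shape = geom  # type: ignore[misc]
    return ClimateStack(
        layer_names=names,
        values=np.stack(grids),
        x_origin=x0,
        y_origin=yll + shape[0] * d,
        cell_size=d,
    )
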