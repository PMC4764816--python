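"""Covariate raster stack management.

Holds the co-registered environmental predictor layers (scorpan factors:
terrain, climate, spectral bands, position) on one grid definition, computes
the derived predictors (NDVI, north-south folded aspect, coordinate layers),
resamples layers between grids, and extracts covariate vectors at point
locations.

Raster conventions: row 0 is the northernmost row, pixel values refer to
cell centers, and nodata is a single mask shared across all layers (a pixel
missing in any layer is excluded from training and prediction). Layers are
read and written as ESRI ASCII grids with a JSON manifest mapping file to
layer name.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

__all__ = [
    "GridDef", "CovariateStack",
    "compute_ndvi", "fold_aspect", "make_coordinate_layers",
    "resample_to_grid", "extract_at_points",
]

_NODATA = -9999.0


@dataclass(frozen=True)
class GridDef:
    """A regular raster grid; ``x_origin``/``y_origin`` locate the NW corner."""

    n_rows: int
    n_cols: int
    x_origin: float
    y_origin: float
    cell_size: float  # map units (90 m in the mapped products)
    crs_tag: str = "local"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def x_centers(self) -> np.ndarray:
        return self.x_origin + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        return self.y_origin - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the pixel containing map point (x, y)."""
        col = int(np.floor((x - self.x_origin) / self.cell_size))
        row = int(np.floor((self.y_origin - y) / self.cell_size))
        return row, col

    def coord_of(self, row: int, col: int) -> tuple[float, float]:
        """Cell-center (x, y) of pixel (row, col); inverse of index_of."""
        x = self.x_origin + (col + 0.5) * self.cell_size
        y = self.y_origin - (row + 0.5) * self.cell_size
        return x, y

    def contains(self, x: float, y: float) -> bool:
        row, col = self.index_of(x, y)
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols


def compute_ndvi(b3, b4):
    """NDVI = (B4 - B3) / (B4 + B3); NaN where both bands are zero.

    Scale-invariant, so bands may be reflectance or DN. B3 is the visible
    red band, B4 near infrared.
    """
    b3 = np.asarray(b3, dtype=float)
    b4 = np.asarray(b4, dtype=float)
    if np.any(b3 < 0) or np.any(b4 < 0):
        raise ValueError("band values must be >= 0")
    denom = b4 + b3
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (b4 - b3) / np.where(denom > 0, denom, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


def fold_aspect(aspect_deg):
    """Fold compass aspect (0-360 deg) to absolute 0-180 deg from north.

    East- and west-facing slopes map to the same value, leaving a single
    north-to-south exposure axis.
    """
    a = np.asarray(aspect_deg, dtype=float)
    if np.any((a < 0) | (a >= 360)):
        raise ValueError("aspect must lie in [0, 360)")
    out = np.where(a <= 180.0, a, 360.0 - a)
    return float(out) if out.ndim == 0 else out


def make_coordinate_layers(grid: GridDef) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel (Lat, Lon) layers from cell-center coordinates.

    Lat varies along rows (constant within a row), Lon along columns.
    """
    lon = np.broadcast_to(grid.x_centers(), grid.shape).copy()
    lat = np.broadcast_to(grid.y_centers()[:, None], grid.shape).copy()
    return lat, lon


def resample_to_grid(
    layer: np.ndarray,
    src_grid: GridDef,
    dst_grid: GridDef,
    method: str = "bilinear",
) -> np.ndarray:
    """Resample a layer onto another grid (``bilinear`` or ``nearest``).

    Use nearest-neighbour for categorical layers, bilinear for continuous
    ones. NaN nodata is propagated: any destination pixel whose footprint
    touches a NaN source pixel becomes NaN.
    """
    if method not in ("bilinear", "nearest"):
        raise ValueError(f"unknown method {method!r}")
    layer = np.asarray(layer, dtype=float)
    if layer.shape != src_grid.shape:
        raise ValueError("layer shape does not match src_grid")
    # destination cell centers in fractional source-array indices
    dst_x = dst_grid.x_centers()
    dst_y = dst_grid.y_centers()
    col_f = (dst_x - src_grid.x_origin) / src_grid.cell_size - 0.5
    row_f = (src_grid.y_origin - dst_y) / src_grid.cell_size - 0.5
    if (col_f.max() < -0.5 or col_f.min() > src_grid.n_cols - 0.5
            or row_f.max() < -0.5 or row_f.min() > src_grid.n_rows - 0.5):
        raise ValueError("grids have disjoint extents")
    cc, rr = np.meshgrid(col_f, row_f)
    order = 1 if method == "bilinear" else 0
    mask = np.isnan(layer)
    filled = np.where(mask, 0.0, layer)
    out = map_coordinates(filled, [rr, cc], order=order, mode="nearest")
    if mask.any():
        bad = map_coordinates(mask.astype(float), [rr, cc], order=order,
                              mode="nearest")
        out = np.where(bad > 0, np.nan, out)
    return out


class CovariateStack:
    """Named co-registered 2-D covariate layers sharing one grid and mask."""

    def __init__(self, grid: GridDef, layers: dict[str, np.ndarray] | None = None):
        self.grid = grid
        self.layers: dict[str, np.ndarray] = {}
        if layers:
            for name, arr in layers.items():
                self.add_layer(name, arr)

    def add_layer(self, name: str, arr: np.ndarray) -> None:
        arr = np.asarray(arr, dtype=float)
        if arr.shape != self.grid.shape:
            raise ValueError(
                f"layer {name!r} shape {arr.shape} != grid shape {self.grid.shape}"
            )
        self.layers[name] = arr

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def nodata_mask(self) -> np.ndarray:
        """True where any layer is NaN (pixel excluded everywhere)."""
        mask = np.zeros(self.grid.shape, dtype=bool)
        for arr in self.layers.values():
            mask |= np.isnan(arr)
        return mask

    def table(self, names: list[str] | None = None) -> pd.DataFrame:
        """Valid pixels as rows; includes 'row'/'col' index columns."""
        names = names or self.names
        valid = ~self.nodata_mask
        rows, cols = np.nonzero(valid)
        data = {"row": rows, "col": cols}
        for n in names:
            data[n] = self.layers[n][rows, cols]
        return pd.DataFrame(data)

    # -- text raster I/O (ESRI ASCII grid + manifest) -----------------------

    def write(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "grid": {
                "n_rows": self.grid.n_rows, "n_cols": self.grid.n_cols,
                "x_origin": self.grid.x_origin, "y_origin": self.grid.y_origin,
                "cell_size": self.grid.cell_size, "crs_tag": self.grid.crs_tag,
            },
            "layers": {name: f"{name}.asc" for name in self.layers},
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        for name, arr in self.layers.items():
            write_ascii_grid(out_dir / f"{name}.asc", arr, self.grid)

    @classmethod
    def read(cls, in_dir) -> "CovariateStack":
        in_dir = Path(in_dir)
        manifest = json.loads((in_dir / "manifest.json").read_text())
        g = manifest["grid"]
        grid = GridDef(**g)
        stack = cls(grid)
        for name, fname in manifest["layers"].items():
            arr, file_grid = read_ascii_grid(in_dir / fname)
            if file_grid.shape != grid.shape:
                raise ValueError(f"layer {name!r} shape mismatch in {fname}")
            stack.add_layer(name, arr)
        return stack


def write_ascii_grid(path, arr: np.ndarray, grid: GridDef) -> None:
    """Write one layer as an ESRI ASCII grid (NaN -> NODATA)."""
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.x_origin!r}\n"
        f"yllcorner {grid.y_origin - grid.n_rows * grid.cell_size!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {_NODATA}\n"
    )
    body = np.where(np.isnan(arr), _NODATA, arr)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.10g")


def read_ascii_grid(path) -> tuple[np.ndarray, GridDef]:
    with open(path, encoding="utf-8") as fh:
        hdr = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        arr = np.loadtxt(fh)
    arr = np.atleast_2d(arr)
    nodata = hdr.get("nodata_value", _NODATA)
    arr = np.where(arr == nodata, np.nan, arr)
    n_rows, n_cols = int(hdr["nrows"]), int(hdr["ncols"])
    grid = GridDef(
        n_rows=n_rows, n_cols=n_cols,
        x_origin=hdr["xllcorner"],
        y_origin=hdr["yllcorner"] + n_rows * hdr["cellsize"],
        cell_size=hdr["cellsize"],
    )
    return arr.reshape(n_rows, n_cols), grid


def extract_at_points(stack: CovariateStack, sites: pd.DataFrame) -> pd.DataFrame:
    """Covariate vector per site from the containing pixel.

    ``sites`` needs columns ``site_id``, ``lat`` (y) and ``lon`` (x) in the
    grid's CRS. Sites on a nodata pixel get ``nodata=True``; sites outside
    the grid extent raise, listing the offending site ids.
    """
    grid = stack.grid
    outside = [
        str(s.site_id) for s in sites.itertuples()
        if not grid.contains(s.lon, s.lat)
    ]
    if outside:
        raise ValueError(f"sites outside grid extent: {outside}")
    mask = stack.nodata_mask
    records = []
    for s in sites.itertuples():
        row, col = grid.index_of(s.lon, s.lat)
        rec = {"site_id": s.site_id, "row": row, "col": col,
               "nodata": bool(mask[row, col])}
        for name, arr in stack.layers.items():
            rec[name] = arr[row, col]
        records.append(rec)
    return pd.DataFrame(records)
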