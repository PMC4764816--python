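"""Wall-to-wall application of the fitted models: parameter and stock maps.

Applies the trained model set to every valid pixel of a covariate stack,
yielding per-pixel depth-function parameters, then integrates the function
in closed form into SOC stock maps for arbitrary depth layers (including the
per-pixel mattic layer [0, d_mat]), area and total-mass summaries, and
vertical sections. Stocks always come from the closed-form integral; 1-cm
slices are for visualization only.

Soil depth is assumed to reach the integration bottom at every mapped pixel
unless a bedrock-depth raster is supplied to truncate it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from soc3d.covariates import CovariateStack, GridDef
from soc3d.depth_model import DepthFunctionParams, discretize_profile
from soc3d.spatial_model import TrainedModelSet

__all__ = [
    "ParameterMaps", "StockMap",
    "predict_parameter_maps", "map_stock", "total_stock", "mattic_area",
    "relative_stock_report", "vertical_section",
]

KG_PER_TG = 1e9


@dataclass
class ParameterMaps:
    """Per-pixel depth-function parameters on a grid (NaN = nodata)."""

    grid: GridDef
    has_mattic: np.ndarray  # bool, False on nodata pixels
    d_mat: np.ndarray       # m
    c_a: np.ndarray         # kg/m3
    k: np.ndarray           # 1/m
    mask: np.ndarray        # True = nodata

    def __post_init__(self) -> None:
        for name in ("has_mattic", "d_mat", "c_a", "k", "mask"):
            if getattr(self, name).shape != self.grid.shape:
                raise ValueError(f"{name} shape does not match grid")
        valid = ~self.mask
        if np.any(self.c_a[valid] <= 0) or np.any(self.k[valid] <= 0):
            raise ValueError("c_a and k must be positive on valid pixels")
        if np.any(self.d_mat[valid & ~self.has_mattic] != 0):
            raise ValueError("d_mat must be 0 where has_mattic is false")

    def params_at(self, row: int, col: int) -> DepthFunctionParams | None:
        if self.mask[row, col]:
            return None
        return DepthFunctionParams(
            has_mattic=bool(self.has_mattic[row, col]),
            d_mat=float(self.d_mat[row, col]),
            c_a=float(self.c_a[row, col]),
            k=float(self.k[row, col]),
        )


@dataclass
class StockMap:
    """SOC stock (kg/m2) per pixel for one depth layer."""

    grid: GridDef
    values: np.ndarray  # kg/m2, NaN = nodata
    layer: str          # e.g. "0-30 cm", "0-100 cm", "mattic"

    def __post_init__(self) -> None:
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")
        if np.any(self.values[~np.isnan(self.values)] < 0):
            raise ValueError("stocks must be >= 0")


def predict_parameter_maps(
    models: TrainedModelSet, stack: CovariateStack
) -> ParameterMaps:
    """Predict the four parameter layers over every valid pixel."""
    missing = set(models.covariates) - set(stack.names)
    if missing:
        raise ValueError(f"stack lacks covariate layers: {sorted(missing)}")
    grid = stack.grid
    mask = stack.nodata_mask
    rows, cols = np.nonzero(~mask)
    X = np.column_stack(
        [stack.layers[n][rows, cols] for n in models.covariates]
    )
    true_col = list(models.classifier.classes_).index(True)
    p = models.classifier.predict_proba(X)[:, true_col]
    has_mattic_v = p > 0.5
    d_mat_v = np.where(has_mattic_v, np.exp(models.reg_log_dmat.predict(X)), 0.0)
    c_a_v = np.exp(models.reg_log_ca.predict(X))
    k_v = np.exp(models.reg_log_k.predict(X))

    shape = grid.shape
    has_mattic = np.zeros(shape, dtype=bool)
    d_mat = np.full(shape, np.nan)
    c_a = np.full(shape, np.nan)
    k = np.full(shape, np.nan)
    has_mattic[rows, cols] = has_mattic_v
    d_mat[rows, cols] = d_mat_v
    c_a[rows, cols] = c_a_v
    k[rows, cols] = k_v
    d_mat[mask] = 0.0
    c_a[mask] = np.nan
    k[mask] = np.nan
    return ParameterMaps(
        grid=grid, has_mattic=has_mattic, d_mat=d_mat, c_a=c_a, k=k, mask=mask
    )


def _stock_arrays(c_a, k, d_mat, z_top, z_bottom):
    """Vectorized closed-form stock over [z_top, z_bottom] (arrays OK)."""
    plateau = c_a * (np.minimum(z_bottom, d_mat) - np.minimum(z_top, d_mat))
    a = np.maximum(z_top, d_mat)
    b = np.maximum(z_bottom, d_mat)
    decay = (c_a / k) * (np.exp(-k * (a - d_mat)) - np.exp(-k * (b - d_mat)))
    return plateau + decay


def map_stock(pmaps: ParameterMaps, z_top=0.0, z_bottom=1.0,
              layer: str | None = None) -> StockMap:
    """Pixelwise SOC stock map for a depth layer.

    ``layer="mattic"`` integrates [0, d_mat] per pixel (0 where no mattic);
    otherwise the fixed interval [z_top, z_bottom] is used everywhere.
    """
    valid = ~pmaps.mask
    values = np.full(pmaps.grid.shape, np.nan)
    if layer == "mattic":
        values[valid] = pmaps.c_a[valid] * pmaps.d_mat[valid]
        name = "mattic"
    else:
        if not (0 <= z_top < z_bottom):
            raise ValueError(f"need 0 <= z_top < z_bottom, got [{z_top}, {z_bottom}]")
        values[valid] = _stock_arrays(
            pmaps.c_a[valid], pmaps.k[valid], pmaps.d_mat[valid], z_top, z_bottom
        )
        name = layer or f"{z_top * 100:g}-{z_bottom * 100:g} cm"
    return StockMap(grid=pmaps.grid, values=values, layer=name)


def total_stock(smap: StockMap) -> tuple[float, float]:
    """(total mass in Tg, mean stock in kg/m2) over valid pixels.

    Total = sum(stock x pixel area); pixel area = cell_size^2 m2;
    1 Tg = 1e9 kg.
    """
    valid = ~np.isnan(smap.values)
    if not valid.any():
        raise ValueError("all-nodata stock map")
    area = smap.grid.cell_size**2
    total_kg = float(np.sum(smap.values[valid]) * area)
    mean = float(np.mean(smap.values[valid]))
    return total_kg / KG_PER_TG, mean


def mattic_area(pmaps: ParameterMaps) -> float:
    """Area (km2) of pixels classified as mattic-covered."""
    n = int(np.sum(pmaps.has_mattic & ~pmaps.mask))
    return n * pmaps.grid.cell_size**2 / 1e6


def relative_stock_report(
    smaps: list[StockMap], reference: StockMap
) -> pd.DataFrame:
    """Layer summary table: mean kg/m2, total Tg, and % of the reference
    (0-100 cm) total — the standard stock-partition report."""
    ref_total, _ = total_stock(reference)
    if ref_total == 0:
        raise ValueError("reference map has zero total stock")
    rows = []
    for sm in smaps:
        tot, mean = total_stock(sm)
        rows.append({
            "layer": sm.layer,
            "mean_kg_m2": mean,
            "total_Tg": tot,
            "relative_pct": 100.0 * tot / ref_total,
        })
    return pd.DataFrame(rows)


def vertical_section(
    pmaps: ParameterMaps,
    path: list[tuple[int, int]],
    dz: float = 0.01,
    z_max: float = 1.0,
) -> np.ndarray:
    """Depth x distance SOC content array along a pixel path.

    Column j holds :func:`discretize_profile` of path pixel j; nodata pixels
    give NaN columns. Default vertical resolution 1 cm.
    """
    if not path:
        raise ValueError("empty pixel path")
    n_z = round(z_max / dz)
    out = np.full((n_z, len(path)), np.nan)
    for j, (row, col) in enumerate(path):
        params = pmaps.params_at(row, col)
        if params is not None:
            out[:, j] = discretize_profile(params, dz=dz, z_max=z_max)
    return out
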