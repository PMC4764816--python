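"""Accuracy indices and validation protocols for predicted SOC stocks.

Three indices compare predicted (P) with observed (O) stocks:

* mean error  ME = mean(P - O)          (negative = under-prediction),
* root mean square error  RMSE = sqrt(mean((P - O)^2)),
* Lin's concordance correlation coefficient
  LCCC = 2 r s_P s_O / (s_P^2 + s_O^2 + (mean_P - mean_O)^2),
  with population (1/n) variances — 1 only when the points fall exactly on
  the 45 degree identity line.

Two protocols: internal validation compares map predictions at the
calibration sites against stocks integrated from each site's fitted depth
function (optimistic, in-sample); independent validation uses pedons
densely sampled at a 5-cm interval, whose observed stock is the increment
sum soc_volume x 0.05 m. Run-to-run spread comes from re-seeding the forest
training. A Matheron semivariogram of the residuals checks for remaining
spatial structure (a flat variogram means regression kriging cannot help).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from soc3d.covariates import CovariateStack, extract_at_points
from soc3d.depth_model import FitResult, integrate_stock
from soc3d.profile_prep import PedonRecord
from soc3d.spatial_model import TrainedModelSet, predict_parameters, summarize_runs

__all__ = [
    "ValidationPairs",
    "mean_error", "rmse", "lccc",
    "validate_internal", "validate_independent", "repeat_validation",
    "residual_semivariogram",
]


@dataclass
class ValidationPairs:
    """Observed/predicted stock pairs (kg/m2) for one depth layer."""

    site_id: list[str]
    observed: np.ndarray
    predicted: np.ndarray
    layer: tuple[float, float]
    x: np.ndarray | None = None
    y: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=float)
        if self.observed.shape != self.predicted.shape:
            raise ValueError("observed/predicted length mismatch")
        if not (np.isfinite(self.observed).all() and np.isfinite(self.predicted).all()):
            raise ValueError("non-finite values in validation pairs")

    def indices(self) -> dict[str, float]:
        return {"ME": mean_error(self), "RMSE": rmse(self), "LCCC": lccc(self)}


def _vectors(pairs) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pairs, ValidationPairs):
        return pairs.predicted, pairs.observed
    pred, obs = pairs
    return np.asarray(pred, dtype=float), np.asarray(obs, dtype=float)


def mean_error(pairs) -> float:
    """ME = mean(predicted - observed); negative means under-prediction."""
    pred, obs = _vectors(pairs)
    if pred.size == 0:
        raise ValueError("no validation pairs")
    return float(np.mean(pred - obs))


def rmse(pairs) -> float:
    """Root mean square error of predicted vs observed."""
    pred, obs = _vectors(pairs)
    if pred.size == 0:
        raise ValueError("no validation pairs")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def lccc(pairs) -> float:
    """Lin's concordance correlation coefficient (population variances)."""
    pred, obs = _vectors(pairs)
    if pred.size < 2:
        raise ValueError("LCCC needs at least 2 pairs")
    var_p = float(np.var(pred))
    var_o = float(np.var(obs))
    if var_p == 0 and var_o == 0:
        raise ValueError("LCCC undefined: both vectors constant")
    cov = float(np.mean((pred - pred.mean()) * (obs - obs.mean())))
    return 2.0 * cov / (var_p + var_o + (pred.mean() - obs.mean()) ** 2)


def _predict_stocks_at_sites(
    models: TrainedModelSet,
    pedons: list[PedonRecord],
    stack: CovariateStack,
    layer: tuple[float, float],
) -> np.ndarray:
    sites = pd.DataFrame(
        {"site_id": [p.site_id for p in pedons],
         "lat": [p.lat for p in pedons],
         "lon": [p.lon for p in pedons]}
    )
    cov = extract_at_points(stack, sites)
    if cov["nodata"].any():
        bad = cov.loc[cov["nodata"], "site_id"].tolist()
        raise ValueError(f"validation sites on nodata pixels: {bad}")
    params = predict_parameters(models, cov)
    return np.array([integrate_stock(p, layer[0], layer[1]) for p in params])


def validate_internal(
    models: TrainedModelSet,
    pedons: list[PedonRecord],
    fits: list[FitResult],
    stack: CovariateStack,
    layer: tuple[float, float] = (0.0, 1.0),
) -> ValidationPairs:
    """In-sample validation at the calibration sites.

    Observed stock integrates each site's *fitted* depth function over the
    layer; predicted stock applies the trained models to the covariates of
    the site's pixel (identical to reading the stock map there).
    """
    if len(pedons) != len(fits):
        raise ValueError("pedons and fits must align")
    observed = np.array(
        [integrate_stock(f.params, layer[0], layer[1]) for f in fits]
    )
    predicted = _predict_stocks_at_sites(models, pedons, stack, layer)
    return ValidationPairs(
        site_id=[p.site_id for p in pedons],
        observed=observed, predicted=predicted, layer=layer,
        x=np.array([p.lon for p in pedons]),
        y=np.array([p.lat for p in pedons]),
    )


def observed_stock_from_increments(
    pedon: PedonRecord, layer: tuple[float, float]
) -> float:
    """Increment-sum stock of a densely sampled pedon over a layer.

    Sums soc_volume x thickness over the contiguous depth increments
    covering [layer]; raises if coverage has gaps.
    """
    z_top, z_bottom = layer
    if not z_top < z_bottom:
        raise ValueError("empty validation layer")
    covered = z_top
    stock = 0.0
    for h in pedon.horizons:
        if h.bottom <= z_top or h.top >= z_bottom:
            continue
        if h.top > covered + 1e-9:
            raise ValueError(
                f"pedon {pedon.site_id}: gap in increment coverage at {covered} m"
            )
        lo, hi = max(h.top, z_top), min(h.bottom, z_bottom)
        stock += h.soc_volume * (hi - lo)
        covered = max(covered, hi)
    if covered < z_bottom - 1e-9:
        raise ValueError(
            f"pedon {pedon.site_id}: increments end at {covered} m < {z_bottom} m"
        )
    return stock


def validate_independent(
    models: TrainedModelSet,
    dense_pedons: list[PedonRecord],
    stack: CovariateStack,
    layer: tuple[float, float] = (0.0, 1.0),
) -> ValidationPairs:
    """Validation against pedons sampled at a fixed (5-cm) depth interval.

    Observed stocks are increment sums, never depth-function fits, so the
    comparison is independent of the functional form.
    """
    observed = np.array(
        [observed_stock_from_increments(p, layer) for p in dense_pedons]
    )
    predicted = _predict_stocks_at_sites(models, dense_pedons, stack, layer)
    return ValidationPairs(
        site_id=[p.site_id for p in dense_pedons],
        observed=observed, predicted=predicted, layer=layer,
        x=np.array([p.lon for p in dense_pedons]),
        y=np.array([p.lat for p in dense_pedons]),
    )


def repeat_validation(
    procedure: Callable[[int], ValidationPairs],
    n_runs: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Re-train and re-validate across seeds; summarize each index.

    ``procedure(seed)`` runs one full train-validate cycle. Returns a table
    with one row per index (ME, RMSE, LCCC) and the seven order statistics.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    per_index: dict[str, list[float]] = {"ME": [], "RMSE": [], "LCCC": []}
    for i in range(n_runs):
        pairs = procedure(seed + i)
        for name, value in pairs.indices().items():
            per_index[name].append(value)
    rows = []
    for name, values in per_index.items():
        rows.append({"index": name, **summarize_runs(values)})
    return pd.DataFrame(rows)


def residual_semivariogram(
    pairs: ValidationPairs, lag_bins: np.ndarray
) -> pd.DataFrame:
    """Classical Matheron semivariogram of the prediction residuals.

    gamma(h) = (1 / 2N(h)) sum (r_i - r_j)^2 over point pairs whose
    separation falls in each lag bin. A flat variogram indicates no
    remaining spatial structure in the residuals.
    """
    if pairs.x is None or pairs.y is None:
        raise ValueError("pairs lack coordinates")
    n = pairs.observed.size
    if n < 10:
        raise ValueError("need >= 10 located residuals")
    resid = pairs.predicted - pairs.observed
    pts = np.column_stack([pairs.x, pairs.y])
    d = pdist(pts)
    sq = pdist(resid[:, None], metric="sqeuclidean")
    lag_bins = np.asarray(lag_bins, dtype=float)
    rows = []
    for lo, hi in zip(lag_bins[:-1], lag_bins[1:]):
        sel = (d >= lo) & (d < hi)
        n_pairs = int(sel.sum())
        gamma = float(sq[sel].mean() / 2.0) if n_pairs else np.nan
        rows.append({"lag": 0.5 * (lo + hi), "gamma": gamma, "n_pairs": n_pairs})
    out = pd.DataFrame(rows)
    if (out["n_pairs"] < 2).all():
        raise ValueError("fewer than 2 pairs in every lag bin")
    return out
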