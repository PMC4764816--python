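"""Seeded synthetic study area for end-to-end pipeline testing.

No pedon or raster data from a real survey ship with this package, so every
pipeline stage is exercised against a simulated alpine-grassland landscape
whose generating process is known exactly:

* spatially smooth covariates on a 90-m-style grid (Gaussian-filtered white
  noise): elevation with a linked temperature lapse and precipitation
  gradient, NDVI with consistent red/NIR bands, and independent terrain
  attributes;
* latent depth-function parameter fields with stated link functions —
  mattic occurrence from a logistic link on standardized NDVI and MAT,
  log-linear fields for mattic depth, C_a and k;
* calibration pedons sampled by genetic horizons (horizon value = the true
  function's depth average, times multiplicative lognormal noise) and dense
  validation pedons at a 5-cm interval;
* analytic truth summaries (true parameter maps, stock maps, totals) as
  recovery targets.

Default magnitudes mirror a high-alpine meadow survey: ~40% mattic
prevalence, mattic depth around 0.14 m, surface contents in the 20-45 kg/m3
range, decay rates around 2.3 /m. Everything is drawn from one seeded
generator hierarchy, so a master seed reproduces the bundle bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

from soc3d.covariates import CovariateStack, GridDef, compute_ndvi, make_coordinate_layers
from soc3d.depth_model import DepthFunctionParams, integrate_stock
from soc3d.mapping import ParameterMaps, StockMap, map_stock
from soc3d.profile_prep import HorizonSample, PedonRecord, PTFConfig

__all__ = [
    "SimConfig", "TruthBundle",
    "simulate_covariates", "simulate_parameter_fields", "sample_pedons",
    "truth_summary", "make_truth_bundle",
]

COVARIATE_NAMES = [
    "elevation", "aspect", "slope", "SL", "Plan_cur", "Prof_cur", "CA",
    "TWI", "MrVBF", "VD", "MAT", "MAP", "B3", "B4", "B5", "NDVI",
    "Lat", "Lon",
]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults define the standard test conditions."""

    n_rows: int = 200
    n_cols: int = 200
    cell_size: float = 90.0          # m
    smooth_sigma: float = 25.0       # px, autocorrelation range of the fields
    n_calibration_sites: int = 96
    n_independent_pedons: int = 3

    # mattic occurrence: logit P = b0 + b1*NDVI_std + b2*MAT_std
    beta: tuple[float, float, float] = (-0.5, 3.0, -1.5)
    # log d_mat = g0 + g1*NDVI_std + N(0, g_sd); clipped to d_mat_range
    gamma: tuple[float, float] = (-1.966, 0.20)   # exp(-1.966) ~ 0.14 m
    gamma_sd: float = 0.05
    d_mat_range: tuple[float, float] = (0.06, 0.30)
    # log c_a = d0 + d1*NDVI_std + d2*elev_std + N(0, d_sd); clipped
    delta: tuple[float, float, float] = (3.30, 0.60, -0.20)  # exp(3.30) ~ 27
    delta_sd: float = 0.18
    c_a_range: tuple[float, float] = (5.0, 100.0)
    # log k = e0 + e1*MAT_std + N(0, e_sd); clipped
    eta: tuple[float, float] = (0.83, 0.45)       # exp(0.83) ~ 2.3 /m
    eta_sd: float = 0.18
    k_range: tuple[float, float] = (0.2, 10.0)

    # genetic-horizon sampling
    first_thickness: tuple[float, float] = (0.12, 0.03)  # mean, SD (m)
    later_thickness: tuple[float, float] = (0.20, 0.05)
    profile_depth: float = 1.0       # m, minimum described depth
    dense_interval: float = 0.05     # m, independent-pedon increment
    cv: float = 0.10                 # multiplicative lognormal noise CV
    flag_error_rate: float = 0.0     # P(mattic flag recorded wrongly)
    seed: int = 0

    def grid(self) -> GridDef:
        return GridDef(
            n_rows=self.n_rows, n_cols=self.n_cols,
            x_origin=0.0, y_origin=self.n_rows * self.cell_size,
            cell_size=self.cell_size, crs_tag="synthetic-local",
        )


def _smooth_field(rng: np.random.Generator, shape, sigma) -> np.ndarray:
    """Standardized Gaussian-filtered white noise (mean 0, SD 1)."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    return (f - f.mean()) / f.std()


def _standardize(a: np.ndarray) -> np.ndarray:
    return (a - a.mean()) / a.std()


def simulate_covariates(cfg: SimConfig, seed: int | None = None) -> CovariateStack:
    """Generate the full covariate stack for one landscape realization."""
    master = cfg.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([master, 0]))
    grid = cfg.grid()
    shape = grid.shape
    sg = cfg.smooth_sigma

    elevation = 3000.0 + 600.0 * _smooth_field(rng, shape, sg)
    # temperature lapse ~ -6.5 K/km plus local smooth noise
    mat = 2.0 - 0.0065 * (elevation - 3000.0) + 0.5 * _smooth_field(rng, shape, sg)
    mapr = 300.0 + 0.05 * (elevation - 3000.0) + 20.0 * _smooth_field(rng, shape, sg)
    ndvi = np.clip(0.45 + 0.22 * _smooth_field(rng, shape, sg), -1.0, 1.0)
    # red/NIR bands back-solved so that compute_ndvi reproduces the NDVI field
    total = 0.5 + 0.05 * _smooth_field(rng, shape, sg)
    total = np.clip(total, 0.1, None)
    b4 = total * (1.0 + ndvi) / 2.0
    b3 = total * (1.0 - ndvi) / 2.0
    b5 = np.clip(0.25 + 0.05 * _smooth_field(rng, shape, sg), 0.01, None)
    aspect = np.abs(180.0 * _smooth_field(rng, shape, sg) / 2.5)
    aspect = np.clip(aspect, 0.0, 180.0)  # already folded north-south
    lat, lon = make_coordinate_layers(grid)

    stack = CovariateStack(grid)
    stack.add_layer("elevation", elevation)
    stack.add_layer("aspect", aspect)
    for name, (offset, scale) in {
        "slope": (8.0, 4.0), "SL": (50.0, 20.0),
        "Plan_cur": (0.0, 1.0), "Prof_cur": (0.0, 1.0),
        "CA": (1000.0, 400.0), "TWI": (8.0, 2.0),
        "MrVBF": (2.0, 1.0), "VD": (40.0, 15.0),
    }.items():
        stack.add_layer(name, offset + scale * _smooth_field(rng, shape, sg))
    stack.add_layer("MAT", mat)
    stack.add_layer("MAP", mapr)
    stack.add_layer("B3", b3)
    stack.add_layer("B4", b4)
    stack.add_layer("B5", b5)
    stack.add_layer("NDVI", compute_ndvi(b3, b4))
    stack.add_layer("Lat", lat)
    stack.add_layer("Lon", lon)
    return stack


def simulate_parameter_fields(
    stack: CovariateStack, cfg: SimConfig, seed: int | None = None
) -> ParameterMaps:
    """Draw the true depth-function parameter fields from the link models."""
    master = cfg.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([master, 1]))
    shape = stack.grid.shape
    ndvi_s = _standardize(stack.layers["NDVI"])
    mat_s = _standardize(stack.layers["MAT"])
    elev_s = _standardize(stack.layers["elevation"])

    b0, b1, b2 = cfg.beta
    p_mattic = 1.0 / (1.0 + np.exp(-(b0 + b1 * ndvi_s + b2 * mat_s)))
    has_mattic = rng.random(shape) < p_mattic

    g0, g1 = cfg.gamma
    d_mat = np.exp(g0 + g1 * ndvi_s + rng.normal(0.0, cfg.gamma_sd, shape))
    d_mat = np.clip(d_mat, *cfg.d_mat_range)
    d_mat = np.where(has_mattic, d_mat, 0.0)

    d0, d1, d2 = cfg.delta
    c_a = np.exp(d0 + d1 * ndvi_s + d2 * elev_s
                 + rng.normal(0.0, cfg.delta_sd, shape))
    c_a = np.clip(c_a, *cfg.c_a_range)

    e0, e1 = cfg.eta
    k = np.exp(e0 + e1 * mat_s + rng.normal(0.0, cfg.eta_sd, shape))
    k = np.clip(k, *cfg.k_range)

    return ParameterMaps(
        grid=stack.grid, has_mattic=has_mattic, d_mat=d_mat,
        c_a=c_a, k=k, mask=stack.nodata_mask.copy(),
    )


_PTF = PTFConfig()


def _soc_mass_for_volume(soc_volume: float) -> float:
    """Invert Cv = Cm * BD(Cm) (gravel-free) for the mass content Cm.

    The product m * (a0 + a1 exp(-a2 m)) is strictly increasing for the
    default PTF coefficients, so the root is unique.
    """
    if soc_volume <= 0:
        return 0.0

    def f(m):
        return m * (_PTF.a0 + _PTF.a1 * np.exp(-_PTF.a2 * m)) - soc_volume

    hi = max(soc_volume / _PTF.a0, 1.0)
    return brentq(f, 0.0, hi, xtol=1e-10)


def _noisy_horizon(params, top, bottom, rng, cv) -> HorizonSample:
    true_mean = integrate_stock(params, top, bottom) / (bottom - top)
    if cv > 0:
        s = np.sqrt(np.log1p(cv**2))
        noise = np.exp(rng.normal(-0.5 * s * s, s))  # mean-1 lognormal
    else:
        noise = 1.0
    soc_volume = true_mean * noise
    soc_mass = _soc_mass_for_volume(soc_volume)
    bd = _PTF.a0 + _PTF.a1 * np.exp(-_PTF.a2 * soc_mass)
    hz = HorizonSample(
        top=top, bottom=bottom, soc_mass=soc_mass,
        bulk_density=bd, gravel_frac=0.0,
    )
    hz.soc_volume = soc_volume
    return hz


def _horizon_boundaries(params, cfg: SimConfig, rng) -> list[float]:
    bounds = [0.0]
    if params.has_mattic:
        bounds.append(params.d_mat)
    else:
        m, s = cfg.first_thickness
        bounds.append(max(0.05, rng.normal(m, s)))
    while bounds[-1] < cfg.profile_depth:
        m, s = cfg.later_thickness
        bounds.append(bounds[-1] + float(np.clip(rng.normal(m, s), 0.08, 0.40)))
    return bounds


def _pedon_at(site_id, pmaps, cfg, row, col, rng, dense: bool) -> PedonRecord:
    params = pmaps.params_at(row, col)
    x, y = pmaps.grid.coord_of(row, col)
    if dense:
        n = round(cfg.profile_depth / cfg.dense_interval)
        bounds = [i * cfg.dense_interval for i in range(n + 1)]
    else:
        bounds = _horizon_boundaries(params, cfg, rng)
    horizons = [
        _noisy_horizon(params, t, b, rng, cfg.cv)
        for t, b in zip(bounds[:-1], bounds[1:])
    ]
    has_mattic = params.has_mattic
    if cfg.flag_error_rate > 0 and rng.random() < cfg.flag_error_rate:
        has_mattic = not has_mattic
    if has_mattic and not params.has_mattic:
        mattic_depth = 0.10  # wrongly flagged: nominal depth
    else:
        mattic_depth = params.d_mat if has_mattic else None
    return PedonRecord(
        site_id=site_id, lat=y, lon=x, horizons=horizons,
        has_mattic=has_mattic, mattic_depth=mattic_depth,
    )


def sample_pedons(
    pmaps: ParameterMaps, stack: CovariateStack, cfg: SimConfig,
    seed: int | None = None,
) -> tuple[list[PedonRecord], list[PedonRecord]]:
    """Sample calibration and dense validation pedons from the truth fields.

    Calibration sites are drawn uniformly over valid pixels without
    replacement; the dense validation pedons are placed purposively, one per
    NDVI stratum (equal-count bins of the vegetation gradient), emulating a
    survey design that spreads its few independent sites across contrasting
    conditions. Calibration pedons carry genetic horizons down to >= 1 m
    whose value is the horizon-averaged true content with multiplicative
    lognormal noise; dense pedons are contiguous 5-cm increments with the
    same noise model.
    """
    master = cfg.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([master, 2]))
    valid = np.nonzero(~pmaps.mask)
    n_valid = valid[0].size
    n_total = cfg.n_calibration_sites + cfg.n_independent_pedons
    if n_total > n_valid:
        raise ValueError(f"requested {n_total} sites but only {n_valid} valid pixels")
    pick = rng.choice(n_valid, size=cfg.n_calibration_sites, replace=False)
    cal = []
    for j, idx in enumerate(pick):
        row, col = int(valid[0][idx]), int(valid[1][idx])
        cal.append(_pedon_at(f"cal{j:03d}", pmaps, cfg, row, col, rng, False))
    # purposive placement of the dense pedons, one per equal-count NDVI
    # stratum, spreading the few independent sites across contrasting
    # vegetation conditions
    taken = set(pick.tolist())
    ndvi_valid = stack.layers["NDVI"][valid]
    order = np.argsort(ndvi_valid, kind="mergesort")
    strata = np.array_split(order, cfg.n_independent_pedons)
    dense = []
    for i, stratum in enumerate(strata):
        while True:
            idx = int(stratum[rng.integers(stratum.size)])
            if idx not in taken:
                taken.add(idx)
                break
        row, col = int(valid[0][idx]), int(valid[1][idx])
        dense.append(_pedon_at(f"val{i:03d}", pmaps, cfg, row, col, rng, True))
    return cal, dense


STANDARD_LAYERS = [("mattic", None), ("0-30 cm", (0.0, 0.3)),
                   ("0-50 cm", (0.0, 0.5)), ("0-100 cm", (0.0, 1.0))]


@dataclass
class TruthBundle:
    """Everything one seeded realization produced, truth included."""

    cfg: SimConfig
    seed: int
    stack: CovariateStack
    true_params: ParameterMaps
    calibration_pedons: list[PedonRecord]
    dense_pedons: list[PedonRecord]
    true_stocks: dict[str, StockMap] = field(default_factory=dict)


def make_truth_bundle(cfg: SimConfig = SimConfig(), seed: int | None = None) -> TruthBundle:
    """Run the full generator: covariates, truth fields, pedons, stock maps."""
    master = cfg.seed if seed is None else seed
    stack = simulate_covariates(cfg, master)
    pmaps = simulate_parameter_fields(stack, cfg, master)
    cal, dense = sample_pedons(pmaps, stack, cfg, master)
    stocks = {}
    for name, interval in STANDARD_LAYERS:
        if interval is None:
            stocks[name] = map_stock(pmaps, layer="mattic")
        else:
            stocks[name] = map_stock(pmaps, *interval, layer=name)
    return TruthBundle(
        cfg=cfg, seed=master, stack=stack, true_params=pmaps,
        calibration_pedons=cal, dense_pedons=dense, true_stocks=stocks,
    )


def truth_summary(bundle: TruthBundle):
    """Analytic truth twin of the stock-partition report.

    Returns (table, mattic_area_km2) computed from the true parameter maps
    through the same mapping operations used for predictions.
    """
    from soc3d.mapping import mattic_area, relative_stock_report

    smaps = [bundle.true_stocks[name] for name, _ in STANDARD_LAYERS]
    table = relative_stock_report(smaps, bundle.true_stocks["0-100 cm"])
    return table, mattic_area(bundle.true_params)
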