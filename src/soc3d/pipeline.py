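"""End-to-end orchestration: simulate -> fit -> train -> map -> validate.

Glue used by the command-line interface, the test suite and the acceptance
script. One :func:`run_pipeline` call executes the whole mapping workflow on
a seeded synthetic landscape and returns predictions, summaries and
validation indices alongside the generator's analytic truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from soc3d.covariates import extract_at_points
from soc3d.depth_model import FitResult, fit_depth_function
from soc3d.mapping import (
    ParameterMaps, StockMap, map_stock, mattic_area, predict_parameter_maps,
    relative_stock_report, total_stock,
)
from soc3d.profile_prep import PedonRecord
from soc3d.spatial_model import RFConfig, TrainedModelSet, train_model_set
from soc3d.synthetic_data import (
    COVARIATE_NAMES, STANDARD_LAYERS, SimConfig, TruthBundle,
    make_truth_bundle, truth_summary,
)
from soc3d.validation import ValidationPairs, validate_independent, validate_internal

__all__ = ["PipelineResult", "build_site_table", "run_pipeline"]


@dataclass
class PipelineResult:
    bundle: TruthBundle
    fits: list[FitResult]
    models: TrainedModelSet
    pred_params: ParameterMaps
    stock_maps: dict[str, StockMap]
    report: pd.DataFrame            # predicted stock-partition table
    truth_report: pd.DataFrame      # analytic truth twin
    mattic_area_km2: float
    true_mattic_area_km2: float
    internal: ValidationPairs
    independent: ValidationPairs
    site_table: pd.DataFrame = field(repr=False, default=None)

    @property
    def internal_indices(self) -> dict[str, float]:
        return self.internal.indices()

    @property
    def independent_indices(self) -> dict[str, float]:
        return self.independent.indices()


def build_site_table(
    pedons: list[PedonRecord],
    fits: list[FitResult],
    stack,
) -> pd.DataFrame:
    """Covariates at each site joined with its fitted depth-function targets."""
    sites = pd.DataFrame({
        "site_id": [p.site_id for p in pedons],
        "lat": [p.lat for p in pedons],
        "lon": [p.lon for p in pedons],
    })
    table = extract_at_points(stack, sites)
    table["has_mattic"] = [p.has_mattic for p in pedons]
    table["d_mat"] = [p.mattic_depth if p.has_mattic else np.nan for p in pedons]
    table["c_a"] = [f.params.c_a for f in fits]
    table["k"] = [f.params.k for f in fits]
    return table


def run_pipeline(
    seed: int,
    cfg: SimConfig = SimConfig(),
    rf_cfg: RFConfig = RFConfig(),
    layer: tuple[float, float] = (0.0, 1.0),
) -> PipelineResult:
    """Full workflow on one synthetic realization under one master seed."""
    bundle = make_truth_bundle(cfg, seed)
    fits = [fit_depth_function(p) for p in bundle.calibration_pedons]
    site_table = build_site_table(bundle.calibration_pedons, fits, bundle.stack)
    models = train_model_set(site_table, COVARIATE_NAMES, rf_cfg, seed=seed)
    pred = predict_parameter_maps(models, bundle.stack)

    stock_maps: dict[str, StockMap] = {}
    for name, interval in STANDARD_LAYERS:
        if interval is None:
            stock_maps[name] = map_stock(pred, layer="mattic")
        else:
            stock_maps[name] = map_stock(pred, *interval, layer=name)
    report = relative_stock_report(
        [stock_maps[n] for n, _ in STANDARD_LAYERS], stock_maps["0-100 cm"]
    )
    truth_report, true_area = truth_summary(bundle)

    internal = validate_internal(
        models, bundle.calibration_pedons, fits, bundle.stack, layer
    )
    independent = validate_independent(
        models, bundle.dense_pedons, bundle.stack, layer
    )
    return PipelineResult(
        bundle=bundle, fits=fits, models=models, pred_params=pred,
        stock_maps=stock_maps, report=report, truth_report=truth_report,
        mattic_area_km2=mattic_area(pred), true_mattic_area_km2=true_area,
        internal=internal, independent=independent, site_table=site_table,
    )
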