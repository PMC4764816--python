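import numpy as np
import pytest

from soc3d.covariates import CovariateStack, GridDef
from soc3d.depth_model import DepthFunctionParams
from soc3d.profile_prep import HorizonSample, PedonRecord
from soc3d.synthetic_data import SimConfig, make_truth_bundle


def random_params(rng, k_max=5.0, k_min=0.2) -> DepthFunctionParams:
    """Random depth-function parameters in the realistic alpine range."""
    has = bool(rng.random() < 0.5)
    return DepthFunctionParams(
        has_mattic=has,
        d_mat=float(rng.uniform(0.06, 0.30)) if has else 0.0,
        c_a=float(np.exp(rng.uniform(np.log(5.0), np.log(100.0)))),
        k=float(np.exp(rng.uniform(np.log(k_min), np.log(k_max)))),
    )


def profile_from_params(params, midpoints, site_id="p1", lat=0.0, lon=0.0):
    """Noiseless pedon whose horizon values sit exactly on the function."""
    from soc3d.depth_model import evaluate_soc

    horizons = []
    for m in midpoints:
        half = min(0.04, m)
        hz = HorizonSample(top=m - half, bottom=m + half, soc_mass=1.0,
                          bulk_density=1.0)
        hz.soc_volume = float(evaluate_soc(params, m))
        horizons.append(hz)
    return PedonRecord(
        site_id=site_id, lat=lat, lon=lon, horizons=horizons,
        has_mattic=params.has_mattic,
        mattic_depth=params.d_mat if params.has_mattic else None,
        max_depth=max(midpoints) + 0.1,
    )


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced landscape for fast end-to-end tests."""
    return SimConfig(n_rows=60, n_cols=60, smooth_sigma=8.0,
                     n_calibration_sites=60, seed=0)


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    return make_truth_bundle(small_cfg, seed=42)


@pytest.fixture
def tiny_grid():
    return GridDef(n_rows=4, n_cols=5, x_origin=0.0, y_origin=360.0,
                   cell_size=90.0)


@pytest.fixture
def tiny_stack(tiny_grid):
    rng = np.random.default_rng(3)
    stack = CovariateStack(tiny_grid)
    stack.add_layer("a", rng.random(tiny_grid.shape))
    stack.add_layer("b", rng.random(tiny_grid.shape))
    return stack
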