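"""Step-wise exponential SOC depth function.

The vertical distribution of volumetric SOC content C_v(z) (kg/m3) in a
profile is modelled as a plateau within the mattic epipedon followed by
exponential decay below it:

    C_v(z) = C_a                       for z <= d_mat
    C_v(z) = C_a * exp(-k (z - d_mat)) for z >  d_mat

with d_mat = 0 for profiles without a mattic epipedon (pure exponential
decay from the surface). Anchoring the decay at d_mat makes the function
continuous and identifies the surface content C_a with the mattic-layer
content C_mat. Four parameters describe a profile: mattic occurrence
(categorical), mattic depth d_mat (m), C_a (kg/m3) and decay rate k (1/m).

Stocks over a depth interval are available in closed form, so mapped stocks
never depend on vertical discretization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import least_squares

from soc3d.profile_prep import PedonRecord

__all__ = [
    "DepthFunctionParams", "FitResult",
    "evaluate_soc", "fit_depth_function", "integrate_stock",
    "discretize_profile", "IdentifiabilityError",
]

# optimizer bounds; generous relative to alpine-soil magnitudes
K_BOUNDS = (1e-3, 50.0)     # 1/m
CA_BOUNDS = (1e-3, 500.0)   # kg/m3


class IdentifiabilityError(ValueError):
    """Too few informative depths to determine (c_a, k)."""


@dataclass(frozen=True)
class DepthFunctionParams:
    """The four depth-function parameters at a site or pixel."""

    has_mattic: bool
    d_mat: float  # m; 0 iff no mattic
    c_a: float    # kg/m3, surface SOC content (= C_mat when mattic present)
    k: float      # 1/m, decay rate below the plateau

    def __post_init__(self) -> None:
        if self.c_a <= 0:
            raise ValueError(f"c_a must be > 0, got {self.c_a}")
        if self.k <= 0:
            raise ValueError(f"k must be > 0, got {self.k}")
        if self.has_mattic != (self.d_mat > 0):
            raise ValueError(
                f"d_mat must be > 0 iff has_mattic (got d_mat={self.d_mat}, "
                f"has_mattic={self.has_mattic})"
            )
        if self.d_mat < 0:
            raise ValueError("d_mat must be >= 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "DepthFunctionParams":
        return cls(**json.loads(text))


@dataclass
class FitResult:
    """Per-profile least-squares fit of (c_a, k)."""

    params: DepthFunctionParams
    r_squared: float
    n_obs: int
    residuals: np.ndarray  # observed - fitted, kg/m3 per horizon


def evaluate_soc(params: DepthFunctionParams, z) -> np.ndarray | float:
    """Volumetric SOC content (kg/m3) at depth ``z`` (m, scalar or array)."""
    z_arr = np.asarray(z, dtype=float)
    if np.any(z_arr < 0):
        raise ValueError("depth z must be >= 0")
    out = np.where(
        z_arr <= params.d_mat,
        params.c_a,
        params.c_a * np.exp(-params.k * (z_arr - params.d_mat)),
    )
    return float(out) if np.isscalar(z) or out.ndim == 0 else out


def integrate_stock(
    params: DepthFunctionParams, z_top: float, z_bottom: float
) -> float:
    """SOC stock (kg/m2) over [z_top, z_bottom], in closed form.

    Plateau part: c_a * overlap of [z_top, z_bottom] with [0, d_mat];
    decay part: (c_a / k) * (e^{-k(a - d_mat)} - e^{-k(b - d_mat)}) with
    a, b the interval clipped below d_mat. Matches numerical quadrature of
    :func:`evaluate_soc` to <= 1e-8 relative.
    """
    if not (0 <= z_top < z_bottom):
        raise ValueError(f"need 0 <= z_top < z_bottom, got [{z_top}, {z_bottom}]")
    d, k, c_a = params.d_mat, params.k, params.c_a
    plateau = c_a * (min(z_bottom, d) - min(z_top, d))
    a = max(z_top, d)
    b = max(z_bottom, d)
    decay = (c_a / k) * (np.exp(-k * (a - d)) - np.exp(-k * (b - d)))
    return float(plateau + decay)


def mean_soc_over(params: DepthFunctionParams, z_top: float, z_bottom: float) -> float:
    """Depth-averaged SOC content (kg/m3) over an interval (stock/thickness)."""
    return integrate_stock(params, z_top, z_bottom) / (z_bottom - z_top)


def discretize_profile(
    params: DepthFunctionParams, dz: float = 0.01, z_max: float = 1.0
) -> np.ndarray:
    """SOC content per ``dz``-thick slice down to ``z_max`` (midpoint values).

    For visualization (vertical sections); stocks use :func:`integrate_stock`.
    """
    if dz <= 0:
        raise ValueError("dz must be > 0")
    n = z_max / dz
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"z_max={z_max} must be a multiple of dz={dz}")
    mids = (np.arange(round(n)) + 0.5) * dz
    return np.asarray(evaluate_soc(params, mids))


def _two_point_init(z1: float, v1: float, z2: float, v2: float, d_mat: float):
    """Closed-form (c_a, k) through two sub-plateau observations.

    k = ln(v1/v2) / (z2 - z1); c_a back-extrapolated to d_mat.
    Used to initialize the optimizer deterministically.
    """
    if v1 <= 0 or v2 <= 0 or v1 <= v2:
        return None
    k = np.log(v1 / v2) / (z2 - z1)
    c_a = v1 * np.exp(k * (z1 - d_mat))
    return float(c_a), float(k)


def fit_depth_function(pedon: PedonRecord) -> FitResult:
    """Fit (c_a, k) to a pedon's horizon soc_volume by nonlinear least squares.

    Mattic occurrence and d_mat come from the field record and are held
    fixed. Horizons are located at their interval midpoints. When a mattic
    layer is present, within-plateau observations are fitted by the constant
    c_a, so c_a couples both segments. R2 = 1 - SSE/SST with SST about the
    observed mean.
    """
    d_mat = pedon.mattic_depth if pedon.has_mattic else 0.0
    z = np.array([h.midpoint for h in pedon.horizons])
    y = np.array([h.soc_volume for h in pedon.horizons])
    below = z > d_mat
    n_below = int(below.sum())
    if pedon.has_mattic:
        if n_below < 2 or (~below).sum() < 1:
            raise IdentifiabilityError(
                f"pedon {pedon.site_id}: need >=1 midpoint within and >=2 below "
                f"the mattic layer (got {int((~below).sum())} within, {n_below} below)"
            )
    elif n_below < 2 or len(np.unique(z)) < 2:
        raise IdentifiabilityError(
            f"pedon {pedon.site_id}: need >= 2 distinct midpoints, got {len(z)}"
        )

    zb = z[below]
    yb = y[below]
    i_lo, i_hi = int(np.argmin(zb)), int(np.argmax(zb))
    init = _two_point_init(zb[i_lo], yb[i_lo], zb[i_hi], yb[i_hi], d_mat)
    if init is None:
        init = (max(y.max(), 1.0), 1.0)
    c0 = float(np.clip(init[0], *CA_BOUNDS))
    k0 = float(np.clip(init[1], *K_BOUNDS))

    def resid(theta):
        c_a, k = theta
        pred = np.where(z <= d_mat, c_a, c_a * np.exp(-k * (z - d_mat)))
        return pred - y

    sol = least_squares(
        resid, x0=[c0, k0],
        bounds=([CA_BOUNDS[0], K_BOUNDS[0]], [CA_BOUNDS[1], K_BOUNDS[1]]),
        method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    c_a, k = map(float, sol.x)
    if not (c_a > 0 and k > 0):
        raise RuntimeError(
            f"pedon {pedon.site_id}: fit returned non-positive parameters "
            f"(c_a={c_a}, k={k}); status={sol.status}"
        )
    params = DepthFunctionParams(
        has_mattic=pedon.has_mattic, d_mat=float(d_mat), c_a=c_a, k=k
    )
    residuals = y - np.asarray(evaluate_soc(params, z))
    sse = float(np.sum(residuals**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else -np.inf)
    return FitResult(params=params, r_squared=r2, n_obs=len(y), residuals=residuals)
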