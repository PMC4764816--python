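"""Pedon ingestion and horizon-level unit handling.

Reads per-horizon soil profile tables, fills missing bulk density with an
exponential pedo-transfer function (PTF), converts SOC from mass basis
(g C per kg fine earth) to volume basis (kg C per m3 of soil) with a gravel
correction, and checks the measurable mattic-epipedon criteria.

Depth convention: meters, positive downward; horizon intervals are half-open
[top, bottom). Measured bulk density always takes precedence over the PTF.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "HorizonSample", "PedonRecord", "PTFConfig",
    "estimate_bd_ptf", "soc_mass_to_volume", "check_mattic_criteria",
    "read_pedons", "write_pedons",
    "PedonError",
]

#: Minimum thickness (m) a root-mat layer must exceed to qualify as a
#: mattic epipedon.
MATTIC_MIN_THICKNESS = 0.05

#: Diagnostic bulk-density window (g/cm3) for the mattic epipedon.
MATTIC_BD_RANGE = (0.5, 1.1)


class PedonError(ValueError):
    """Invalid pedon input (inverted depths, bad units, missing fields)."""


@dataclass(frozen=True)
class PTFConfig:
    """Coefficients of the bulk-density pedo-transfer function.

    BD(soc) = a0 + a1 * exp(-a2 * soc), with soc in g/kg and BD in g/cm3.
    The default coefficients give 1.4 g/cm3 for carbon-free mineral soil,
    decaying toward a 0.5 g/cm3 asymptote for organic-rich topsoils --
    magnitudes typical of alpine meadow profiles.
    """

    a0: float = 0.5   # asymptotic bulk density, g/cm3
    a1: float = 0.9   # amplitude, g/cm3
    a2: float = 0.008  # decay per (g/kg)

    def __post_init__(self) -> None:
        if not (self.a0 > 0 and self.a1 > 0 and self.a2 > 0):
            raise PedonError("PTF coefficients must all be positive")
        lo, hi = self.a0, self.a0 + self.a1
        if not (0.1 < lo and hi < 2.5):
            raise PedonError(
                f"PTF range ({lo:.3f}, {hi:.3f}] g/cm3 leaves (0.1, 2.5)"
            )


def estimate_bd_ptf(soc_mass: float, cfg: PTFConfig = PTFConfig()) -> float:
    """Estimate bulk density (g/cm3) from SOC mass content (g/kg).

    Strictly decreasing in ``soc_mass``; bounded in (a0, a0 + a1].
    """
    if soc_mass < 0:
        raise PedonError(f"soc_mass must be >= 0, got {soc_mass}")
    return cfg.a0 + cfg.a1 * math.exp(-cfg.a2 * soc_mass)


def soc_mass_to_volume(
    soc_mass: float, bulk_density: float, gravel_frac: float = 0.0
) -> float:
    """Convert SOC mass content to volumetric content (kg C per m3 soil).

    Cv = Cm * BD * (1 - G): (g/kg) * (g/cm3) is dimensionally kg/m3; the
    (1 - G) factor removes the volume occupied by >2 mm rock fragments.
    ``gravel_frac`` is a fraction in [0, 1), not a percentage.
    """
    if soc_mass < 0 or bulk_density < 0:
        raise PedonError("soc_mass and bulk_density must be >= 0")
    if not (0.0 <= gravel_frac < 1.0):
        raise PedonError(f"gravel_frac must be in [0, 1), got {gravel_frac}")
    return soc_mass * bulk_density * (1.0 - gravel_frac)


@dataclass
class HorizonSample:
    """One genetic horizon (or fixed-depth increment) of a pedon."""

    top: float                    # m
    bottom: float                 # m
    soc_mass: float               # g/kg
    bulk_density: float | None = None  # g/cm3; None -> PTF
    gravel_frac: float = 0.0      # volume fraction in [0, 1)
    soc_volume: float = field(default=0.0)  # kg/m3, derived

    def __post_init__(self) -> None:
        if self.top < 0:
            raise PedonError(f"horizon top must be >= 0, got {self.top}")
        if self.bottom <= self.top:
            raise PedonError(
                f"horizon bottom ({self.bottom}) must exceed top ({self.top})"
            )
        if self.soc_mass < 0:
            raise PedonError("soc_mass must be >= 0")
        if self.bulk_density is not None and not (0.1 < self.bulk_density < 2.5):
            raise PedonError(
                f"measured bulk density {self.bulk_density} g/cm3 outside (0.1, 2.5)"
            )
        if not (0.0 <= self.gravel_frac < 1.0):
            raise PedonError("gravel_frac must be in [0, 1)")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.top + self.bottom)

    @property
    def thickness(self) -> float:
        return self.bottom - self.top

    def finalize(self, ptf: PTFConfig) -> None:
        """Fill bulk density from the PTF when unmeasured, derive soc_volume."""
        if self.bulk_density is None:
            self.bulk_density = estimate_bd_ptf(self.soc_mass, ptf)
        self.soc_volume = soc_mass_to_volume(
            self.soc_mass, self.bulk_density, self.gravel_frac
        )


@dataclass
class PedonRecord:
    """A described soil profile: the calibration/validation unit.

    ``lat``/``lon`` are carried in whatever planar or geographic CRS the
    covariate grid uses (lon maps to x, lat to y).
    """

    site_id: str
    lat: float
    lon: float
    horizons: list[HorizonSample]
    has_mattic: bool = False
    mattic_depth: float | None = None  # m, present iff has_mattic
    max_depth: float | None = None     # m, profile description depth

    def __post_init__(self) -> None:
        if not self.horizons:
            raise PedonError(f"pedon {self.site_id}: no horizons")
        hs = sorted(self.horizons, key=lambda h: h.top)
        for a, b in zip(hs, hs[1:]):
            if b.top < a.bottom - 1e-12:
                raise PedonError(
                    f"pedon {self.site_id}: overlapping horizons "
                    f"[{a.top}, {a.bottom}) and [{b.top}, {b.bottom})"
                )
        self.horizons = hs
        if self.max_depth is None:
            self.max_depth = hs[-1].bottom
        if self.has_mattic:
            if self.mattic_depth is None:
                raise PedonError(
                    f"pedon {self.site_id}: has_mattic set but mattic_depth missing"
                )
            if not (MATTIC_MIN_THICKNESS < self.mattic_depth <= self.max_depth):
                raise PedonError(
                    f"pedon {self.site_id}: mattic_depth {self.mattic_depth} m must be "
                    f"in ({MATTIC_MIN_THICKNESS}, max_depth={self.max_depth}]"
                )
        else:
            self.mattic_depth = None


def check_mattic_criteria(pedon: PedonRecord) -> list[str]:
    """Check the measurable mattic-epipedon criteria; return advisory flags.

    Occurrence itself is a field (expert) judgment and is never overridden;
    this inspects the flagged layer against the measurable diagnostics:
    thickness > 5 cm and topmost bulk density within 0.5-1.1 g/cm3.
    Returns an empty list when all checked criteria pass (or no mattic).
    """
    if not pedon.has_mattic:
        return []
    if pedon.mattic_depth is None:
        raise PedonError(f"pedon {pedon.site_id}: has_mattic without mattic_depth")
    flags: list[str] = []
    if pedon.mattic_depth <= MATTIC_MIN_THICKNESS:
        flags.append(
            f"thickness {pedon.mattic_depth * 100:.1f} cm <= 5 cm threshold"
        )
    top = pedon.horizons[0]
    lo, hi = MATTIC_BD_RANGE
    if top.bulk_density is not None and not (lo <= top.bulk_density <= hi):
        flags.append(
            f"topmost bulk density {top.bulk_density:.2f} g/cm3 outside [{lo}, {hi}]"
        )
    return flags


# -- pedon table I/O ---------------------------------------------------------

CSV_COLUMNS = [
    "site_id", "lat", "lon", "hz_top_m", "hz_bottom_m", "soc_g_kg",
    "bd_g_cm3", "gravel_frac", "mattic", "mattic_depth_m",
]


def _parse_float(text: str, column: str, row: int) -> float:
    try:
        return float(text)
    except ValueError as exc:
        raise PedonError(f"row {row}: non-numeric {column!r}: {text!r}") from exc


def read_pedons(
    path, ptf: PTFConfig = PTFConfig(), delimiter: str = ","
) -> list[PedonRecord]:
    """Read a per-horizon pedon table into validated :class:`PedonRecord` s.

    Expected columns: ``site_id, lat, lon, hz_top_m, hz_bottom_m, soc_g_kg,
    bd_g_cm3 (blank allowed), gravel_frac, mattic (0/1), mattic_depth_m``.
    Missing bulk densities are filled with the PTF and ``soc_volume`` is
    derived for every horizon. Parse errors name the offending data row.
    """
    groups: dict[str, dict] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        missing = set(CSV_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise PedonError(f"missing columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=2):  # 1-based, after header
            sid = row["site_id"].strip()
            if not sid:
                raise PedonError(f"row {i}: empty site_id")
            top = _parse_float(row["hz_top_m"], "hz_top_m", i)
            bottom = _parse_float(row["hz_bottom_m"], "hz_bottom_m", i)
            if bottom <= top:
                raise PedonError(
                    f"row {i}: horizon bottom {bottom} <= top {top} for site {sid}"
                )
            bd_text = (row["bd_g_cm3"] or "").strip()
            try:
                hz = HorizonSample(
                    top=top,
                    bottom=bottom,
                    soc_mass=_parse_float(row["soc_g_kg"], "soc_g_kg", i),
                    bulk_density=float(bd_text) if bd_text else None,
                    gravel_frac=_parse_float(row["gravel_frac"], "gravel_frac", i),
                )
            except PedonError as exc:
                raise PedonError(f"row {i}: {exc}") from exc
            g = groups.setdefault(
                sid,
                {"lat": float(row["lat"]), "lon": float(row["lon"]),
                 "horizons": [], "keys": set(),
                 "mattic": row["mattic"].strip() in ("1", "true", "True"),
                 "mattic_depth": None},
            )
            key = (round(top, 6), round(bottom, 6))
            if key in g["keys"]:
                raise PedonError(f"row {i}: duplicate horizon {key} for site {sid}")
            g["keys"].add(key)
            md = (row["mattic_depth_m"] or "").strip()
            if md:
                g["mattic_depth"] = float(md)
            g["horizons"].append(hz)

    pedons: list[PedonRecord] = []
    for sid, g in groups.items():
        for hz in g["horizons"]:
            hz.finalize(ptf)
        pedons.append(
            PedonRecord(
                site_id=sid, lat=g["lat"], lon=g["lon"], horizons=g["horizons"],
                has_mattic=g["mattic"],
                mattic_depth=g["mattic_depth"] if g["mattic"] else None,
            )
        )
    return pedons


def write_pedons(pedons: Iterable[PedonRecord], path, delimiter: str = ",") -> None:
    """Write pedons back to the delimited table format read_pedons accepts."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(CSV_COLUMNS)
        for p in pedons:
            for hz in p.horizons:
                writer.writerow([
                    p.site_id, repr(float(p.lat)), repr(float(p.lon)),
                    repr(float(hz.top)), repr(float(hz.bottom)),
                    repr(float(hz.soc_mass)),
                    "" if hz.bulk_density is None else repr(float(hz.bulk_density)),
                    repr(float(hz.gravel_frac)),
                    int(p.has_mattic),
                    "" if p.mattic_depth is None else repr(float(p.mattic_depth)),
                ])
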