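"""Static closed-chamber gas flux and cumulative emission arithmetic.

Fluxes follow the standard static-chamber form: the ordinary
least-squares slope of headspace concentration against closure time
(ppmv·h⁻¹) converted to a mass flux with the ideal-gas molar volume
(22.4 L·mol⁻¹ at STP) and a temperature correction, scaled by the
chamber volume-to-area ratio:

    F (mg·m⁻²·h⁻¹) = slope · (M / 22.4) · 273.15/(273.15 + T) · V/A

with M = 16 g·mol⁻¹ for CH4 and 44 g·mol⁻¹ for CO2.  Negative fluxes
(net uptake, e.g. CH4 oxidation) are retained, never clipped.

Cumulative emissions integrate daily fluxes with the trapezoidal rule
and convert mg·m⁻² to kg·ha⁻¹ (factor 0.01).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .isotopes import ChamberGeometry

#: Molar volume of an ideal gas at STP, L·mol⁻¹.
MOLAR_VOLUME_STP = 22.4

#: Molar masses, g·mol⁻¹.
MOLAR_MASS = {"CH4": 16.0, "CO2": 44.0}

#: mg·m⁻² → kg·ha⁻¹.
MG_M2_TO_KG_HA = 0.01


class Gas(str, enum.Enum):
    CH4 = "CH4"
    CO2 = "CO2"


@dataclass(frozen=True)
class GasSampleSeries:
    """Headspace concentrations over one chamber closure.

    times_h are hours since closure (strictly increasing, >= 2 points);
    conc_ppm are mixing ratios in ppmv; temperature_c is the mean air
    temperature during closure.
    """

    gas: Gas
    times_h: tuple[float, ...]
    conc_ppm: tuple[float, ...]
    temperature_c: float = 25.0
    geometry: ChamberGeometry = field(default_factory=ChamberGeometry)
    day: int = 1

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        c = np.asarray(self.conc_ppm, dtype=float)
        if t.size < 2:
            raise ValueError("a closure needs at least 2 gas samples")
        if t.size != c.size:
            raise ValueError("times and concentrations differ in length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("closure times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")
        if self.temperature_c <= -273.15:
            raise ValueError("temperature below absolute zero")


@dataclass(frozen=True)
class FluxRecord:
    """One gas flux on one sampling day, mg·m⁻²·h⁻¹ (sign free)."""

    day: int
    gas: Gas
    flux_mg_m2_h: float
    slope_ppm_h: float = float("nan")
    slope_se: float = float("nan")
    r2: float = float("nan")


def chamber_flux(series: GasSampleSeries) -> FluxRecord:
    """Compute the chamber flux from one closure's concentration series."""
    t = np.asarray(series.times_h, dtype=float)
    c = np.asarray(series.conc_ppm, dtype=float)
    if t.size == 2:
        slope = (c[1] - c[0]) / (t[1] - t[0])
        se = float("nan")
        r2 = 1.0
    else:
        fit = stats.linregress(t, c)
        slope, se = fit.slope, fit.stderr
        r2 = fit.rvalue**2
    molar = MOLAR_MASS[series.gas.value]
    temp_corr = 273.15 / (273.15 + series.temperature_c)
    va = series.geometry.volume_m3 / series.geometry.area_m2
    flux = slope * (molar / MOLAR_VOLUME_STP) * temp_corr * va
    return FluxRecord(
        day=series.day,
        gas=series.gas,
        flux_mg_m2_h=float(flux),
        slope_ppm_h=float(slope),
        slope_se=float(se),
        r2=float(r2),
    )


def cumulative_emission(
    days: Sequence[float], fluxes_mg_m2_h: Sequence[float]
) -> float:
    """Cumulative emission (kg·ha⁻¹) from daily fluxes.

    Trapezoidal integration of flux (mg·m⁻²·h⁻¹) over time (days × 24 h),
    then mg·m⁻² → kg·ha⁻¹.  A single flux measurement integrates to 0.
    """
    d = np.asarray(days, dtype=float)
    f = np.asarray(fluxes_mg_m2_h, dtype=float)
    if d.size != f.size:
        raise ValueError("days and fluxes differ in length")
    if d.size and not np.all(np.diff(d) > 0):
        raise ValueError("sampling days must be strictly increasing")
    if d.size < 2:
        return 0.0
    mg_m2 = float(np.trapezoid(f, d * 24.0))
    return mg_m2 * MG_M2_TO_KG_HA


def flux_table(series_list: Sequence[GasSampleSeries]):
    """Convenience: chamber_flux over many closures as a tidy DataFrame."""
    import pandas as pd

    recs = [chamber_flux(s) for s in series_list]
    return pd.DataFrame(
        {
            "day": [r.day for r in recs],
            "gas": [r.gas.value for r in recs],
            "flux_mg_m2_h": [r.flux_mg_m2_h for r in recs],
            "slope_ppm_h": [r.slope_ppm_h for r in recs],
            "r2": [r.r2 for r in recs],
        }
    )
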