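"""Three-source partitioning of paddy CH4 carbon and contribution coefficients.

The partition bounds the three CH4 carbon sources of an organically
fertilized paddy pot:

* the photosynthesis share p comes from a two-end-member isotope mixing
  contrast between the 13CO2-labelled treatment and its unlabelled
  control;
* the fertilizer share is bounded above by assuming every gram of
  fertilizer carbon is as available to methanogens as native soil
  carbon: fertilizer_max = (fertilizer C : soil C) × (100 − p);
* the native-soil share is the remainder, a lower bound.

Reported values are rounded half-away-from-zero to 2 decimals because
the worked arithmetic chain (carbon ratio 0.66% → fertilizer ≤ 0.34% →
soil ≥ 50.60%) only reproduces under that convention; pass digits=None
for raw arithmetic.

Contribution coefficients K = 1/slope come from ordinary least-squares
regressions of daily pool δ13C accumulation rates on daily δ13CH4
accumulation; a larger K means CH4 label accumulation responds more
strongly per unit of that pool's accumulation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .isotopes import (
    PDB_RATIO,
    IsotopeMeasurement,
    Pool,
    Stage,
    excess_13c,
)

__all__ = [
    "CarbonPools",
    "SourceShares",
    "FractionationProfile",
    "RegressionFit",
    "round_half_away",
    "fertilizer_carbon",
    "soil_carbon",
    "carbon_ratio",
    "photosynthesis_share",
    "partition_sources",
    "three_source_partition",
    "fractionation_profile",
    "fit_line",
    "contribution_coefficient",
]


def round_half_away(x: float, digits: int = 2) -> float:
    """Round half away from zero (0.335 → 0.34, −0.335 → −0.34).

    Python's built-in round() is banker's rounding; reported percentages
    here follow the conventional half-away-from-zero rule.
    """
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CarbonPools:
    """Per-pot carbon mass-balance inputs.

    Defaults are the pot experiment's values: 10.24 g chicken-manure
    fertilizer at 23.05% C, and 359.67 g total C in the 20 cm topsoil.
    The topsoil figure is treated as a given input, never recomputed
    from bulk density.
    """

    fertilizer_mass_g: float = 10.24
    fertilizer_c_fraction: float = 0.2305
    soil_c_g: float = 359.67

    def __post_init__(self) -> None:
        if self.fertilizer_mass_g < 0 or self.soil_c_g < 0:
            raise ValueError("carbon pool masses must be >= 0")
        if not 0.0 <= self.fertilizer_c_fraction <= 1.0:
            raise ValueError("fertilizer C fraction must lie in [0, 1]")

    @property
    def fertilizer_c_g(self) -> float:
        return fertilizer_carbon(self.fertilizer_mass_g, self.fertilizer_c_fraction)


@dataclass(frozen=True)
class SourceShares:
    """Three-way CH4 carbon source partition (percent).

    fertilizer_max is an upper bound, soil_min the matching lower bound;
    the three entries sum to 100 within rounding slack.
    """

    photosynthesis: float
    fertilizer_max: float
    soil_min: float

    def __post_init__(self) -> None:
        for name, v in (
            ("photosynthesis", self.photosynthesis),
            ("fertilizer_max", self.fertilizer_max),
            ("soil_min", self.soil_min),
        ):
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100], got {v}")
        total = self.photosynthesis + self.fertilizer_max + self.soil_min
        if abs(total - 100.0) > 0.02:
            raise ValueError(f"shares must sum to 100 within ±0.02, got {total}")


@dataclass(frozen=True)
class FractionationProfile:
    """Percent of recovered 13C excess per pool at one stage."""

    stage: Stage
    shares: Mapping[Pool, float]

    def __post_init__(self) -> None:
        for pool, v in self.shares.items():
            if v < 0:
                raise ValueError(f"share for {pool} must be >= 0, got {v}")
        total = sum(self.shares.values())
        if abs(total - 100.0) > 0.05:
            raise ValueError(f"shares must sum to 100 within ±0.05, got {total}")


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary least-squares line fit with slope inference."""

    slope: float
    intercept: float
    r2: float
    p: float
    n: int
    slope_se: float = float("nan")


def fertilizer_carbon(mass_g: float, c_fraction: float) -> float:
    """Fertilizer carbon applied per pot (g C) = mass × C fraction."""
    if mass_g < 0:
        raise ValueError(f"fertilizer mass must be >= 0, got {mass_g}")
    if not 0.0 <= c_fraction <= 1.0:
        raise ValueError(f"C fraction must lie in [0, 1], got {c_fraction}")
    return mass_g * c_fraction


def soil_carbon(soil_mass_g: float, tc_fraction: float) -> float:
    """Topsoil carbon per pot (g C) = soil mass × total-C fraction."""
    if soil_mass_g < 0 or tc_fraction < 0:
        raise ValueError("soil mass and C fraction must be >= 0")
    return soil_mass_g * tc_fraction


def carbon_ratio(fert_c_g: float, soil_c_g: float) -> float:
    """Fertilizer-C : soil-C ratio in percent, 100 × fert/soil."""
    if not soil_c_g > 0:
        raise ValueError(f"soil carbon must be positive, got {soil_c_g}")
    if fert_c_g < 0:
        raise ValueError(f"fertilizer carbon must be >= 0, got {fert_c_g}")
    return 100.0 * fert_c_g / soil_c_g


def photosynthesis_share(
    delta_ch4_labeled: float,
    delta_ch4_control: float,
    delta_source_labeled: float,
    delta_source_control: float,
) -> float:
    """Percent of CH4 carbon derived from the labelled source pool.

    Two-end-member mixing on the labelled/control treatment contrast:
    100 × Δδ13CH4 / Δδ13C_source.  Values outside [0, 100] (possible
    under noise) are clipped with a warning.
    """
    source_excess = delta_source_labeled - delta_source_control
    if not source_excess > 0:
        raise ValueError(
            f"source excess must be positive, got {source_excess} permil"
        )
    share = 100.0 * (delta_ch4_labeled - delta_ch4_control) / source_excess
    if share < 0.0 or share > 100.0:
        warnings.warn(
            f"mixing share {share:.2f}% outside [0, 100]; clipping",
            stacklevel=2,
        )
        share = min(max(share, 0.0), 100.0)
    return share


def partition_sources(
    p_photo: float, ratio_percent: float, digits: Optional[int] = 2
) -> SourceShares:
    """Bound the three CH4 carbon sources.

    fertilizer_max = ratio × (100 − p_photo)/100 (fertilizer C fully as
    available as soil C — the worst case); soil_min is the remainder.
    The ratio is rounded to *digits* before multiplying, and each
    reported value rounded half-away-from-zero, matching the reported
    arithmetic chain; digits=None disables all rounding.
    """
    if not 0.0 <= p_photo <= 100.0:
        raise ValueError(f"photosynthesis share must lie in [0, 100], got {p_photo}")
    if ratio_percent < 0:
        raise ValueError(f"carbon ratio must be >= 0, got {ratio_percent}")
    ratio = ratio_percent if digits is None else round_half_away(ratio_percent, digits)
    non_photo = 100.0 - p_photo
    fert = ratio / 100.0 * non_photo
    if digits is not None:
        fert = round_half_away(fert, digits)
    soil = 100.0 - p_photo - fert
    if digits is not None:
        soil = round_half_away(soil, digits)
    return SourceShares(photosynthesis=p_photo, fertilizer_max=fert, soil_min=soil)


@dataclass(frozen=True)
class PartitionReport:
    """Full mass-balance chain from raw pool inputs to source shares."""

    pools: CarbonPools
    fertilizer_c_g: float
    carbon_ratio_percent: float
    shares: SourceShares


def three_source_partition(
    pools: CarbonPools, p_photo: float, digits: Optional[int] = 2
) -> PartitionReport:
    """Run the whole worked chain: fertilizer C → C ratio → source bounds."""
    fert_c = pools.fertilizer_c_g
    ratio = carbon_ratio(fert_c, pools.soil_c_g)
    shares = partition_sources(p_photo, ratio, digits=digits)
    if digits is not None:
        fert_c = round_half_away(fert_c, digits)
        ratio = round_half_away(ratio, digits)
    return PartitionReport(
        pools=pools,
        fertilizer_c_g=fert_c,
        carbon_ratio_percent=ratio,
        shares=shares,
    )


def fractionation_profile(
    labeled: Iterable[IsotopeMeasurement],
    control: Iterable[IsotopeMeasurement],
    r_standard: float = PDB_RATIO,
) -> FractionationProfile:
    """Percent of recovered 13C excess in each pool for one stage.

    Measurements are paired labelled/control per pool; replicates are
    averaged (delta and pool C mass) before the atom-percent-excess ×
    mass computation.  All four pools must be present and the total
    excess positive.  Tiny negative pool excesses (noise) are clipped to
    zero with a warning before normalisation.
    """
    labeled = list(labeled)
    control = list(control)
    stages = {m.stage for m in labeled} | {m.stage for m in control}
    if len(stages) != 1:
        raise ValueError(f"measurements must come from exactly one stage, got {stages}")
    stage = stages.pop()

    def _mean_by_pool(ms: Sequence[IsotopeMeasurement]) -> dict[Pool, IsotopeMeasurement]:
        out: dict[Pool, IsotopeMeasurement] = {}
        for pool in Pool:
            sub = [m for m in ms if m.pool == pool]
            if not sub:
                continue
            if any(m.pool_c_mass_g is None for m in sub):
                raise ValueError(f"pool {pool.value} is missing pool_c_mass_g")
            out[pool] = IsotopeMeasurement(
                pool=pool,
                treatment=sub[0].treatment,
                stage=stage,
                day=sub[0].day,
                replicate=1,
                delta_permil=float(np.mean([m.delta_permil for m in sub])),
                pool_c_mass_g=float(np.mean([m.pool_c_mass_g for m in sub])),
            )
        return out

    lab = _mean_by_pool(labeled)
    ctl = _mean_by_pool(control)
    missing = [p.value for p in Pool if p not in lab or p not in ctl]
    if missing:
        raise ValueError(f"missing pools for fractionation profile: {missing}")

    excess = {p: excess_13c(lab[p], ctl[p], r_standard) for p in Pool}
    clipped = {p: e for p, e in excess.items() if e < 0}
    if clipped:
        warnings.warn(
            f"negative 13C excess clipped to 0 for pools {[p.value for p in clipped]}",
            stacklevel=2,
        )
        excess = {p: max(e, 0.0) for p, e in excess.items()}
    total = sum(excess.values())
    if not total > 0:
        raise ValueError("total 13C excess must be positive")
    shares = {p: 100.0 * e / total for p, e in excess.items()}
    return FractionationProfile(stage=stage, shares=shares)


def fit_line(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Closed-form OLS line y = a·x + b with r² and a two-sided t-test
    p-value on the slope.  Requires n ≥ 3 and non-constant x."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y differ in length")
    if xa.size < 3:
        raise ValueError(f"need n >= 3 for slope inference, got n={xa.size}")
    if np.ptp(xa) == 0:
        raise ValueError("x is constant; slope is undefined")
    fit = stats.linregress(xa, ya)
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        p=float(fit.pvalue),
        n=int(xa.size),
        slope_se=float(fit.stderr),
    )


def contribution_coefficient(
    fit: Union[RegressionFit, float], digits: Optional[int] = 2
) -> float:
    """Contribution coefficient K = 1/slope of a pool-vs-CH4 regression.

    Accepts a RegressionFit or a bare slope.  Rounded half-away-from-zero
    to *digits* (default 2, matching reported values); digits=None
    returns the raw reciprocal.
    """
    slope = fit.slope if isinstance(fit, RegressionFit) else float(fit)
    if slope == 0 or not math.isfinite(slope):
        raise ValueError(f"contribution coefficient undefined for slope {slope}")
    k = 1.0 / slope
    return k if digits is None else round_half_away(k, digits)
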