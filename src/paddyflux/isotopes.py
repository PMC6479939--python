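"""Stable carbon isotope arithmetic on the delta (per-mil) scale.

All delta values are per mil (‰) relative to a reference standard, by
default Pee Dee Belemnite (PDB).  The delta notation is

    δ13C (‰) = 1000 · (R_sample − R_standard) / R_standard,

where R is the 13C/12C atom ratio.  Conversions to atom ratios or atom
percent happen only inside operations; data structures store deltas.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

#: Conventional Pee Dee Belemnite 13C/12C ratio.  The original analysis
#: lab's exact value is not knowable; this is the community convention
#: and may be overridden wherever a standard ratio is accepted.
PDB_RATIO: float = 0.0112372


class Pool(str, enum.Enum):
    """Carbon pool a measurement belongs to."""

    CO2 = "CO2"
    CH4 = "CH4"
    PLANT = "plant"
    SOIL = "soil"


class Treatment(str, enum.Enum):
    """Pot treatment: C = no fertilizer, O = organic fertilizer;
    Y = 13CO2-labelled chamber, N = unlabelled (12C) control."""

    CN = "CN"
    CY = "CY"
    ON = "ON"
    OY = "OY"


class Stage(str, enum.Enum):
    """Rice growth stage covered by one labelling period."""

    REGREENING = "regreening"
    TILLERING = "tillering"
    BOOTING = "booting"


#: Duration of each labelling stage in days.
STAGE_DAYS: dict[Stage, int] = {
    Stage.REGREENING: 9,
    Stage.TILLERING: 27,
    Stage.BOOTING: 33,
}

LABELED_OF = {Treatment.CN: Treatment.CY, Treatment.ON: Treatment.OY}
CONTROL_OF = {v: k for k, v in LABELED_OF.items()}


@dataclass(frozen=True)
class ChamberGeometry:
    """Static chamber geometry and the rice stand it encloses.

    area_m2 / volume_m3 default to the 0.49 m² footprint of the 490 L
    incubation chamber.  rice_biomass_g_m2 is the dry rice biomass per
    unit chamber area and is only required by :func:`per_biomass_delta`.
    """

    area_m2: float = 0.49
    volume_m3: float = 0.49
    rice_biomass_g_m2: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.area_m2 > 0 and math.isfinite(self.area_m2)):
            raise ValueError(f"chamber area must be positive, got {self.area_m2}")
        if not (self.volume_m3 > 0 and math.isfinite(self.volume_m3)):
            raise ValueError(f"chamber volume must be positive, got {self.volume_m3}")
        if self.rice_biomass_g_m2 is not None and not self.rice_biomass_g_m2 > 0:
            raise ValueError("rice biomass must be positive when given")


@dataclass(frozen=True)
class IsotopeMeasurement:
    """One pool's δ13C at one time point of one pot.

    pool_c_mass_g is the total carbon mass (g C) of the pool at that
    time; it is needed for 13C excess-mass accounting and may be omitted
    for pure delta bookkeeping.
    """

    pool: Pool
    treatment: Treatment
    stage: Stage
    day: int
    replicate: int
    delta_permil: float
    pool_c_mass_g: Optional[float] = None

    def __post_init__(self) -> None:
        if self.day < 1:
            raise ValueError(f"day must be >= 1, got {self.day}")
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")
        if self.delta_permil <= -1000.0:
            raise ValueError("delta must exceed -1000 permil (ratio must stay positive)")
        if self.pool_c_mass_g is not None and self.pool_c_mass_g < 0:
            raise ValueError("pool carbon mass must be >= 0")


def delta_from_ratio(r_sample: float, r_standard: float = PDB_RATIO) -> float:
    """δ13C (‰) of a sample with 13C/12C ratio *r_sample*."""
    if not (r_sample > 0 and math.isfinite(r_sample)):
        raise ValueError(f"sample ratio must be positive and finite, got {r_sample}")
    if not (r_standard > 0 and math.isfinite(r_standard)):
        raise ValueError(f"standard ratio must be positive and finite, got {r_standard}")
    return 1000.0 * (r_sample - r_standard) / r_standard


def ratio_from_delta(delta_permil: float, r_standard: float = PDB_RATIO) -> float:
    """13C/12C ratio of a sample with δ13C = *delta_permil* ‰ (inverse of
    :func:`delta_from_ratio`)."""
    if delta_permil <= -1000.0:
        raise ValueError(f"delta must exceed -1000 permil, got {delta_permil}")
    if not r_standard > 0:
        raise ValueError(f"standard ratio must be positive, got {r_standard}")
    return r_standard * (1.0 + delta_permil / 1000.0)


def atom_percent(r: float) -> float:
    """13C atom percent, 100·R/(1+R), of a pool with 13C/12C ratio *r*."""
    if not (r > 0 and math.isfinite(r)):
        raise ValueError(f"isotope ratio must be positive and finite, got {r}")
    return 100.0 * r / (1.0 + r)


def atom_percent_from_delta(delta_permil: float, r_standard: float = PDB_RATIO) -> float:
    """13C atom percent of a pool with the given δ13C (‰)."""
    return atom_percent(ratio_from_delta(delta_permil, r_standard))


def excess_13c(
    labeled: IsotopeMeasurement,
    control: IsotopeMeasurement,
    r_standard: float = PDB_RATIO,
) -> float:
    """13C excess mass (g) of a labelled pool over its unlabelled control.

    excess = (atom%_labeled − atom%_control)/100 × pool C mass.  The
    labelled measurement's pool carbon mass is used.  The result may be
    ~0 or slightly negative under measurement noise; no sign is imposed.
    """
    if labeled.pool != control.pool:
        raise ValueError(f"pool mismatch: {labeled.pool} vs {control.pool}")
    if labeled.stage != control.stage:
        raise ValueError(f"stage mismatch: {labeled.stage} vs {control.stage}")
    if labeled.pool_c_mass_g is None or control.pool_c_mass_g is None:
        raise ValueError("both measurements need pool_c_mass_g for excess accounting")
    ap_l = atom_percent_from_delta(labeled.delta_permil, r_standard)
    ap_c = atom_percent_from_delta(control.delta_permil, r_standard)
    return (ap_l - ap_c) / 100.0 * labeled.pool_c_mass_g


def daily_accumulation(delta_start: float, delta_end: float, t_days: float) -> float:
    """Daily δ13C accumulation rate V (‰·d⁻¹) over a stage of *t_days*:
    V = (δ_end − δ_start)/t."""
    if not t_days > 0:
        raise ValueError(f"stage length must be positive, got {t_days}")
    return (delta_end - delta_start) / t_days


def per_biomass_delta(final_delta: float, geometry: ChamberGeometry) -> float:
    """Final δ13CH4 normalised by chamber area and rice biomass,
    final δ / S_chamber / W_rice.

    Note on units: the quotient is ‰ per m² per (g·m⁻²); it carries the
    conventional ‰·g⁻¹ label only when W_rice is read as biomass per
    chamber.  Implemented literally as the printed quotient.
    """
    if geometry.rice_biomass_g_m2 is None or not geometry.rice_biomass_g_m2 > 0:
        raise ValueError("geometry.rice_biomass_g_m2 must be positive")
    return final_delta / geometry.area_m2 / geometry.rice_biomass_g_m2
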