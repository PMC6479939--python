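"""Synthetic pot-experiment generator.

Emulates a 13CO2 pulse-labelling pot experiment with two fertilizer
arms (no fertilizer C*, organic fertilizer O*), each split into an
unlabelled control (CN/ON) and a 13C-labelled treatment (CY/OY), three
growth stages and three replicates.  Matching the staged design, every
stage starts from fresh unlabelled pots; each pot carries its own
lognormal photosynthetic-uptake multiplier (biological variability),
which is what spreads the contribution-coefficient regressions.

Within a stage the label moves through a four-compartment first-order
tracer model in 13C-excess mass,

    chamber CO2 → plant → soil,  plant/soil → CH4,

integrated with sub-daily Euler steps; the chamber CO2 pool is topped
up to the target enrichment once per day (the "pulse"), and excess mass
is conserved between pulses.  Photosynthetic uptake scales with plant
maturity (bigger canopies capture more of the pulse).  Measured δ13CH4
in the labelled arms follows the two-end-member mixing identity

    δ13CH4 = δ_bg + (p/100) · (δ13C_plant − δ_bg,plant),

so the planted photosynthesis share p is exactly recoverable from the
labelled/control contrast at zero measurement noise — the identity is
linear, hence replicate averaging preserves it.  Gaussian noise is
added to every reported δ; chamber gas concentration series are drawn
around planted flux profiles so the chamber-flux arithmetic can be
tested against known rates.  All randomness flows from one seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .flux import MOLAR_MASS, MOLAR_VOLUME_STP
from .isotopes import (
    PDB_RATIO,
    Pool,
    Stage,
    Treatment,
    delta_from_ratio,
    ratio_from_delta,
)
from .partition import SourceShares

__all__ = [
    "ExperimentParams",
    "SyntheticDataset",
    "simulate_pot_experiment",
    "simulate_abundance_table",
    "stage_table",
    "METHANOGEN_SPECIES",
    "ENVIRONMENT_FACTORS",
]

#: Species-level methanogen labels used for synthetic abundance tables.
METHANOGEN_SPECIES = [
    "Methanosarcina sp. 795",
    "Methanosarcina sp. 1H1",
    "Methanobrevibacter sp. AbM23",
    "Methanobrevibacter ruminantium",
    "Methanoculleus sp. 25XMc2",
    "Methanosaeta sp. HA",
    "Methanobacterium sp. MB1",
    "Methanobacterium palustre",
    "Methanosphaera sp. ISO3-F5",
    "Methanolobus psychrophilus",
]

#: Environmental factors carried alongside the abundance table.
ENVIRONMENT_FACTORS = [
    "acetate",
    "d13CO2",
    "TC",
    "AK",
    "TN",
    "AP",
    "d13CH4",
    "soil_d13C",
    "AN",
]

_BACKGROUND_DELTA = {
    Pool.CO2: -8.0,
    Pool.PLANT: -27.0,
    Pool.SOIL: -20.0,
    Pool.CH4: -55.0,
}


@dataclass(frozen=True)
class ExperimentParams:
    """Ground-truth parameters of one simulated pot experiment.

    Stage durations, replicate count and chamber geometry mirror the
    pot design (regreening 9 d, tillering 27 d, booting 33 d; 3
    replicates; 0.49 m² / 490 L chamber).  label_pulse_permil is the
    chamber CO2 enrichment above its natural background during
    labelling; transfer rates are first-order per-day coefficients; the
    organic-fertilizer arm multiplies uptake and biomass by
    organic_boost; pot_sd is the lognormal sigma of the per-pot uptake
    multiplier.  noise_sd_permil is Gaussian measurement noise on every
    reported δ.
    """

    stage_days: tuple[int, int, int] = (9, 27, 33)
    replicates: int = 3
    label_pulse_permil: float = 5000.0
    uptake_rate: float = 0.25
    uptake_maturity_exponent: float = 2.0
    rhizodeposition_rate: float = 0.02
    plant_to_ch4_rate: float = 0.008
    soil_to_ch4_rate: float = 0.0005
    organic_boost: float = 1.3
    pot_sd: float = 0.25
    true_source_shares: SourceShares = field(
        default_factory=lambda: SourceShares(49.0, 0.34, 50.66)
    )
    noise_sd_permil: float = 0.5
    flux_noise_ppm: float = 0.02
    peak_ch4_flux: Mapping[str, float] = field(
        default_factory=lambda: {"C": 0.16, "O": 0.46}
    )
    soil_c_g: float = 359.67
    chamber_co2_c_g: float = 1.2
    plant_c_start_g: float = 5.0
    plant_c_end_g: float = 30.0
    plant_growth_tau_d: float = 25.0
    temperature_c: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.stage_days):
            raise ValueError("stage durations must be positive")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        for name in (
            "uptake_rate",
            "rhizodeposition_rate",
            "plant_to_ch4_rate",
            "soil_to_ch4_rate",
            "pot_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_sd_permil < 0 or self.flux_noise_ppm < 0:
            raise ValueError("noise levels must be >= 0")
        # SourceShares itself enforces the sum-to-100 invariant.

    @property
    def total_days(self) -> int:
        return int(sum(self.stage_days))

    def stage_bounds(self) -> dict[Stage, tuple[int, int]]:
        """First and last absolute day of each stage (contiguous)."""
        stages = list(Stage)
        out = {}
        start = 1
        for st, dur in zip(stages, self.stage_days):
            out[st] = (start, start + dur - 1)
            start += dur
        return out


@dataclass(frozen=True)
class SyntheticDataset:
    """One simulated experiment: tidy tables plus the generating truth.

    measurements: pool δ13C series (pool, treatment, stage, day,
    replicate, delta_permil, pool_c_mass_g).  gas: chamber closure
    concentration series (treatment, gas, day, time_h, conc_ppm,
    temp_C).  biomass: plant carbon per pot by arm and stage end.
    tracer: per-pot 13C-excess mass ledger, keyed "arm:replicate", with
    a stage column — excess is conserved between pulses within a stage
    (each stage starts from fresh pots).  truth: the generating
    parameters.
    """

    measurements: pd.DataFrame
    gas: pd.DataFrame
    biomass: pd.DataFrame
    tracer: Mapping[str, pd.DataFrame]
    truth: ExperimentParams


def _sampling_offsets(stage_len: int) -> list[int]:
    """Within-stage sampling days: the 72 h closure window (days 1-3),
    then every 5 days, always including the stage end."""
    offs = {1, 2, 3}
    offs.update(range(5, stage_len + 1, 5))
    offs.add(stage_len)
    return sorted(d for d in offs if d <= stage_len)


def stage_table(params: ExperimentParams) -> pd.DataFrame:
    """Absolute sampling days with their stage labels."""
    rows = []
    for st, (lo, hi) in params.stage_bounds().items():
        for off in _sampling_offsets(hi - lo + 1):
            rows.append({"stage": st.value, "day": lo + off - 1, "stage_day": off})
    return pd.DataFrame(rows)


def _atom_fraction(delta: float, r_standard: float = PDB_RATIO) -> float:
    r = ratio_from_delta(delta, r_standard)
    return r / (1.0 + r)


def _delta_from_fraction(x: float, r_standard: float = PDB_RATIO) -> float:
    return delta_from_ratio(x / (1.0 - x), r_standard)


def _plant_c(params: ExperimentParams, day: float, boost: float) -> float:
    """Plant carbon per pot (g C): saturating growth from the transplanted
    seedling mass toward the harvest mass (timescale plant_growth_tau_d),
    so established plants gain mass slower than they accumulate label."""
    span = params.plant_c_end_g - params.plant_c_start_g
    mass = params.plant_c_end_g - span * math.exp(-day / params.plant_growth_tau_d)
    return mass * boost


def _ch4_flux_profile(day: float, peak: float, total_days: int) -> float:
    """Planted CH4 flux (mg·m⁻²·h⁻¹): rises linearly to the peak on day
    30, then falls to 20% of the peak by the season end."""
    if day <= 30.0:
        return peak * max(day, 0.0) / 30.0
    return peak * (1.0 - 0.8 * (day - 30.0) / max(total_days - 30.0, 1.0))


def _integrate_stage(
    params: ExperimentParams,
    boost: float,
    xi: float,
    start_day: int,
    n_days: int,
) -> pd.DataFrame:
    """Daily-pulsed Euler integration of one fresh pot over one stage.

    Photosynthetic uptake scales with plant maturity (plant C relative
    to harvest mass) and the pot's multiplier xi.  Returns the excess
    ledger at stage-relative days 0..n_days (absolute day column).
    """
    dt = 0.25
    steps_per_day = int(round(1.0 / dt))
    x_bg = _atom_fraction(_BACKGROUND_DELTA[Pool.CO2])
    x_label = _atom_fraction(_BACKGROUND_DELTA[Pool.CO2] + params.label_pulse_permil)
    target_excess = (x_label - x_bg) * params.chamber_co2_c_g

    e_co2 = e_plant = e_soil = e_ch4 = 0.0
    rows = [
        {"day": float(start_day - 1), "co2": 0.0, "plant": 0.0, "soil": 0.0,
         "ch4": 0.0, "pulse_added": 0.0}
    ]
    for rel in range(n_days):
        day_abs = start_day + rel
        # canopy light capture develops superlinearly with plant maturity
        maturity = _plant_c(params, day_abs, 1.0) / params.plant_c_end_g
        uptake = (
            params.uptake_rate
            * boost
            * xi
            * maturity**params.uptake_maturity_exponent
        )
        pulse = max(target_excess - e_co2, 0.0)
        e_co2 += pulse
        for _ in range(steps_per_day):
            f_up = uptake * e_co2 * dt
            f_rz = params.rhizodeposition_rate * e_plant * dt
            f_pm = params.plant_to_ch4_rate * e_plant * dt
            f_sm = params.soil_to_ch4_rate * e_soil * dt
            e_co2 -= f_up
            e_plant += f_up - f_rz - f_pm
            e_soil += f_rz - f_sm
            e_ch4 += f_pm + f_sm
        rows.append(
            {
                "day": float(day_abs),
                "co2": e_co2,
                "plant": e_plant,
                "soil": e_soil,
                "ch4": e_ch4,
                "pulse_added": pulse,
            }
        )
    return pd.DataFrame(rows)


def simulate_pot_experiment(params: ExperimentParams | None = None) -> SyntheticDataset:
    """Generate one full synthetic pot experiment (see module docstring).

    Deterministic for a given params.seed; labelled and control
    treatments coincide when label_pulse_permil and noise_sd_permil are
    both zero.
    """
    params = params or ExperimentParams()
    rng = np.random.default_rng(params.seed)
    bounds = params.stage_bounds()
    p_photo = params.true_source_shares.photosynthesis
    arms = {"C": 1.0, "O": params.organic_boost}
    area = 0.49

    # per-pot uptake multipliers: fresh pots per arm × stage × replicate
    xi = {
        (arm, st, rep): float(np.exp(rng.normal(0.0, params.pot_sd)))
        for arm in arms
        for st in Stage
        for rep in range(1, params.replicates + 1)
    }

    # per-stage cumulative CH4 carbon per pot, for the CH4 pool C mass
    cum_ch4_c: dict[tuple[str, Stage, int], float] = {}
    for arm in arms:
        peak = params.peak_ch4_flux[arm]
        for st, (lo, hi) in bounds.items():
            acc = 0.0
            for day in range(lo, hi + 1):
                flux = _ch4_flux_profile(day, peak, params.total_days)
                acc += flux * area * 24.0 / 1000.0 * (12.0 / 16.0)  # g C / pot·day
                cum_ch4_c[(arm, st, day)] = acc

    tracer: dict[str, pd.DataFrame] = {}
    mrows = []
    for arm, boost in arms.items():
        control = Treatment(arm + "N")
        labeled = Treatment(arm + "Y")
        for rep in range(1, params.replicates + 1):
            segs = []
            for st, (lo, hi) in bounds.items():
                seg = _integrate_stage(
                    params, boost, xi[(arm, st, rep)], lo, hi - lo + 1
                )
                seg.insert(0, "stage", st.value)
                segs.append(seg)
                traj = seg.set_index("day")
                for off in _sampling_offsets(hi - lo + 1):
                    day = lo + off - 1
                    row = traj.loc[float(day)]
                    plant_c = _plant_c(params, day, boost)

                    def _delta(pool: Pool, excess: float, mass: float) -> float:
                        bg = _BACKGROUND_DELTA[pool]
                        if excess == 0.0:  # unlabelled arms stay exactly at background
                            return bg
                        return _delta_from_fraction(_atom_fraction(bg) + excess / mass)

                    d_plant = _delta(Pool.PLANT, row["plant"], plant_c)
                    d_soil = _delta(Pool.SOIL, row["soil"], params.soil_c_g)
                    d_co2 = _delta(Pool.CO2, row["co2"], params.chamber_co2_c_g)
                    d_ch4 = _BACKGROUND_DELTA[Pool.CH4] + p_photo / 100.0 * (
                        d_plant - _BACKGROUND_DELTA[Pool.PLANT]
                    )
                    labeled_delta = {
                        Pool.CO2: d_co2,
                        Pool.PLANT: d_plant,
                        Pool.SOIL: d_soil,
                        Pool.CH4: d_ch4,
                    }
                    masses = {
                        Pool.CO2: params.chamber_co2_c_g,
                        Pool.PLANT: plant_c,
                        Pool.SOIL: params.soil_c_g,
                        Pool.CH4: cum_ch4_c[(arm, st, day)],
                    }
                    for pool in Pool:
                        for trt, base in (
                            (control, _BACKGROUND_DELTA[pool]),
                            (labeled, labeled_delta[pool]),
                        ):
                            noise = (
                                rng.normal(0.0, params.noise_sd_permil)
                                if params.noise_sd_permil
                                else 0.0
                            )
                            mrows.append(
                                {
                                    "pool": pool.value,
                                    "treatment": trt.value,
                                    "stage": st.value,
                                    "day": day,
                                    "replicate": rep,
                                    "delta_permil": base + noise,
                                    "pool_c_mass_g": masses[pool],
                                }
                            )
            tracer[f"{arm}:{rep}"] = pd.concat(segs, ignore_index=True)
    measurements = pd.DataFrame(mrows)

    # chamber gas concentration series around the planted flux profiles
    temp_corr = 273.15 / (273.15 + params.temperature_c)
    va = 1.0  # 0.49 m3 / 0.49 m2
    closure_h = [0.0, 6.0, 12.0, 24.0, 36.0, 48.0, 72.0]
    sample_days = sorted(stage_table(params)["day"].unique())
    grows = []
    for arm in arms:
        for gas, base_ppm, molar in (
            ("CH4", 1.9, MOLAR_MASS["CH4"]),
            ("CO2", 410.0, MOLAR_MASS["CO2"]),
        ):
            conv = (molar / MOLAR_VOLUME_STP) * temp_corr * va
            for day in sample_days:
                if gas == "CH4":
                    flux = _ch4_flux_profile(
                        day, params.peak_ch4_flux[arm], params.total_days
                    )
                else:
                    flux = 30.0 * (params.organic_boost if arm == "O" else 1.0)
                slope = flux / conv  # ppm per hour
                for t in closure_h:
                    noise = (
                        rng.normal(0.0, params.flux_noise_ppm)
                        if params.flux_noise_ppm
                        else 0.0
                    )
                    grows.append(
                        {
                            "treatment": arm + "N",
                            "gas": gas,
                            "day": int(day),
                            "time_h": t,
                            "conc_ppm": base_ppm + slope * t + noise,
                            "temp_C": params.temperature_c,
                        }
                    )
    gas_df = pd.DataFrame(grows)

    brows = []
    for arm, boost in arms.items():
        for st, (lo, hi) in bounds.items():
            plant_c = _plant_c(params, hi, boost)
            brows.append(
                {
                    "arm": arm,
                    "stage": st.value,
                    "day": hi,
                    "plant_c_g": plant_c,
                    "biomass_g_m2": plant_c / 0.4 / area,
                }
            )
    biomass = pd.DataFrame(brows)

    return SyntheticDataset(
        measurements=measurements,
        gas=gas_df,
        biomass=biomass,
        tracer=tracer,
        truth=params,
    )


def simulate_abundance_table(
    n_taxa: int = 24,
    n_samples: int = 30,
    planted_edges: Sequence[tuple[str, str]] = (),
    seed: int = 0,
    n_factors: Optional[int] = None,
    noise_sd: float = 0.0,
):
    """Species × sample abundance table with planted monotone dependencies.

    Taxa latents are i.i.d. standard normal log-abundances; a planted
    (u, v) edge with both endpoints taxa copies u's latent into v (plus
    Gaussian noise of sd *noise_sd*), giving a monotone dependence that
    survives the per-sample closure to relative abundances.  A planted
    edge whose second endpoint is an environmental factor makes that
    factor a monotone (log) function of u's *relative* abundance.  All
    unplanted pairs are independent by construction.

    Returns (AbundanceTable, EnvironmentTable, truth-dict).
    """
    from .network import AbundanceTable, EnvironmentTable

    if n_samples < 10:
        raise ValueError("need at least 10 samples for MIC downstream")
    rng = np.random.default_rng(seed)
    taxa = list(METHANOGEN_SPECIES[:n_taxa])
    for i in range(len(taxa), n_taxa):
        taxa.append(f"Methanogen sp. OTU{i + 1}")
    factors = ENVIRONMENT_FACTORS[
        : (n_factors if n_factors is not None else len(ENVIRONMENT_FACTORS))
    ]
    samples = [f"S{i + 1}" for i in range(n_samples)]

    known = set(taxa) | set(factors)
    for u, v in planted_edges:
        missing = {u, v} - known
        if missing:
            raise ValueError(
                f"planted edge references unknown variables: {sorted(missing)}"
            )
        if u not in taxa:
            raise ValueError(f"planted edge source must be a taxon, got {u!r}")

    latent = {t: rng.normal(0.0, 1.0, n_samples) for t in taxa}
    for u, v in planted_edges:
        if v in latent:
            latent[v] = latent[u] + (
                rng.normal(0.0, noise_sd, n_samples) if noise_sd else 0.0
            )

    raw = np.exp(np.vstack([latent[t] for t in taxa]))
    rel = raw / raw.sum(axis=0, keepdims=True)
    abund = pd.DataFrame(rel, index=taxa, columns=samples)

    factor_rows = {}
    planted_targets = {v: u for u, v in planted_edges if v in factors}
    for f in factors:
        if f in planted_targets:
            src = abund.loc[planted_targets[f]].to_numpy()
            vals = np.log(src) + (
                rng.normal(0.0, noise_sd, n_samples) if noise_sd else 0.0
            )
        else:
            vals = rng.normal(0.0, 1.0, n_samples)
        factor_rows[f] = vals
    env = pd.DataFrame(factor_rows, index=samples).T

    truth = {
        "planted_edges": [tuple(e) for e in planted_edges],
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return AbundanceTable(abund), EnvironmentTable(env), truth
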