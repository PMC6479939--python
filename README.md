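# paddyflux

Partitioning the carbon sources of methane emitted from flooded rice
(paddy) soil, from ¹³CO₂ pulse-labelling pot experiments.

Flooded paddies are a major anthropogenic CH₄ source, and organic
fertilization raises their emissions. The question this package
addresses is *where the emitted carbon comes from*: freshly fixed
photosynthate, the applied organic fertilizer, or native soil organic
carbon. It is written for soil biogeochemists and greenhouse-gas
researchers who run static-chamber isotope-labelling experiments and
want the whole analysis chain — chamber fluxes, δ¹³C bookkeeping,
source partitioning, and methanogen co-occurrence networks — as tested,
scriptable functions.

## What it computes

**Isotope arithmetic** (`paddyflux.isotopes`). Delta notation against
Pee Dee Belemnite, δ¹³C (‰) = 1000·(R_sample − R_standard)/R_standard
with R the ¹³C/¹²C ratio; atom percent 100·R/(1+R); ¹³C excess mass of
a labelled pool over its unlabelled control; daily label accumulation
V (‰·d⁻¹) = (δ₂ − δ₁)/t; and biomass-normalised final δ¹³CH₄.

**Static-chamber fluxes** (`paddyflux.flux`). F (mg·m⁻²·h⁻¹) =
slope(ppm vs h) · (M/22.4) · 273.15/(273.15+T) · V/A, with negative
fluxes (CH₄ uptake) retained; cumulative emissions by trapezoidal
integration, reported in kg·ha⁻¹.

**Three-source partition** (`paddyflux.partition`). The photosynthesis
share p comes from a two-end-member mixing contrast between the
labelled treatment and its unlabelled control,
p = 100·Δδ¹³CH₄/Δδ¹³C_plant. The fertilizer contribution is bounded
above by assuming fertilizer C is fully as available as soil C:
fertilizer ≤ (fertilizer C / soil C)·(100 − p), and native soil
supplies at least the remainder. Pool-wise fractionation profiles
(percent of recovered ¹³C in CO₂ / plant / soil / CH₄) use atom-percent
excess × pool carbon mass. Contribution coefficients are reciprocal
regression slopes, K = 1/a, from OLS fits of daily pool δ¹³C
accumulation on daily δ¹³CH₄ accumulation.

**Co-occurrence networks** (`paddyflux.mic`, `paddyflux.network`). A
maximal-information-coefficient engine (grid budget B(n) = n^0.6,
exhaustive over all tie-respecting grids when enumeration is cheap,
MINE-style equipartition + dynamic programming otherwise), thresholded
into signed networks between methanogen species and soil factors, with
degree/density/clustering topology summaries and TSV/GraphML export.

**Synthetic experiments** (`paddyflux.simulate`). A generator that
emulates the staged pot design (two fertilizer arms × labelled/control,
three stages on fresh pots, three replicates) with a four-compartment
first-order ¹³C tracer model, returning ground truth alongside the
data so every pipeline stage has recovery tests.

## Worked example

```bash
python examples/01_three_source_partition.py
```

```
fertilizer C applied:        2.36 g
fertilizer : soil C ratio:   0.66%
CH4 C from photosynthesis:   49.06%
CH4 C from fertilizer:    <= 0.34%
CH4 C from native soil:   >= 50.6%
```

Reading: the pot received 10.24 g of manure at 23.05 % C, i.e. 2.36 g
fertilizer C against 359.67 g of topsoil C — a 0.66 % carbon ratio.
With 49.06 % of CH₄ carbon traced to photosynthate, even if *all*
fertilizer C were mineralised to CH₄ it could supply at most 0.66 % of
the remaining 50.94 points, i.e. 0.34 % — so native soil carbon must
contribute at least 50.60 %.

`examples/03_synthetic_experiment.py` runs the same analysis on a
simulated experiment with a planted 49 % photosynthesis share:

```
estimated photosynthesis share: 49.04% (planted 49.0%)
plant regression: slope 2.015, r2 0.999, p 6.08e-26  ->  K_r = 0.5
soil  regression: slope 0.099, r2 0.799, p 5.72e-07  ->  K_s = 10.15
```

K_s ≫ K_r: per unit of daily δ¹³CH₄ accumulation the soil pool's δ
moves far less than the plant pool's, i.e. CH₄ label accumulation is
much more sensitive to soil carbon turnover. The other examples cover
chamber fluxes (`02`) and the MIC network (`04`). A thin CLI wraps the
same functions: `paddyflux simulate | flux | partition | network |
report`.

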