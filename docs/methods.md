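# Methods

## Isotope bookkeeping

All δ¹³C values are per mil against Pee Dee Belemnite throughout the
package; conversions to atom ratios or atom percent happen only inside
operations. The PDB ¹³C/¹²C ratio is not a measured quantity here but a
reporting convention; the package fixes it at 0.0112372 (the
conventional value) and every operation that touches it accepts an
override. ¹³C *excess* of a labelled pool is atom-percent difference
against the unlabelled control times the pool's carbon mass, in grams
of ¹³C. Excess may be slightly negative under measurement noise; no
sign is imposed at the measurement level.

The biomass-normalised quantity `per_biomass_delta` divides the final
δ¹³CH₄ by chamber area (0.49 m² by default) and rice biomass exactly as
that quotient is conventionally written. Note the unit caveat: the
result is ‰ per m² per (g·m⁻²) and carries the usual ‰·g⁻¹ label only
when biomass is read per chamber. We implement the quotient literally
rather than reinterpreting it.

## Three-source partition

The partition rests on three ingredients:

1. **Photosynthesis share** p, from a two-end-member mixing model on
   the labelled/control treatment contrast:
   p = 100·(δ¹³CH₄,lab − δ¹³CH₄,ctl)/(δ¹³C_plant,lab − δ¹³C_plant,ctl).
   This is the minimal model consistent with a design that differs only
   in the chamber CO₂ label; it assumes non-photosynthetic CH₄ carbon
   is isotopically indistinguishable between treatments. Shares outside
   [0, 100] (possible under noise) are clipped with a warning.
2. **Fertilizer upper bound.** Fertilizer carbon is a small pool beside
   topsoil carbon. Assuming the worst case — every gram of fertilizer C
   as available to methanogens as native soil C — the fertilizer can
   supply at most its carbon-ratio share of the non-photosynthetic
   fraction: fert_max = (fert C/soil C)·(100 − p).
3. **Soil lower bound** as the remainder: soil_min = 100 − p − fert_max.

Reported values are rounded *half away from zero* to two decimals, and
the carbon ratio is rounded before it multiplies the non-photosynthetic
share. This ordering matters at the second decimal and is the package's
reporting convention; `digits=None` switches every step to raw
arithmetic. The topsoil carbon figure (default 359.67 g per pot) is a
measured input, never recomputed from bulk density and soil mass.

Fractionation profiles express each pool's share of the total recovered
¹³C excess; pools must therefore carry carbon masses, because raw δ
values across pools of wildly different size are not comparable.
Slightly negative pool excesses are clipped to zero with a warning
before normalisation; a non-positive total is an error.

Contribution coefficients are reciprocals of OLS slopes of daily pool
δ¹³C accumulation on daily δ¹³CH₄ accumulation, with a two-sided t-test
on the slope. Only two regressions are ever fit, so no multiple-testing
correction is applied. Whether the original analysis pooled both
fertilizer arms and all stages is not documented; the pipeline pools
them (two arms × three stages × three replicates), which is stated here
as the package's choice.

## Chamber fluxes

The flux formula is the standard static-chamber form: the OLS slope of
headspace concentration over the full closure (ppmv·h⁻¹), converted
with the ideal-gas molar volume 22.4 L·mol⁻¹, a 273.15/(273.15+T)
temperature correction and the chamber volume-to-area ratio. A
two-point closure falls back to the finite difference. Negative fluxes
are retained because CH₄ oxidation can produce net uptake. Cumulative
emissions integrate daily fluxes with the trapezoidal rule (a
deterministic, testable convention for sparse chamber campaigns) and
convert mg·m⁻² to kg·ha⁻¹. Linear OLS over the whole closure, rather
than two-point differences or nonlinear chamber models, is a documented
assumption; no leak diagnostics are attempted.

## Maximal information coefficient

For a grid with k columns on x and l rows on y, the score is
I(X;Y)/log₂ min(k, l); MIC maximises this over all grids with
k·l ≤ B(n) = n^0.6. B is floored at 4 so the 2×2 grid is always
admissible (at n = 10, n^0.6 ≈ 3.98 would otherwise admit nothing).
Grid lines may only fall between distinct data values, so tied points
never straddle a bin edge; edge signs use Spearman rank correlation
(average ranks for ties), with Pearson as an option.

Two search strategies sit behind one estimator:

* **Exhaustive**: enumerate every admissible tie-respecting grid and
  take the true maximum. Chosen automatically whenever the total
  enumeration is at most 20 000 grids — which covers all small samples
  (e.g. any n ≤ 12, where the budget only admits 2×2 grids) — and
  available by request via `NetworkConfig(exhaustive=True)`.
* **Approximate** (MINE-style): for every admissible (k, l), one axis
  is equipartitioned, the other collapsed into clumps of identical row
  membership (capped at c·k superclumps, c = 15), and column boundaries
  are optimised by an exact dynamic program over clump boundaries; both
  orientations are tried. The approximation searches a subset of the
  exhaustive space, so it can undershoot but never exceed the true
  maximum.

A small-sample caveat follows directly from the definition: with an odd
sample size the 2×2 grid cannot split the data into equal halves, so a
noiseless monotone pair at n = 25 scores H(12/25) = 0.99885 rather than
exactly 1.0; at even n the score is exactly 1.0. Constant vectors and
samples below n = 10 return 0 with a warning rather than an error.

The default edge threshold is 0.6 and configurable; a threshold of 0
keeps every pair, which reproduces the convention of building the
network from all relationships when the variable set is small. No
significance filter is applied beyond the threshold. Species–species
edges are classed apart from edges involving environmental factors.
Topology reports node degrees, edge count, density 2E/(N(N−1)) and mean
local clustering.

## Synthetic pot experiment

The generator emulates the staged design: two fertilizer arms (C = no
fertilizer, O = organic) × labelled/unlabelled chamber (Y/N), stages of
9, 27 and 33 days on *fresh pots each stage*, three replicates, gas
sampling at 0–72 h after labelling starts and every five days
thereafter. Within a stage, ¹³C excess mass moves through four
compartments — chamber CO₂ → plant → soil, with plant and soil both
feeding CH₄ — by first-order kinetics integrated with 0.25 d Euler
steps; the chamber pool is topped up to the target enrichment once per
day, and total excess is conserved between top-ups to machine precision
(an invariant under test).

Key parameter choices, with rationale:

| parameter | default | meaning |
|---|---|---|
| `label_pulse_permil` | 5000 ‰ | chamber CO₂ enrichment above background during labelling; yields plant enrichments of order 10²–10³ ‰, typical of pulse studies |
| `uptake_rate` | 0.25 d⁻¹ | fraction of chamber CO₂ excess fixed per day at full canopy |
| `uptake_maturity_exponent` | 2 | canopy light capture grows superlinearly during establishment and tillering |
| `rhizodeposition_rate` | 0.02 d⁻¹ | plant → soil transfer |
| `plant_to_ch4_rate`, `soil_to_ch4_rate` | 0.008, 0.0005 d⁻¹ | substrate flow to methanogenesis |
| `pot_sd` | 0.25 | lognormal sigma of the per-pot uptake multiplier (biological variability; this is what spreads the contribution regressions) |
| `organic_boost` | 1.3 | fertilized arm's multiplier on uptake and biomass |
| `noise_sd_permil` | 0.5 ‰ | Gaussian δ measurement noise, matching typical IRMS accuracy (±0.3–0.5 ‰) |
| `true_source_shares` | 49 / 0.34 / 50.66 % | planted partition, so recovery tests and the analysis chain share fixtures |
| `peak_ch4_flux` | 0.16 / 0.46 mg·m⁻²·h⁻¹ | planted flux peaks (control/organic) on day 30, the tillering maximum |

Plant biomass follows saturating growth from the transplanted-seedling
carbon mass (5 g C) toward harvest mass (30 g C) with a 25 d timescale.
Measured δ¹³CH₄ in labelled arms is generated by the two-end-member
mixing identity δ¹³CH₄ = δ_bg + (p/100)(δ¹³C_plant − δ_bg,plant) —
i.e. the generator *is* the estimator's model, so the planted share is
recovered exactly at zero noise, and replicate averaging preserves the
identity because it is linear. Chamber gas series are straight lines in
time whose slopes invert the flux formula at the planted rates, plus
Gaussian ppm noise.

Abundance tables are log-normal (i.i.d. standard-normal latents,
exponentiated and closed to relative form per sample); planted
taxon–taxon edges copy latents (plus optional noise), which survives
closure because both taxa share the per-sample denominator, and planted
taxon–factor edges make the factor a monotone function of the taxon's
relative abundance. Unplanted pairs are independent by construction
(before closure).

What the generator deliberately does **not** emulate: CH₄ oxidation and
transport dynamics, priming feedbacks between fertilizer and soil pools
(the planted shares are constants, not emergent), compositional
sequencing noise or read-level artefacts, within-chamber spatial
gradients, or day-to-day weather forcing of fluxes. Passing recovery
tests therefore demonstrates that the analysis chain is correct and
well-conditioned under the stated noise model — not that the stated
bounds are robust to violations of the two-end-member assumption in
real soils.

## Numerical conventions and problem sizes

* Rounding of reported percentages: half away from zero (`Decimal`),
  never banker's rounding.
* Euler step 0.25 d; the tracer's conservation residual is checked to
  ≤ 1e−9 relative.
* OLS via closed-form normal equations (scipy.stats.linregress), slope
  p-values from the t distribution.
* Degenerate inputs: constant x in a regression, non-positive mixing
  denominator, empty gas series and unordered times are errors;
  constant MIC inputs warn and return 0.
* Test problem sizes: parameter-recovery acceptance uses 100 simulated
  experiments (69 days each) at 5 ‰ noise with a ±5-point criterion at
  the 95 % level; the MIC null check uses n = 200 with a 150-permutation
  band and 50 replicate pairs; brute-force MIC agreement is asserted
  for n ≤ 12 where the grid budget admits only 2×2 grids.

## Known limitations

* The fertilizer bound is an inequality, not an estimate; no Bayesian
  mixing (MixSIAR-style) posterior is attempted, and ¹⁵N is out of
  scope.
* The MIC approximation is heuristic for large n; only small-n results
  carry an exactness guarantee.
* The pipeline's regression pooling (arms × stages × replicates) is one
  defensible choice among several; with other poolings the coefficients
  will differ.
* `run_pipeline` estimates the photosynthesis share from the final
  sampling day only; earlier days carry weaker label signal and are
  used for the accumulation regressions instead.
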