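"""Static-chamber CH4 flux from one closure, and a seasonal emission total.

A closed chamber accumulates CH4; the flux is the OLS slope of the
concentration series converted to mass per area per hour, and seasonal
emissions integrate daily fluxes with the trapezoidal rule.
"""

import paddyflux as pf
from paddyflux.flux import Gas, GasSampleSeries

# one 72 h closure: headspace CH4 climbing ~0.11 ppm/h at 25 degC
series = GasSampleSeries(
    gas=Gas.CH4,
    times_h=(0, 6, 12, 24, 36, 48, 72),
    conc_ppm=(1.92, 2.55, 3.21, 4.50, 5.86, 7.19, 9.83),
    temperature_c=25.0,
    geometry=pf.ChamberGeometry(area_m2=0.49, volume_m3=0.49),
    day=30,
)
rec = pf.chamber_flux(series)
print(f"slope: {rec.slope_ppm_h:.4f} ppm/h  (r2 = {rec.r2:.4f})")
print(f"flux on day {rec.day}: {rec.flux_mg_m2_h:.3f} mg CH4 m-2 h-1")

# a coarse season: fluxes rise to a tillering peak then decline
days = [1, 10, 20, 30, 40, 55, 69]
fluxes = [0.02, 0.15, 0.31, 0.46, 0.38, 0.22, 0.10]
total = pf.cumulative_emission(days, fluxes)
print(f"seasonal emission: {total:.2f} kg CH4 ha-1")
# The flux is the instantaneous emission rate; the seasonal total is its
# time integral expressed per hectare.
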