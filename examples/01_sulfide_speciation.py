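"""Total dissolved sulfide from paired H2S and pH microprofiles.

Amperometric H2S sensors see only the gaseous species; at porewater pH
much of the sulfide pool is HS⁻.  This example builds a small paired
profile, computes pK1 for cold brackish water, and speciates ΣH2S at each
depth.
"""

import numpy as np

from sedflux import SoluteProfile, SpeciationParams, pk1, speciate_profile

# pK1 of H2S/HS⁻ under deep-basin conditions (8 °C, salinity 7)
print(f"pK1(25 °C, S=0)  = {pk1(25, 0):.2f}   (fresh water reference)")
print(f"pK1(25 °C, S=35) = {pk1(25, 35):.2f}   (open-ocean reference)")
print(f"pK1( 8 °C, S=7)  = {pk1(8, 7):.2f}   (cold brackish bottom water)")

# a sulfide profile appearing below 3 mm, with pH declining over depth
depths = np.arange(0.0, 8.01, 0.25)
h2s_sensor = np.clip(30.0 * (depths - 3.0), 0, None) / 2.5  # gas fraction only
ph_vals = 7.8 - 0.15 * depths

h2s = SoluteProfile("H2S", depths, h2s_sensor, resolution_um=250)
ph = SoluteProfile("pH", depths, ph_vals, resolution_um=250)

result = speciate_profile(h2s, ph, SpeciationParams(temperature_c=8, salinity=7))

print("\ndepth_mm   pH    [H2S]_uM  [HS-]_uM  Sum_uM")
for i in range(12, len(depths), 4):
    print(f"{result.depths[i]:7.2f} {result.ph_used[i]:6.2f} "
          f"{result.h2s_gas[i]:9.2f} {result.hs_minus[i]:9.2f} {result.total[i]:8.2f}")

print(
    "\nAt pH above pK1 the HS⁻ share dominates: the sensor alone would "
    "undercount total sulfide several-fold, which is why ΣH2S, not the raw "
    "signal, enters the flux and budget calculations."
)
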