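"""Shear and transport conditions in the culture channel.

Computes, for each flow regime of the study, the volumetric flow rate that
produces the regime's wall shear rate in a 10 mm x 1 mm x 150 um channel,
the shear stress on the attached monolayer, and the oxygen/nutrient
Damkohler numbers confirming that growth is not transport-limited.
"""

from shearcolony.channel import (PAPER_REGIMES, ChannelGeometry,
                                 TransportParams, damkohler_numbers,
                                 flow_rate_for_shear, shear_stress)

geometry = ChannelGeometry()
print(f"channel: {geometry.length_L*1e3:.0f} x {geometry.width_w*1e3:.0f} "
      f"x {geometry.height_h*1e6:.0f} (mm x mm x um)\n")

print(f"{'regime':>6} {'shear (1/s)':>12} {'stress (mPa)':>13} "
      f"{'Q (uL/min)':>11}")
for regime in PAPER_REGIMES:
    q = flow_rate_for_shear(geometry, regime.shear_rate_s)
    stress = shear_stress(regime.shear_rate_s)
    print(f"{regime.name:>6} {regime.shear_rate_s:>12.0f} {stress:>13.1f} "
          f"{q * 6e10:>11.2f}")

# transport check at the densest monolayer coverage (late in a movie,
# when the perfusion is well established)
params = TransportParams(B=2e11, v_mean=7e-4, D_O2_pdms=3.4e-9)
da_o2, da_n = damkohler_numbers(params, geometry)
print(f"\nDamkohler numbers at B = 2e11 cells/m^2, v = 7e-4 m/s:")
print(f"  Da_O2 = {da_o2:.2e}   Da_nutrient = {da_n:.2e}")
print("both << 1: oxygen diffusion through the membrane and glucose")
print("advection outrun consumption, so shear is the only variable.")
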