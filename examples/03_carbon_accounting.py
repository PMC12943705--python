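"""Carbon emissions of heating the process streams, and the greenness scorecard.

Heating 1/wi + lam_a/wj kg of stream per kg of lanolin from 25 degC to the
reaction temperature with natural gas emits
mass x c_spec x (T - 25) x EF / 1e6 kg CO2, with EF = 0.1424 kg CO2 per MJ
for the standard fuel constants.
"""

import greenflow as gf

mp = gf.MaterialProperties()
k = gf.EmissionConstants()

print(f"fuel emission factor: {gf.emission_factor(k):.5f} kg CO2/MJ")

optimised = gf.ProcessConditions(T=70, t0=5, wi=0.25, lam_a=0.116)
hot_dilute = gf.ProcessConditions(T=90, t0=5, wi=0.15, lam_a=0.119)
for label, pc in [("optimised (70 degC, wi=0.25)", optimised),
                  ("hot & dilute (90 degC, wi=0.15)", hot_dilute)]:
    em = gf.carbon_emission(pc, mp, k)
    print(f"{label}: heated mass {gf.heated_mass(pc, mp):.2f} kg/kg, "
          f"emission {em:.3f} kg CO2 / kg lanolin")
print("Cooler, more concentrated operation cuts the heating duty and with it the emission.")

# 12-principle green-chemistry scorecard: 0-10 per principle, 120 maximum
card = gf.greenness_total([9, 9, 8, 7, 8, 9, 7, 8, 6, 7, 7, 8])
print(f"\ngreenness score: {card.total:.0f} / 120")
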