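"""Drought and CO2 scenario experiments at a single synthetic site.

Generates two years of 3-hourly forcing whose second year is a
rainfall-suppressed drought, then runs the control (CTL), a 20% drier
drought (rPPT) and the drier drought under doubled CO2 (eCO2 x rPPT).
Psi_min is the deepest leaf water potential reached (vs the species' P50)
and max PLC the worst conductivity loss: drier -> deeper Psi_min, higher
PLC; doubled CO2 saves water and relieves both.
"""

import pandas as pd

import profitmax as pm

registry = pm.load_species_registry()
species = registry["E. blakelyi"]

spec = pm.ClimateSpec(
    map_mm_yr=700.0,
    drought_start=pd.Timestamp("2018-01-01"),
    drought_end=pd.Timestamp("2018-12-31"),
    drought_rain_factor=0.6,
)
forcing = pm.generate_forcing(spec, years=2, seed=7)
soil = pm.default_profile(theta_frac=0.7)

outputs = pm.run_scenarios(forcing, species, soil, pm.RunConfig(lai=1.5))

print(f"{species.species_name}: P50 = {species.P50} MPa\n")
for name, out in outputs.items():
    s = pm.summarise(out, species)
    print(
        f"{name:<10} psi_min {s['psi_min']:7.2f} MPa   "
        f"max PLC {s['max_plc']:5.1f}%   "
        f"months below P50: {s['months_below_p50']}"
    )
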