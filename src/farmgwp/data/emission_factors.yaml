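# Default emission-factor set, version-tagged so results can record provenance.
# Values are editable Tier-1-style defaults seeded from the 2019 refinement of
# the IPCC inventory guidelines where a Tier-1 factor exists; operation energy
# coefficients and embedded-manufacture factors are representative UK figures.
version: "factors-2026.1-default"

enteric_ch4:            # kg CH4 head-1 yr-1
  dairy_cow: 126.0
  other_cattle: 52.0
  sheep: 9.0
  pig: 1.5
  poultry: 0.02

manure_ch4:             # kg CH4 head-1 yr-1 by storage system
  dairy_cow: {slurry: 31.0, solid: 4.0, pasture: 1.6}
  other_cattle: {slurry: 6.0, solid: 2.0, pasture: 0.6}
  sheep: {slurry: 0.0, solid: 0.15, pasture: 0.1}
  pig: {slurry: 6.0, solid: 1.0, pasture: 0.3}
  poultry: {slurry: 0.0, solid: 0.02, pasture: 0.01}

excreted_n:             # kg N head-1 yr-1
  dairy_cow: 115.0
  other_cattle: 50.0
  sheep: 12.0
  pig: 12.0
  poultry: 0.6

ef1_direct: 0.01        # kg N2O-N per kg N applied to managed soils
ef3_prp: 0.004          # kg N2O-N per kg N deposited by grazing animals
ef4_volat: 0.01         # kg N2O-N per kg NH3-N + NOx-N volatilised
ef5_leach: 0.011        # kg N2O-N per kg N leached or in runoff
frac_leach: 0.24        # fraction of applied N leached

volat_fraction:         # fraction of N volatilised as NH3-N + NOx-N
  fertilizer: {broadcast: 0.11, band: 0.06, incorporated: 0.03}
  manure: {broadcast: 0.21, band: 0.12, incorporated: 0.05}
  housing: 0.20         # applied to N excreted into housed (non-pasture) systems

energy:                 # kg CO2 per operation unit
  cultivation_pass_per_ha: 45.0
  spray_pass_per_ha: 3.0
  spread_pass_per_ha: 6.0
  milking_per_head: 150.0      # dairy cows only
  housing_per_head:
    dairy_cow: 100.0
    other_cattle: 40.0
    sheep: 2.0
    pig: 30.0
    poultry: 0.15
  drying_per_tonne: 30.0       # grain drying

embedded_fert: 6.8      # kg CO2 eq per kg manufactured fertiliser N
embedded_pest: 22.0     # kg CO2 eq per kg pesticide active ingredient
pesticide_rate_kg_per_ha: 1.5  # a.i. applied per sprayed hectare-pass-season

crops:                  # agronomic defaults per crop
  #            kg N/ha  cult  spray  fert   yield  dried
  #            fert     pass  pass   apps   t/ha
  winter_wheat:   {fert_n: 190.0, cult_passes: 3, spray_passes: 4, fert_apps: 2, yield_t_ha: 8.2, dried: true}
  spring_barley:  {fert_n: 110.0, cult_passes: 3, spray_passes: 3, fert_apps: 2, yield_t_ha: 5.9, dried: true}
  oilseed_rape:   {fert_n: 190.0, cult_passes: 3, spray_passes: 4, fert_apps: 2, yield_t_ha: 3.3, dried: true}
  field_beans:    {fert_n: 0.0,   cult_passes: 3, spray_passes: 3, fert_apps: 0, yield_t_ha: 3.8, dried: true}
  potatoes:       {fert_n: 160.0, cult_passes: 4, spray_passes: 8, fert_apps: 2, yield_t_ha: 45.0, dried: false}
  sugar_beet:     {fert_n: 100.0, cult_passes: 3, spray_passes: 4, fert_apps: 2, yield_t_ha: 70.0, dried: false}
  vegetables:     {fert_n: 150.0, cult_passes: 4, spray_passes: 6, fert_apps: 2, yield_t_ha: 25.0, dried: false}
  orchard:        {fert_n: 80.0,  cult_passes: 1, spray_passes: 8, fert_apps: 1, yield_t_ha: 12.0, dried: false}
  maize_silage:   {fert_n: 120.0, cult_passes: 3, spray_passes: 2, fert_apps: 2, yield_t_ha: 42.0, dried: false}
  grass:          {fert_n: 100.0, cult_passes: 0.3, spray_passes: 0.2, fert_apps: 2, yield_t_ha: 0.0, dried: false}
  rough_grazing:  {fert_n: 0.0,   cult_passes: 0.0, spray_passes: 0.0, fert_apps: 0, yield_t_ha: 0.0, dried: false}
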