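# Robust farm-type profiles used by the synthetic generator. Area-share targets
# follow the national shares of the nine robust types (cereals ~33%; general
# cropping, lowland and LFA grazing ~15% each; dairy and mixed ~10%;
# horticulture, pigs and poultry together <2%). Livestock densities, crop
# mixes, typical sizes and production values are editable generator defaults.
profiles:
  cereals:
    rainfall_cap_mm: 900
    area_share: 0.33
    mean_farm_size_ha: 160
    production_value_gbp_per_ha: 1100
    crop_mix: {winter_wheat: 0.50, spring_barley: 0.20, oilseed_rape: 0.15, field_beans: 0.10, grass: 0.05}
    livestock_density: {}
    manure_system_split: {}
  general_cropping:
    rainfall_cap_mm: null
    area_share: 0.15
    mean_farm_size_ha: 150
    production_value_gbp_per_ha: 1800
    crop_mix: {winter_wheat: 0.30, potatoes: 0.20, sugar_beet: 0.20, vegetables: 0.15, spring_barley: 0.15}
    livestock_density: {}
    manure_system_split: {}
  horticulture:
    rainfall_cap_mm: null
    area_share: 0.007
    mean_farm_size_ha: 40
    production_value_gbp_per_ha: 9000
    crop_mix: {vegetables: 0.60, orchard: 0.25, winter_wheat: 0.15}
    livestock_density: {}
    manure_system_split: {}
  lowland_grazing:
    rainfall_cap_mm: null
    area_share: 0.15
    mean_farm_size_ha: 60
    production_value_gbp_per_ha: 700
    crop_mix: {grass: 0.90, rough_grazing: 0.10}
    livestock_density: {other_cattle: [0.8, 1.5], sheep: [2.0, 6.0]}
    manure_system_split: {slurry: 0.15, solid: 0.25, pasture: 0.60}
  lfa_grazing:
    rainfall_cap_mm: 700        # printed constraint; see enforce_lfa_rainfall_cap
    area_share: 0.15
    mean_farm_size_ha: 120
    production_value_gbp_per_ha: 450
    crop_mix: {grass: 0.50, rough_grazing: 0.50}
    livestock_density: {other_cattle: [0.2, 0.6], sheep: [3.0, 8.0]}
    manure_system_split: {slurry: 0.05, solid: 0.20, pasture: 0.75}
  dairy:
    rainfall_cap_mm: null
    area_share: 0.10
    mean_farm_size_ha: 120
    production_value_gbp_per_ha: 2600
    crop_mix: {grass: 0.85, maize_silage: 0.10, winter_wheat: 0.05}
    livestock_density: {dairy_cow: [1.2, 2.2], other_cattle: [0.8, 1.4]}
    manure_system_split: {slurry: 0.60, solid: 0.15, pasture: 0.25}
  mixed:
    rainfall_cap_mm: null
    area_share: 0.10
    mean_farm_size_ha: 130
    production_value_gbp_per_ha: 1100
    crop_mix: {winter_wheat: 0.25, spring_barley: 0.15, grass: 0.45, field_beans: 0.10, rough_grazing: 0.05}
    livestock_density: {other_cattle: [0.4, 1.0], sheep: [1.0, 3.0]}
    manure_system_split: {slurry: 0.20, solid: 0.30, pasture: 0.50}
  pigs:
    rainfall_cap_mm: null
    area_share: 0.006
    mean_farm_size_ha: 30
    production_value_gbp_per_ha: 5500
    crop_mix: {grass: 0.40, winter_wheat: 0.40, spring_barley: 0.20}
    livestock_density: {pig: [15.0, 40.0]}
    manure_system_split: {slurry: 0.60, solid: 0.35, pasture: 0.05}
  poultry:
    rainfall_cap_mm: null
    area_share: 0.007
    mean_farm_size_ha: 20
    production_value_gbp_per_ha: 9000
    crop_mix: {grass: 0.50, winter_wheat: 0.50}
    livestock_density: {poultry: [500.0, 2000.0]}
    manure_system_split: {solid: 1.0}

# Catchment generator defaults: 90 units, areas 105-4000 km2 with mean ~1500,
# rainfall on a west(high)-east(low) gradient proxy.
catchments:
  n_default: 90
  area_km2_min: 105
  area_km2_max: 4000
  area_km2_mean: 1500
  rainfall_mm_west: 1300
  rainfall_mm_east: 620
  rainfall_mm_sd: 90
  rainfall_mm_floor: 550
  rainfall_mm_ceiling: 1800
  uaa_fraction_range: [0.40, 0.80]

generator:
  farms_per_catchment_mean: 40
  holding_count_mean: 30          # geometric; per-catchment total optional
  holding_total_per_catchment: null
  crop_utilisation: 0.97          # cropped fraction of farm area
  fert_rate_cv: 0.10
  enforce_lfa_rainfall_cap: true
  spreading_method_probs: {broadcast: 0.70, band: 0.20, incorporated: 0.10}
  manure_retained_fraction: 0.5   # share of excreted N collected and land-applied

# Export-coefficient water-loads model: a transparent structural stand-in for
# a full catchment water-quality model. kg ha-1 yr-1 base coefficients.
water_export:
  nitrate_n:   {cereals: 30, general_cropping: 35, horticulture: 30, lowland_grazing: 15, lfa_grazing: 6, dairy: 30, mixed: 22, pigs: 40, poultry: 35}
  phosphorus:  {cereals: 0.6, general_cropping: 0.9, horticulture: 0.8, lowland_grazing: 0.5, lfa_grazing: 0.3, dairy: 1.0, mixed: 0.7, pigs: 1.2, poultry: 1.0}
  sediment:    {cereals: 500, general_cropping: 600, horticulture: 550, lowland_grazing: 150, lfa_grazing: 200, dairy: 250, mixed: 400, pigs: 450, poultry: 300}
  nitrate_per_kg_n: 0.15          # incremental leached NO3-N per kg N applied
  rainfall_reference_mm: 900      # modifier = rainfall / reference
  drainage_modifier: {free_draining: 1.0, drained_arable: 0.85, drained_arable_grass: 0.7}
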