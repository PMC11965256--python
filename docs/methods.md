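# Methods

## Scope and design

`farmgwp` is a desk-scale implementation of a model-farm pipeline for
greenhouse-gas accounting over English water management catchments (WMCs).
A model farm is an attribute bundle — robust farm type, area, crop areas,
livestock cohorts, rainfall, drainage class, nitrate-vulnerable-zone flag —
standing for `holding_count` real holdings. Geography is deliberately
abstract: catchments carry attributes, not polygons, and the west-high /
east-low rainfall gradient is a scalar covariate. Mapping, national
inventory comparison and waterbody status classification are out of scope.

## Synthetic population

The generator emulates the structure of the survey inputs such a study
draws on, without any of their data:

- **Catchments.** `n` units (default 90) with gamma-distributed areas
  rejected outside 105–4000 km², configurable mean 1500 km². Mean rainfall
  interpolates linearly between a western (1300 mm) and an eastern (620 mm)
  anchor along a uniform position covariate, with 90 mm noise, clipped to
  550–1800 mm. Utilised agricultural area is a uniform 40–80% fraction of
  the catchment. Drainage-class proportions are Dirichlet(2,2,2); the NVZ
  fraction rises toward the dry end (≈0.64 at 620 mm, ≈0 at 1300 mm),
  mirroring the arable-east designation pattern.
- **Farms.** National area-share targets (cereals 33%; general cropping,
  lowland and LFA grazing 15% each; dairy and mixed 10%; horticulture, pigs
  and poultry <2% combined) are renormalised over the types whose rainfall
  constraints admit the catchment; each type's farm sizes are lognormal
  (σ=0.45) around its typical size and rescaled so the type's summed area
  hits its share exactly. Livestock cohorts draw uniform densities from the
  profile's range; livestock-free profiles always yield empty cohorts.
  Holding counts are geometric with mean 30 (the surveys' counts are not
  public); a configured per-catchment total is honoured by largest-remainder
  rescaling. Production value is a configured constant per type and hectare,
  used only for valuation ratios.
- **Rainfall caps.** Cereals are capped at 900 mm. The LFA cap of 700 mm is
  stored exactly as configured with an `enforce_lfa_rainfall_cap` switch
  (default on): an *upper* limit sits oddly with upland grazing, and with
  the cap enforced LFA farms concentrate in drier catchments and their
  national area share falls well below its 15% target. Per-catchment share
  targeting (the tested property) is unaffected; disable the switch for a
  population where LFA tracks its national share.
- **Practice.** Per-crop fertiliser rates are normal around configured
  national means (CV 10%, truncated at zero). Manure N applied equals total
  excreted N × a retained fraction (default 0.5); the remainder follows the
  type's manure-system split, whose `pasture` component routes excreta to
  grazing deposition. Spreading method is categorical
  (broadcast/band/incorporated, 0.7/0.2/0.1).

All generators are pure functions of (config, seed); per-farm substreams
derive from the root seed via CRC32 of string tokens, so results are stable
across processes and insertion orders.

## Emission factors

Factor values are an editable, version-tagged YAML configuration
(`factors-2026.1-default`), seeded from Tier-1 values of the 2019
refinement of the IPCC inventory guidelines where such a factor exists
(EF₁ = 0.01, EF₃ = 0.004, EF₄ = 0.01, EF₅ = 0.011, FracLEACH = 0.24;
enteric CH₄ 126 kg/head/yr for dairy cows, 52 for other cattle, 9 for
sheep). Ammonia volatilisation is a lookup by nitrogen source and spreading
method (band < broadcast; incorporation lowest) plus a housing fraction —
a deliberate reduction of a full ammonia model to the mechanism the
pipeline needs. Operation energy coefficients and embedded-manufacture
factors (6.8 kg CO₂e/kg N; 22 kg CO₂e/kg a.i.) are representative UK
figures; pesticide mass is sprayed area × passes × a configurable rate.
Every result table records the factor-set version.

N₂O leaves the engine as N₂O mass (44/28 applied at the boundary) because
the warming-potential coefficient 273 is defined per unit N₂O. Embedded CO₂
is kept separate from energy CO₂ and enters GWP only when requested; both
variants are always reported.

## Scenario engine

Uptake is the fraction of a model farm's represented holdings implementing
a measure, so expected efficacy scales linearly with uptake before
stacking. Stacking is multiplicative on residual fractions, order-invariant,
subadditive, and capped at 100%; individual efficacies above 100% are
rejected. Baseline uptake ranges resolve by a per-(farm, measure) seeded
uniform draw shared across pollutants; single printed rates are fixed;
the maximum-feasible scenario sets every applicable measure to 100%.
Efficacy ranges (e.g. "−50 to 25") resolve to the midpoint by default.
Per-pollutant stacks are independent: pollution swapping enters only
through a measure's own signed efficacies (a positive value increases the
pollutant, as with the extra drying energy under autumn cover crops).

The packaged catalogue merges three verbatim transcriptions of the printed
measure tables (24 measures with uptake ranges, 41 with single rates, and
the ten-measure N₂O/energy/biodiversity shortlist) with
`measure_efficacy_defaults_synthetic.csv`, an implementer-supplied defaults
file providing applicability and efficacies for pollutants the printed
tables do not cover (CH₄ and the water pollutants). Those defaults are
plausible magnitudes, not survey or experimental values, and are flagged
synthetic in the filename and header. One steading-runoff wetland measure
appears only in the shortlist; it receives a nominal 2% baseline uptake in
the defaults file.

## Aggregation statistics

Percentiles of a weighted farm set are defined as linear interpolation
between adjacent order statistics of the holding-count-expanded population,
computed from cumulative weights; for integer weights this equals
`np.percentile(np.repeat(values, weights), q)` exactly, which is the tested
oracle. The dispersion statistic is the non-parametric
`CV = (P95 − P5)/median × 100`; zero medians (the livestock-free CH₄
columns) report as missing rather than infinite. Both weighted and
unweighted modes are exposed because the source tables do not state which
was used. Normalisation divides by utilised agricultural area, not total
catchment area.

## Co-benefits

Baseline water loads use an export-coefficient model — a transparent
structural stand-in for a full catchment water-quality model: per-type
base coefficients (kg/ha/yr) scaled by rainfall (relative to 900 mm) and a
drainage-class modifier, plus 0.15 kg leached NO₃-N per kg N applied.
Coefficients are editable and synthetic. Biodiversity benefit is additive
across measures (scores are ordinal indices, not percentages), scaled by
uptake; methane efficacies never contribute to the score.

## What the defaults do and do not show

Passing tests demonstrate the *mechanics* — conservation, linearity,
stacking oracles, orderings — and the qualitative structure of the
reference fixtures: zero CH₄ for livestock-free types, dairy highest in
per-ha CH₄ (≈309 kg/ha at mid densities) and GWP20, and GWP20 more than
double GWP100 for the non-specialist grazing systems. They do not
demonstrate national statistics: the synthetic population's
maximum-feasible medians (≈37% for GWP20, 76–86% for sediment and
phosphorus co-benefits at seed 1) are higher than a source-apportioned
catchment model would give, because the desk-scale stand-in applies
whole-farm efficacies to total loads rather than to the source fractions
each measure actually touches. The efficacy defaults were set once from the
printed shortlist plus plausible magnitudes and are not calibrated to
reproduce national medians.

## Numerical choices

- Problem sizes: the default pipeline run uses 90 catchments (≈3850 model
  farms, ~20 s single-core); tests use 2–3 catchments, and the large
  constraint sweep checks ~10⁴ farms.
- Valuation reporting: £/£ to 2 decimals, £/t to the nearest pound,
  matching the precision such figures are quoted at. Note 4.2 × 361/1000 =
  1.5162 reports as 1.52.
- Fixture-table IO uses `float_precision="round_trip"` on read; the default
  CSV float parser is not correctly rounded and breaks lossless round-trips.
- Zero baselines in percentage reductions report as missing (NaN), never 0.
- Degenerate inputs: empty cohorts/crops yield exact zeros; empty measure
  catalogues are valid (warned) and leave emissions unchanged.

## Known limitations

- Tier-1 arithmetic only: no animal energy-balance or soil process
  representation, by design.
- The ammonia lookup and export-coefficient water model are structural
  stand-ins, not reimplementations of the models they replace.
- Manure movement between farms, regional practice variation, and
  cost/practicability constraints on measure uptake are not represented.
- GWP* and other dynamic warming metrics are not implemented.
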