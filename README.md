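# farmgwp

Farm-scale greenhouse-gas accounting, mitigation scenarios and co-benefit
analysis for English water management catchments.

## The problem

Agriculture is a leading source of methane and nitrous oxide, and national
1-km inventory grids do not map onto the management units policy teams use.
`farmgwp` implements a model-farm approach at the water-management-catchment
(WMC) scale: representative model farms — unique combinations of robust farm
type and intrinsic environment (rainfall, soil drainage) — carry the
emission arithmetic, and holding counts scale them up to catchments. The
package is aimed at agri-environmental modellers and policy analysts who
want a transparent, fully seeded desk-scale version of this pipeline:
because the underlying survey data (June Agricultural Survey, fertiliser
practice surveys, rainfall and soil products) are not redistributable, a
first-class synthetic generator reproduces their statistical structure so
every stage is testable without any download. Real data in the same table
schemas drop in directly.

## The model

**Emissions.** Annual farm totals use Tier-1-style factor tables: enteric
and manure-management CH₄ per head; direct soil N₂O from applied fertiliser
and manure N (EF₁) and excreta deposited at grazing (EF₃); indirect N₂O from
volatilised N (EF₄, with an ammonia-volatilisation fraction indexed by
nitrogen source and spreading method) and leached N (EF₅, FracLEACH); energy
CO₂ from an itemised operation inventory (cultivation, spraying, spreading,
milking, housing, grain drying); and embedded CO₂ from fertiliser and
pesticide manufacture, kept separate. N₂O-N converts to N₂O mass by 44/28.

**Warming potential.** Gas masses convert to CO₂ equivalents with fixed
coefficients — 273 for N₂O at both horizons, 81.2 (GWP20) and 27.9 (GWP100)
for CH₄ — reported with and without embedded emissions, plus per-gas shares.

**Mitigation.** A catalogue of on-farm measures carries signed per-pollutant
efficacies (negative = reduction), baseline uptake rates and biodiversity
scores. Measure interactions are multiplicative, not additive:

```
E_t = 100 · (1 − Π_i (1 − E_i/100))
```

where `E_i` is measure *i*'s reduction (%) scaled linearly by its uptake
(the fraction of represented holdings implementing it). Business as usual
resolves current uptake; the maximum technically feasible scenario sets
uptake to 100%.

**Aggregation.** Catchment totals multiply per-farm values by holding counts
and are normalised by utilised agricultural area. Dispersion uses weighted
percentiles (linear interpolation on the holding-count-expanded population)
and the non-parametric coefficient of variation
`CV = (P95 − P5) / median × 100`.

**Co-benefits.** Water loads come from a transparent export-coefficient
stand-in (area × coefficient × rainfall × drainage modifiers, with a linear
nitrate term in applied N); the same efficacy stacking gives per-pollutant
co-benefit percentages, and an additive uptake-scaled index scores
terrestrial-biodiversity benefit.

## Worked example

```bash
farmgwp run --seed 1 --out out/            # or: python analysis/01_generate_population.py
python analysis/04_mitigation_potential.py
python analysis/06_carbon_valuation.py
```

The default run (90 synthetic catchments, seed 1) prints:

```
pipeline run complete: 3854 model farms in 90 catchments (seed 1)
GWP20: technically feasible reduction across catchments 33.0-41.4%, median 36.8%
GWP100: technically feasible reduction across catchments 35.7-46.6%, median 38.9%
carbon value per pound of production (BAU): {'low': 0.5, 'central': 1.01, 'high': 1.52}
after ~24% technically feasible mitigation: {'low': 0.38, 'central': 0.77, 'high': 1.15}
production value per tonne CO2 eq: GBP 238
```

Reading these numbers: every pound of farm production under business as
usual carries about 4.2 kg CO₂ eq over a 20-year horizon, so at the central
2020 carbon value (£241/t) the climate cost of a pound of production is
about £1.01, and a tonne of CO₂ eq corresponds to roughly £238 of output.
Full uptake of the measure catalogue cuts the synthetic population's GWP20
by about a third at the catchment median — farm management alone does not
approach net zero. The per-farm-type structure (dairy highest per-hectare
CH₄ and GWP20; zero CH₄ for the livestock-free arable types; GWP20 more
than double GWP100 for grazing systems) is summarised by
`analysis/02_farm_type_emissions.py` and `analysis/03_gwp_accounting.py`.

The numbered scripts under `analysis/` run the full narrative in order;
each writes its tables under `results/` (bulk per-farm tables go to
`scratch/pipeline/`).

## Layout

- `src/farmgwp/` — library: `synthetic` (generators), `emissions`,
  `measures` + `scenarios`, `gwp`, `aggregate`, `cobenefits`, `fixtures`,
  `pipeline`, `cli`
- `src/farmgwp/data/` — verbatim measure-catalogue transcriptions,
  implementer-supplied efficacy defaults (flagged synthetic), emission
  factors and farm-type profiles (editable YAML)
- `analysis/` — numbered narrative drivers
- `docs/methods.md` — model description, parameter choices, limitations
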