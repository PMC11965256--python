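"""Deterministic reference fixtures: one representative model farm per robust
farm type, built from the packaged profiles at midpoint livestock densities
and mean national fertiliser rates. Used for qualitative structural checks
(farm-type orderings, zero-methane rows) and documentation examples."""

from __future__ import annotations

from farmgwp.emissions import EmissionFactorSet
from farmgwp.synthetic import FARM_TYPES, ModelFarm, NutrientPractice, load_profiles

#: fixture rainfall per type, respecting the printed caps
_FIXTURE_RAINFALL = {
    "cereals": 650.0,
    "general_cropping": 620.0,
    "horticulture": 640.0,
    "lowland_grazing": 950.0,
    "lfa_grazing": 690.0,
    "dairy": 1050.0,
    "mixed": 800.0,
    "pigs": 650.0,
    "poultry": 650.0,
}


def default_model_farms() -> dict[str, ModelFarm]:
    """One deterministic farm per type at the profile's typical size."""
    profiles = load_profiles()["profiles"]
    gen = load_profiles()["generator"]
    util = float(gen["crop_utilisation"])
    farms = {}
    for ftype in FARM_TYPES:
        p = profiles[ftype]
        area = p.mean_farm_size_ha
        cohorts = tuple(
            (cat, max(1, round((lo + hi) / 2.0 * area)))
            for cat, (lo, hi) in p.livestock_density.items()
        )
        farms[ftype] = ModelFarm(
            farm_id=f"FX-{ftype}",
            catchment_id="FX",
            farm_type=ftype,
            area_ha=area,
            crops={c: s * area * util for c, s in p.crop_mix.items()},
            cohorts=cohorts,
            rainfall_mm=_FIXTURE_RAINFALL[ftype],
            drainage_class="drained_arable_grass",
            nvz=False,
            holding_count=30,
            production_value_gbp=area * p.production_value_gbp_per_ha,
        )
    return farms


def default_practice(
    farm: ModelFarm, factors: EmissionFactorSet | None = None
) -> NutrientPractice:
    """Deterministic practice: mean fertiliser rates, broadcast spreading,
    the profile's manure-system split, half of excreted N collected."""
    factors = factors or EmissionFactorSet.default()
    cfg = load_profiles()
    profile = cfg["profiles"][farm.farm_type]
    retained = float(cfg["generator"]["manure_retained_fraction"])
    excreted = sum(factors.excreted_n[cat] * head for cat, head in farm.cohorts)
    return NutrientPractice(
        fertilizer_n_rate={
            crop: float(factors.crops[crop]["fert_n"]) for crop in farm.crops
        },
        manure_n_applied=excreted * retained,
        spreading_method="broadcast",
        manure_system_split=dict(profile.manure_system_split),
    )
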