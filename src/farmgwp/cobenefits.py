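"""Water-quality and biodiversity co-benefits of GHG mitigation.

Baseline diffuse loads to water come from a transparent export-coefficient
model — a structural stand-in for a full catchment water-quality model, with
editable per-farm-type coefficients: load = area x coefficient x rainfall
modifier x drainage modifier, plus a linear nitrate term in applied nitrogen.
Co-benefit percentages reuse the same multiplicative efficacy stacking as the
GHG scenarios. Biodiversity impact is an additive index over measures, scaled
by uptake; methane-mitigation effects carry no biodiversity credit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from farmgwp.measures import MeasureSpec
from farmgwp.scenarios import ScenarioSpec, scenario_efficacy
from farmgwp.synthetic import ModelFarm, NutrientPractice, load_profiles, stable_substream

WATER_POLLUTANTS = ("nitrate", "phosphorus", "sediment")


@dataclass(frozen=True)
class WaterLoads:
    """Annual diffuse loads to water, kg yr-1, with per-ha counterparts."""

    nitrate: float
    phosphorus: float
    sediment: float
    area_ha: float

    def __post_init__(self) -> None:
        for name in ("nitrate", "phosphorus", "sediment"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} load must be >= 0")

    @property
    def per_ha(self) -> dict[str, float]:
        if self.area_ha == 0:
            return {p: 0.0 for p in WATER_POLLUTANTS}
        return {p: getattr(self, p) / self.area_ha for p in WATER_POLLUTANTS}

    def as_dict(self) -> dict[str, float]:
        return {p: getattr(self, p) for p in WATER_POLLUTANTS}


@dataclass(frozen=True)
class BiodiversityScore:
    """Additive index of biodiversity benefit from implemented measures."""

    score: float
    contributions: Mapping[str, float]

    def __post_init__(self) -> None:
        if abs(self.score - sum(self.contributions.values())) > 1e-9:
            raise ValueError("score must equal the sum of contributions")


def baseline_water_loads(
    farm: ModelFarm,
    practice: NutrientPractice,
    export_coeffs: Mapping | None = None,
) -> WaterLoads:
    """Unmitigated annual loads from the export-coefficient model."""
    cfg = export_coeffs or load_profiles()["water_export"]
    rain_mod = farm.rainfall_mm / float(cfg["rainfall_reference_mm"])
    if farm.drainage_class not in cfg["drainage_modifier"]:
        raise KeyError(f"no drainage modifier for {farm.drainage_class!r}")
    drain_mod = float(cfg["drainage_modifier"][farm.drainage_class])

    loads = {}
    for pollutant, key in (
        ("nitrate", "nitrate_n"),
        ("phosphorus", "phosphorus"),
        ("sediment", "sediment"),
    ):
        if farm.farm_type not in cfg[key]:
            raise KeyError(f"no {pollutant} coefficient for {farm.farm_type!r}")
        loads[pollutant] = (
            farm.area_ha * float(cfg[key][farm.farm_type]) * rain_mod * drain_mod
        )
    n_applied = practice.manure_n_applied + sum(
        practice.fertilizer_n_rate.get(crop, 0.0) * area
        for crop, area in farm.crops.items()
    )
    loads["nitrate"] += (
        n_applied * float(cfg["nitrate_per_kg_n"]) * rain_mod * drain_mod
    )
    return WaterLoads(area_ha=farm.area_ha, **loads)


def water_cobenefit(
    farm: ModelFarm,
    bau_loads: WaterLoads,
    catalogue: Iterable[MeasureSpec],
    scenario: ScenarioSpec,
    seed: int = 0,
) -> dict[str, float]:
    """Stacked % reduction per water pollutant under a scenario's uptakes."""
    catalogue = list(catalogue)
    out = {}
    for pollutant in WATER_POLLUTANTS:
        stack = scenario_efficacy(
            farm.farm_type, catalogue, scenario, pollutant, seed, farm.farm_id
        )
        out[pollutant] = stack.E_t
    return out


def mitigated_water_loads(
    farm: ModelFarm,
    bau_loads: WaterLoads,
    catalogue: Iterable[MeasureSpec],
    scenario: ScenarioSpec,
    seed: int = 0,
) -> WaterLoads:
    """Apply the scenario's stacked reductions to the baseline loads."""
    reductions = water_cobenefit(farm, bau_loads, catalogue, scenario, seed)
    return WaterLoads(
        area_ha=bau_loads.area_ha,
        **{
            p: getattr(bau_loads, p) * (1.0 - reductions[p] / 100.0)
            for p in WATER_POLLUTANTS
        },
    )


def biodiversity_score(
    catalogue: Iterable[MeasureSpec], uptakes: Mapping[str, float]
) -> BiodiversityScore:
    """Sum of per-measure biodiversity scores scaled by uptake fraction.

    ``uptakes`` maps measure_id to implementation %, and only the catalogue's
    biodiversity indices contribute — a measure's methane efficacy never
    feeds the score.
    """
    contributions = {}
    for measure in catalogue:
        u = uptakes.get(measure.measure_id, 0.0)
        if not 0.0 <= u <= 100.0:
            raise ValueError(f"uptake for {measure.measure_id} outside [0, 100]")
        if measure.biodiversity_score > 0 and u > 0:
            contributions[measure.measure_id] = (
                measure.biodiversity_score * u / 100.0
            )
    return BiodiversityScore(
        score=sum(contributions.values()), contributions=contributions
    )


def scenario_uptakes(
    farm: ModelFarm,
    catalogue: Iterable[MeasureSpec],
    scenario: ScenarioSpec,
    seed: int = 0,
) -> dict[str, float]:
    """Resolve the scenario's per-measure uptake for one farm (same seeded
    draws as the emission and water stacks)."""
    out = {}
    for measure in catalogue:
        if not measure.applies_to(farm.farm_type):
            continue
        rng = stable_substream(
            seed, "uptake", scenario.name, farm.farm_id, measure.measure_id
        )
        out[measure.measure_id] = scenario.resolve_uptake(measure, rng)
    return out
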