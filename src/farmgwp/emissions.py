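"""Annual CH4, N2O and CO2 emissions for one model farm.

Tier-1-style inventory arithmetic: enteric and manure-management methane per
head, direct and indirect nitrous oxide from nitrogen inputs (with an
ammonia-volatilisation lookup indexed by nitrogen source and spreading
method standing in for a full ammonia model), energy CO2 from an itemised
operation inventory (cultivation, spraying, spreading, milking, housing,
grain drying), and embedded CO2 from fertiliser and pesticide manufacture.
All factor values live in an editable, version-tagged configuration; every
component is linear in head counts and nitrogen inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from farmgwp.synthetic import ModelFarm, NutrientPractice

#: mass ratio converting N2O-N to N2O (44 g N2O per 28 g N)
N2O_N_TO_N2O = 44.0 / 28.0


class FactorConfigError(KeyError):
    """A livestock category, crop or lookup entry is missing from the factor set."""


@dataclass(frozen=True)
class EmissionFactorSet:
    """Versioned bundle of emission factors and operation coefficients."""

    version: str
    enteric_ch4: Mapping[str, float]
    manure_ch4: Mapping[str, Mapping[str, float]]
    excreted_n: Mapping[str, float]
    ef1_direct: float
    ef3_prp: float
    ef4_volat: float
    ef5_leach: float
    frac_leach: float
    volat_fraction: Mapping
    energy: Mapping
    embedded_fert: float
    embedded_pest: float
    pesticide_rate_kg_per_ha: float
    crops: Mapping[str, Mapping]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EmissionFactorSet":
        return cls(**yaml.safe_load(Path(path).read_text()))

    @classmethod
    def default(cls) -> "EmissionFactorSet":
        with resources.files("farmgwp.data").joinpath("emission_factors.yaml").open() as fh:
            return cls(**yaml.safe_load(fh))


@dataclass(frozen=True)
class FarmEmissions:
    """Annual farm totals (kg yr-1) with per-hectare counterparts."""

    ch4: float
    n2o: float
    co2_energy: float
    co2_embedded: float
    area_ha: float
    ch4_enteric: float = 0.0
    ch4_manure: float = 0.0
    n2o_direct: float = 0.0
    n2o_indirect: float = 0.0

    def __post_init__(self) -> None:
        for name in ("ch4", "n2o", "co2_energy", "co2_embedded"):
            if getattr(self, name) < -1e-12:
                raise ValueError(f"{name} must be >= 0")
        if self.area_ha <= 0:
            raise ValueError("area_ha must be positive")

    def _per_ha(self, total: float) -> float:
        return total / self.area_ha

    @property
    def ch4_per_ha(self) -> float:
        return self._per_ha(self.ch4)

    @property
    def n2o_per_ha(self) -> float:
        return self._per_ha(self.n2o)

    @property
    def co2_energy_per_ha(self) -> float:
        return self._per_ha(self.co2_energy)

    @property
    def co2_embedded_per_ha(self) -> float:
        return self._per_ha(self.co2_embedded)

    def scaled(self, pollutant_multipliers: Mapping[str, float]) -> "FarmEmissions":
        """Return a copy with named pollutants multiplied (scenario residuals)."""
        m = dict(pollutant_multipliers)
        f_ch4 = m.get("ch4", 1.0)
        f_n2o = m.get("n2o", 1.0)
        return FarmEmissions(
            ch4=self.ch4 * f_ch4,
            n2o=self.n2o * f_n2o,
            co2_energy=self.co2_energy * m.get("co2_energy", 1.0),
            co2_embedded=self.co2_embedded * m.get("co2_embedded", 1.0),
            area_ha=self.area_ha,
            ch4_enteric=self.ch4_enteric * f_ch4,
            ch4_manure=self.ch4_manure * f_ch4,
            n2o_direct=self.n2o_direct * f_n2o,
            n2o_indirect=self.n2o_indirect * f_n2o,
        )


def enteric_methane(
    cohorts: tuple[tuple[str, int], ...], factors: EmissionFactorSet
) -> float:
    """Enteric fermentation CH4, kg yr-1: sum of head x per-head factor."""
    total = 0.0
    for cat, head in cohorts:
        if cat not in factors.enteric_ch4:
            raise FactorConfigError(f"no enteric CH4 factor for category {cat!r}")
        total += head * factors.enteric_ch4[cat]
    return total


def manure_methane(
    cohorts: tuple[tuple[str, int], ...],
    practice: NutrientPractice,
    factors: EmissionFactorSet,
) -> float:
    """Manure-management CH4, kg yr-1, convex over the storage-system split."""
    total = 0.0
    for cat, head in cohorts:
        if cat not in factors.manure_ch4:
            raise FactorConfigError(f"no manure CH4 factors for category {cat!r}")
        by_system = factors.manure_ch4[cat]
        for system, share in practice.manure_system_split.items():
            if system not in by_system:
                raise FactorConfigError(
                    f"no manure CH4 factor for ({cat!r}, {system!r})"
                )
            total += head * share * by_system[system]
    return total


def direct_n2o(n_inputs: Mapping[str, float], factors: EmissionFactorSet) -> float:
    """Direct soil N2O, kg N2O yr-1.

    ``n_inputs`` maps sources to kg N: ``fertilizer`` and ``manure`` receive
    the applied-N factor, ``pasture`` the excreta-at-grazing factor.
    """
    for src, n in n_inputs.items():
        if n < 0:
            raise ValueError(f"negative N input for source {src!r}")
    applied = n_inputs.get("fertilizer", 0.0) + n_inputs.get("manure", 0.0)
    pasture = n_inputs.get("pasture", 0.0)
    return (applied * factors.ef1_direct + pasture * factors.ef3_prp) * N2O_N_TO_N2O


def indirect_n2o(
    n_inputs: Mapping[str, float],
    practice: NutrientPractice,
    factors: EmissionFactorSet,
) -> float:
    """Indirect N2O from volatilised and leached N, kg N2O yr-1.

    Volatilised N uses the practice-specific fraction (band spreading carries
    a lower fraction than broadcast in the default table); excreta routed to
    housing/storage volatilises at the housing fraction. Leaching applies the
    configured fraction to all N reaching soils.
    """
    for src, n in n_inputs.items():
        if n < 0:
            raise ValueError(f"negative N input for source {src!r}")
    method = practice.spreading_method
    volatilized = 0.0
    for src in ("fertilizer", "manure"):
        n = n_inputs.get(src, 0.0)
        if n == 0.0:
            continue
        table = factors.volat_fraction.get(src)
        if table is None or method not in table:
            raise FactorConfigError(
                f"no volatilisation fraction for ({src!r}, {method!r})"
            )
        volatilized += n * table[method]
    volatilized += n_inputs.get("housing", 0.0) * factors.volat_fraction.get(
        "housing", 0.0
    )
    soil_n = (
        n_inputs.get("fertilizer", 0.0)
        + n_inputs.get("manure", 0.0)
        + n_inputs.get("pasture", 0.0)
    )
    leached = soil_n * factors.frac_leach
    return (
        volatilized * factors.ef4_volat + leached * factors.ef5_leach
    ) * N2O_N_TO_N2O


def energy_co2(
    farm: ModelFarm, practice: NutrientPractice, factors: EmissionFactorSet
) -> float:
    """On-farm energy CO2, kg yr-1, from the itemised operation inventory."""
    en = factors.energy
    total = 0.0
    spread_area = 0.0
    for crop, area in farm.crops.items():
        if crop not in factors.crops:
            raise FactorConfigError(f"no crop parameters for {crop!r}")
        c = factors.crops[crop]
        total += area * c["cult_passes"] * en["cultivation_pass_per_ha"]
        total += area * c["spray_passes"] * en["spray_pass_per_ha"]
        total += area * c["fert_apps"] * en["spread_pass_per_ha"]
        if c["dried"]:
            total += area * c["yield_t_ha"] * en["drying_per_tonne"]
        spread_area += area
    if practice.manure_n_applied > 0:
        total += spread_area * en["spread_pass_per_ha"]
    for cat, head in farm.cohorts:
        total += head * en["housing_per_head"].get(cat, 0.0)
        if cat == "dairy_cow":
            total += head * en["milking_per_head"]
    return total


def embedded_co2(
    fertilizer_n: float, pesticide: float, factors: EmissionFactorSet
) -> float:
    """Embedded (manufacture) CO2 eq, kg yr-1, for fertiliser N and pesticide."""
    if fertilizer_n < 0 or pesticide < 0:
        raise ValueError("embedded inputs must be >= 0")
    return fertilizer_n * factors.embedded_fert + pesticide * factors.embedded_pest


def nitrogen_inputs(
    farm: ModelFarm, practice: NutrientPractice, factors: EmissionFactorSet
) -> dict[str, float]:
    """kg N yr-1 by source: fertilizer, manure (land-applied), pasture
    (grazing deposition), housing (excreta routed to housed systems)."""
    fert = sum(
        practice.fertilizer_n_rate.get(crop, 0.0) * area
        for crop, area in farm.crops.items()
    )
    excreted = sum(factors.excreted_n[cat] * head for cat, head in farm.cohorts)
    pasture_share = practice.manure_system_split.get("pasture", 0.0)
    return {
        "fertilizer": fert,
        "manure": practice.manure_n_applied,
        "pasture": excreted * pasture_share,
        "housing": excreted * (1.0 - pasture_share),
    }


def compute_farm_emissions(
    farm: ModelFarm, practice: NutrientPractice, factors: EmissionFactorSet
) -> FarmEmissions:
    """Assemble the full annual emission account for one farm."""
    ch4_ent = enteric_methane(farm.cohorts, factors)
    ch4_man = manure_methane(farm.cohorts, practice, factors)
    n_in = nitrogen_inputs(farm, practice, factors)
    n2o_dir = direct_n2o(n_in, factors)
    n2o_ind = indirect_n2o(n_in, practice, factors)
    energy = energy_co2(farm, practice, factors)
    pesticide = sum(
        area * factors.crops[crop]["spray_passes"] * factors.pesticide_rate_kg_per_ha
        for crop, area in farm.crops.items()
        if crop in factors.crops
    )
    embedded = embedded_co2(n_in["fertilizer"], pesticide, factors)
    return FarmEmissions(
        ch4=ch4_ent + ch4_man,
        n2o=n2o_dir + n2o_ind,
        co2_energy=energy,
        co2_embedded=embedded,
        area_ha=farm.area_ha,
        ch4_enteric=ch4_ent,
        ch4_manure=ch4_man,
        n2o_direct=n2o_dir,
        n2o_indirect=n2o_ind,
    )
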