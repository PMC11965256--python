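"""Global-warming-potential accounting and carbon valuation.

Gas masses convert to CO2 equivalents with fixed coefficients: 273 for N2O at
both horizons, 81.2 (20-year) and 27.9 (100-year) for CH4, 1 for CO2. The
valuation operations reproduce the carbon-value arithmetic used for policy
reporting: emission intensity (kg CO2 eq per pound of farm production),
carbon value per pound of production, and production value per tonne emitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from farmgwp.emissions import FarmEmissions


@dataclass(frozen=True)
class GWPCoefficients:
    """CO2-equivalence coefficients (AR6-style, with climate-carbon feedbacks)."""

    n2o_factor: float = 273.0
    ch4_gwp20: float = 81.2
    ch4_gwp100: float = 27.9
    co2_factor: float = 1.0

    def __post_init__(self) -> None:
        if not self.ch4_gwp20 > self.ch4_gwp100 > 0:
            raise ValueError("require ch4_gwp20 > ch4_gwp100 > 0")
        if self.n2o_factor <= 0:
            raise ValueError("n2o_factor must be positive")

    def ch4_factor(self, horizon: int) -> float:
        if horizon == 20:
            return self.ch4_gwp20
        if horizon == 100:
            return self.ch4_gwp100
        raise ValueError(f"horizon must be 20 or 100, got {horizon}")


DEFAULT_COEFFICIENTS = GWPCoefficients()


@dataclass(frozen=True)
class CarbonValueSeries:
    """Government carbon values, £ per tonne CO2 eq."""

    low: float = 120.0
    central: float = 241.0
    high: float = 361.0
    year: int = 2020

    def __post_init__(self) -> None:
        if not self.low < self.central < self.high:
            raise ValueError("require low < central < high")


@dataclass(frozen=True)
class GWPResult:
    """GWP20/GWP100 for one farm, with and without embedded CO2, per-ha
    counterparts and per-gas shares."""

    gwp20: float
    gwp100: float
    gwp20_with_embedded: float
    gwp100_with_embedded: float
    area_ha: float
    shares: Mapping[tuple[int, bool], Mapping[str, float]]

    @property
    def gwp20_per_ha(self) -> float:
        return self.gwp20 / self.area_ha

    @property
    def gwp100_per_ha(self) -> float:
        return self.gwp100 / self.area_ha


@dataclass(frozen=True)
class ValuationResult:
    """Carbon-value intensity of farm production."""

    gwp_intensity: float           # kg CO2 eq per £ production
    carbon_value_intensity: float  # £ carbon value per £ production
    production_per_tonne: float    # £ production per t CO2 eq


def to_gwp(
    em: FarmEmissions,
    horizon: int,
    include_embedded: bool = False,
    coefficients: GWPCoefficients = DEFAULT_COEFFICIENTS,
) -> float:
    """Total warming potential, kg CO2 eq yr-1."""
    co2 = em.co2_energy + (em.co2_embedded if include_embedded else 0.0)
    return (
        co2 * coefficients.co2_factor
        + em.ch4 * coefficients.ch4_factor(horizon)
        + em.n2o * coefficients.n2o_factor
    )


def contribution_shares(
    em: FarmEmissions,
    horizon: int,
    include_embedded: bool = False,
    coefficients: GWPCoefficients = DEFAULT_COEFFICIENTS,
) -> dict[str, float]:
    """Per-gas percentage contributions to the horizon's GWP; NaN when the
    total is zero."""
    co2 = (
        em.co2_energy + (em.co2_embedded if include_embedded else 0.0)
    ) * coefficients.co2_factor
    ch4 = em.ch4 * coefficients.ch4_factor(horizon)
    n2o = em.n2o * coefficients.n2o_factor
    total = co2 + ch4 + n2o
    if total <= 0:
        return {"co2": math.nan, "ch4": math.nan, "n2o": math.nan}
    return {
        "co2": 100.0 * co2 / total,
        "ch4": 100.0 * ch4 / total,
        "n2o": 100.0 * n2o / total,
    }


def compute_gwp(
    em: FarmEmissions, coefficients: GWPCoefficients = DEFAULT_COEFFICIENTS
) -> GWPResult:
    """Both horizons, both embedded treatments, with per-gas shares."""
    shares = {
        (h, emb): contribution_shares(em, h, emb, coefficients)
        for h in (20, 100)
        for emb in (True, False)
    }
    return GWPResult(
        gwp20=to_gwp(em, 20, False, coefficients),
        gwp100=to_gwp(em, 100, False, coefficients),
        gwp20_with_embedded=to_gwp(em, 20, True, coefficients),
        gwp100_with_embedded=to_gwp(em, 100, True, coefficients),
        area_ha=em.area_ha,
        shares=shares,
    )


def gwp_intensity(gwp_kg: float, production_value_gbp: float) -> float:
    """Emission intensity, kg CO2 eq per £ of farm production."""
    if production_value_gbp <= 0:
        raise ValueError("production value must be positive")
    return gwp_kg / production_value_gbp


def carbon_value_per_pound(
    intensity: float, carbon_value_gbp_per_tonne: float
) -> float:
    """£ of carbon value per £ of production, reported to 2 decimals."""
    return round(intensity * carbon_value_gbp_per_tonne / 1000.0, 2)


def pounds_per_tonne(intensity: float) -> int:
    """£ of production per tonne CO2 eq, reported to the nearest pound."""
    if intensity <= 0:
        raise ValueError("intensity must be positive")
    return round(1000.0 / intensity)


def valuation(
    gwp_kg: float,
    production_value_gbp: float,
    carbon_value_gbp_per_tonne: float,
) -> ValuationResult:
    intensity = gwp_intensity(gwp_kg, production_value_gbp)
    return ValuationResult(
        gwp_intensity=intensity,
        carbon_value_intensity=carbon_value_per_pound(
            intensity, carbon_value_gbp_per_tonne
        ),
        production_per_tonne=pounds_per_tonne(intensity) if intensity > 0 else math.nan,
    )
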