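"""Mitigation scenarios: multiplicative efficacy stacking and uptake rules.

The combined effect of n measures with individual reductions E_i (%) is

    E_t = 100 * (1 - prod_i (1 - E_i / 100))

i.e. residual fractions multiply, which avoids the over-estimation an
additive combination would give. Uptake is the fraction of the holdings a
model farm represents that implement a measure, so a measure's expected
efficacy scales linearly with uptake before stacking. Two named scenarios:
business-as-usual resolves each measure's baseline uptake (ranges by seeded
uniform draw per farm), maximum technically feasible sets uptake to the
measure's maximum (default 100%).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from farmgwp.emissions import FarmEmissions
from farmgwp.measures import MeasureSpec, POLLUTANTS
from farmgwp.synthetic import ModelFarm, stable_substream

log = logging.getLogger(__name__)

GHG_POLLUTANTS = ("ch4", "n2o", "co2_energy")


@dataclass(frozen=True)
class ScenarioSpec:
    """A named uptake rule mapping (measure, farm rng) -> uptake %."""

    name: str
    uptake_rule: Callable[[MeasureSpec, np.random.Generator], float]

    def resolve_uptake(
        self, measure: MeasureSpec, rng: np.random.Generator
    ) -> float:
        u = float(self.uptake_rule(measure, rng))
        if not 0.0 <= u <= 100.0:
            raise ValueError(f"scenario {self.name!r}: uptake {u} outside [0, 100]")
        return u


def _bau_uptake(measure: MeasureSpec, rng: np.random.Generator) -> float:
    lo, hi = measure.baseline_uptake
    return lo if lo == hi else float(rng.uniform(lo, hi))


BAU = ScenarioSpec("bau", _bau_uptake)
MAX_FEASIBLE = ScenarioSpec("max_feasible", lambda m, rng: m.max_uptake)


@dataclass(frozen=True)
class EfficacyStack:
    """A resolved stack: individual reduction-positive percentages and their
    multiplicative combination."""

    E_i: tuple[float, ...]
    E_t: float

    @property
    def n(self) -> int:
        return len(self.E_i)


def stack_efficacies(E_i: Sequence[float]) -> float:
    """Combine reduction percentages multiplicatively.

    Arguments are reduction-positive (negative values denote increases) and
    must not exceed 100. Returns the overall reduction %, order-invariant.
    """
    residual = 1.0
    for e in E_i:
        if e > 100.0:
            raise ValueError(f"efficacy {e} > 100% implies a negative residual")
        residual *= 1.0 - e / 100.0
    return 100.0 * (1.0 - residual)


def effective_uptake_efficacy(
    measure: MeasureSpec, pollutant: str, uptake: float
) -> float:
    """Expected reduction % over represented holdings: sign-normalised
    efficacy scaled linearly by uptake. Unknown pollutants contribute 0."""
    if not 0.0 <= uptake <= 100.0:
        raise ValueError("uptake must lie in [0, 100]")
    eff = measure.efficacies.get(pollutant)
    if eff is None:
        log.debug("measure %s has no efficacy for %s", measure.measure_id, pollutant)
        return 0.0
    return -eff * uptake / 100.0  # printed sign: negative = reduction


def scenario_efficacy(
    farm_type: str,
    catalogue: Iterable[MeasureSpec],
    scenario: ScenarioSpec,
    pollutant: str,
    seed: int = 0,
    farm_id: str = "",
    uptakes: Mapping[str, float] | None = None,
) -> EfficacyStack:
    """Stack the scenario's effective efficacies for one pollutant over the
    measures applicable to a farm type. The per-farm uptake draw is seeded by
    (seed, scenario, farm_id, measure) so it is reproducible and shared across
    pollutants of the same farm; precomputed ``uptakes`` (measure_id -> %)
    short-circuit the draw."""
    E: list[float] = []
    for measure in catalogue:
        if not measure.applies_to(farm_type):
            continue
        if uptakes is not None and measure.measure_id in uptakes:
            u = uptakes[measure.measure_id]
        else:
            rng = stable_substream(
                seed, "uptake", scenario.name, farm_id, measure.measure_id
            )
            u = scenario.resolve_uptake(measure, rng)
        e = effective_uptake_efficacy(measure, pollutant, u)
        if e != 0.0:
            E.append(e)
    return EfficacyStack(E_i=tuple(E), E_t=stack_efficacies(E))


def apply_scenario(
    farm: ModelFarm,
    emissions: FarmEmissions,
    catalogue: Iterable[MeasureSpec],
    scenario: ScenarioSpec,
    seed: int = 0,
) -> FarmEmissions:
    """Scale unmitigated engine output by the scenario's stacked reductions.

    Each gas is multiplied by (1 - E_t/100); measures with positive printed
    efficacies (increases, e.g. extra drying energy under cover crops) can
    raise a pollutant.
    """
    catalogue = [m for m in catalogue if m.applies_to(farm.farm_type)]
    uptakes = {
        m.measure_id: scenario.resolve_uptake(
            m, stable_substream(seed, "uptake", scenario.name, farm.farm_id, m.measure_id)
        )
        for m in catalogue
    }
    multipliers = {}
    for pollutant in GHG_POLLUTANTS:
        stack = scenario_efficacy(
            farm.farm_type, catalogue, scenario, pollutant, seed, farm.farm_id,
            uptakes=uptakes,
        )
        multipliers[pollutant] = 1.0 - stack.E_t / 100.0
    return emissions.scaled(multipliers)


def scenario_reduction(
    bau: Mapping[str, float] | FarmEmissions,
    mitigated: Mapping[str, float] | FarmEmissions,
) -> dict[str, float]:
    """Percentage reduction by quantity, 100 x (bau - mitigated) / bau.

    Zero baselines yield NaN (undefined), never 0.
    """
    def as_map(x):
        if isinstance(x, FarmEmissions):
            return {
                "ch4": x.ch4, "n2o": x.n2o,
                "co2_energy": x.co2_energy, "co2_embedded": x.co2_embedded,
            }
        return dict(x)

    b, m = as_map(bau), as_map(mitigated)
    out = {}
    for key, base in b.items():
        if key not in m:
            continue
        out[key] = 100.0 * (base - m[key]) / base if base > 0 else math.nan
    return out
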