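"""Shared fixtures: default factor set, profiles, deterministic reference
farms, and a small synthetic population."""

from __future__ import annotations

import pytest

from farmgwp.emissions import EmissionFactorSet
from farmgwp.fixtures import default_model_farms, default_practice
from farmgwp.measures import load_measure_catalogue
from farmgwp.synthetic import generate_catchments, generate_farm_population, load_profiles


@pytest.fixture(scope="session")
def factors() -> EmissionFactorSet:
    return EmissionFactorSet.default()


@pytest.fixture(scope="session")
def profile_config() -> dict:
    return load_profiles()


@pytest.fixture(scope="session")
def reference_farms() -> dict:
    return default_model_farms()


@pytest.fixture(scope="session")
def reference_practices(reference_farms, factors) -> dict:
    return {
        ftype: default_practice(farm, factors)
        for ftype, farm in reference_farms.items()
    }


@pytest.fixture(scope="session")
def catalogue():
    return load_measure_catalogue()


@pytest.fixture(scope="session")
def small_population(profile_config):
    """Three catchments of model farms, fixed seed."""
    catchments = generate_catchments(3, seed=7, config=profile_config["catchments"])
    farms = []
    for c in catchments:
        farms.extend(
            generate_farm_population(
                c, profile_config["profiles"], seed=7,
                generator_config=profile_config["generator"],
            )
        )
    return catchments, farms
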