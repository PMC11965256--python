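"""Emission-engine arithmetic: hand-computed component oracles, linearity,
conservation, and zero-input behaviour."""

from __future__ import annotations

import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from farmgwp.emissions import (
    N2O_N_TO_N2O,
    FactorConfigError,
    FarmEmissions,
    compute_farm_emissions,
    direct_n2o,
    embedded_co2,
    energy_co2,
    enteric_methane,
    indirect_n2o,
    manure_methane,
    nitrogen_inputs,
)
from farmgwp.synthetic import NutrientPractice


def practice(method="broadcast", manure=0.0, split=None, rates=None):
    return NutrientPractice(
        fertilizer_n_rate=rates or {},
        manure_n_applied=manure,
        spreading_method=method,
        manure_system_split=split or {},
    )


class TestEntericMethane:
    def test_no_livestock_is_zero(self, factors):
        assert enteric_methane((), factors) == 0.0

    def test_single_head_identity(self, factors):
        assert enteric_methane((("sheep", 1),), factors) == factors.enteric_ch4["sheep"]

    def test_dairy_herd_hand_sum(self, factors):
        # 100 cows x 126 + 40 followers x 52
        got = enteric_methane((("dairy_cow", 100), ("other_cattle", 40)), factors)
        assert got == pytest.approx(14_680.0)

    def test_unknown_category_raises(self, factors):
        with pytest.raises(FactorConfigError, match="llama"):
            enteric_methane((("llama", 3),), factors)


class TestManureMethane:
    def test_no_livestock_is_zero(self, factors):
        assert manure_methane((), practice(split={"slurry": 1.0}), factors) == 0.0

    def test_single_system_identity(self, factors):
        got = manure_methane(
            (("dairy_cow", 1),), practice(split={"slurry": 1.0}), factors
        )
        assert got == factors.manure_ch4["dairy_cow"]["slurry"]

    def test_split_is_convex_combination(self, factors):
        cohorts = (("dairy_cow", 50),)
        full_slurry = manure_methane(cohorts, practice(split={"slurry": 1.0}), factors)
        full_solid = manure_methane(cohorts, practice(split={"solid": 1.0}), factors)
        mixed = manure_methane(
            cohorts, practice(split={"slurry": 0.6, "solid": 0.4}), factors
        )
        assert mixed == pytest.approx(0.6 * full_slurry + 0.4 * full_solid)


class TestNitrousOxide:
    def test_zero_n_zero_output(self, factors):
        assert direct_n2o({}, factors) == 0.0
        assert indirect_n2o({}, practice(), factors) == 0.0

    def test_direct_mass_conversion(self, factors):
        # 100 kg N x EF1 0.01 = 1 kg N2O-N = 44/28 kg N2O
        got = direct_n2o({"fertilizer": 100.0}, factors)
        assert got == pytest.approx(1.0 * N2O_N_TO_N2O)
        assert got == pytest.approx(1.5714285714, rel=1e-9)

    def test_direct_additivity(self, factors):
        a = direct_n2o({"fertilizer": 37.5}, factors)
        b = direct_n2o({"fertilizer": 62.5}, factors)
        assert a + b == pytest.approx(direct_n2o({"fertilizer": 100.0}, factors))

    def test_negative_n_rejected(self, factors):
        with pytest.raises(ValueError):
            direct_n2o({"fertilizer": -1.0}, factors)

    def test_indirect_hand_sum(self, factors):
        # volat fraction 0.10 via a custom table, ef4 0.01, leach 0.24 x 0.011
        custom = dataclasses.replace(
            factors,
            volat_fraction={"fertilizer": {"broadcast": 0.10}, "housing": 0.0},
        )
        got = indirect_n2o({"fertilizer": 100.0}, practice(), custom)
        expected = (100 * 0.10 * 0.01 + 100 * 0.24 * 0.011) * N2O_N_TO_N2O
        assert got == pytest.approx(expected)
        assert got == pytest.approx(0.572, abs=1e-12)

    def test_band_spreading_reduces_volatilisation(self, factors):
        n = {"fertilizer": 200.0, "manure": 150.0}
        broadcast = indirect_n2o(n, practice("broadcast"), factors)
        band = indirect_n2o(n, practice("band"), factors)
        assert band < broadcast

    def test_missing_volatilisation_entry_raises(self, factors):
        with pytest.raises(FactorConfigError):
            indirect_n2o({"fertilizer": 10.0}, practice("helicopter"), factors)


class TestEnergyAndEmbedded:
    def test_bare_farm_is_zero(self, reference_farms, factors):
        farm = dataclasses.replace(
            reference_farms["cereals"], crops={}, farm_id="bare"
        )
        assert energy_co2(farm, practice(), factors) == 0.0

    def test_doubling_scales_energy(self, reference_farms, reference_practices, factors):
        farm = reference_farms["dairy"]
        p = reference_practices["dairy"]
        double = dataclasses.replace(
            farm,
            farm_id="double",
            area_ha=farm.area_ha * 2,
            crops={c: a * 2 for c, a in farm.crops.items()},
            cohorts=tuple((c, h * 2) for c, h in farm.cohorts),
        )
        assert energy_co2(double, p, factors) == pytest.approx(
            2 * energy_co2(farm, p, factors)
        )

    def test_dairy_energy_itemised_oracle(self, reference_farms, reference_practices, factors):
        farm = reference_farms["dairy"]
        p = reference_practices["dairy"]
        en = factors.energy
        expected = 0.0
        for crop, area in farm.crops.items():
            c = factors.crops[crop]
            expected += area * (
                c["cult_passes"] * en["cultivation_pass_per_ha"]
                + c["spray_passes"] * en["spray_pass_per_ha"]
                + c["fert_apps"] * en["spread_pass_per_ha"]
            )
            if c["dried"]:
                expected += area * c["yield_t_ha"] * en["drying_per_tonne"]
        expected += sum(farm.crops.values()) * en["spread_pass_per_ha"]  # manure pass
        for cat, head in farm.cohorts:
            expected += head * en["housing_per_head"][cat]
            if cat == "dairy_cow":
                expected += head * en["milking_per_head"]
        assert energy_co2(farm, p, factors) == pytest.approx(expected)

    def test_embedded_identities(self, factors):
        assert embedded_co2(0.0, 0.0, factors) == 0.0
        assert embedded_co2(1.0, 0.0, factors) == factors.embedded_fert
        mixed = embedded_co2(120.0, 3.5, factors)
        assert mixed == pytest.approx(
            120.0 * factors.embedded_fert + 3.5 * factors.embedded_pest
        )
        with pytest.raises(ValueError):
            embedded_co2(-1.0, 0.0, factors)


class TestAssembledEmissions:
    def test_livestock_free_farm_has_zero_ch4(
        self, reference_farms, reference_practices, factors
    ):
        for ftype in ("cereals", "general_cropping", "horticulture"):
            em = compute_farm_emissions(
                reference_farms[ftype], reference_practices[ftype], factors
            )
            assert em.ch4 == 0.0
            assert em.n2o > 0 and em.co2_energy > 0 and em.co2_embedded > 0

    def test_component_conservation(
        self, reference_farms, reference_practices, factors
    ):
        for ftype, farm in reference_farms.items():
            em = compute_farm_emissions(farm, reference_practices[ftype], factors)
            assert em.ch4 == pytest.approx(em.ch4_enteric + em.ch4_manure)
            assert em.n2o == pytest.approx(em.n2o_direct + em.n2o_indirect)
            assert em.ch4_per_ha * em.area_ha == pytest.approx(em.ch4, rel=1e-9)

    def test_dairy_totals_equal_component_oracle(
        self, reference_farms, reference_practices, factors
    ):
        farm, p = reference_farms["dairy"], reference_practices["dairy"]
        em = compute_farm_emissions(farm, p, factors)
        n_in = nitrogen_inputs(farm, p, factors)
        assert em.ch4 == pytest.approx(
            enteric_methane(farm.cohorts, factors)
            + manure_methane(farm.cohorts, p, factors)
        )
        assert em.n2o == pytest.approx(
            direct_n2o(n_in, factors) + indirect_n2o(n_in, p, factors)
        )
        assert em.co2_energy == pytest.approx(energy_co2(farm, p, factors))

    @settings(derandomize=True, max_examples=50)
    @given(k=st.integers(min_value=1, max_value=20))
    def test_linearity_in_head_counts(self, k, factors):
        base = (("dairy_cow", 7), ("sheep", 13))
        scaled = tuple((c, h * k) for c, h in base)
        assert enteric_methane(scaled, factors) == pytest.approx(
            k * enteric_methane(base, factors)
        )

    @settings(derandomize=True, max_examples=50)
    @given(n=st.floats(min_value=0, max_value=1e4, allow_nan=False))
    def test_linearity_in_nitrogen(self, n, factors):
        one = direct_n2o({"fertilizer": 1.0}, factors)
        assert direct_n2o({"fertilizer": n}, factors) == pytest.approx(n * one)


def test_negative_emissions_rejected():
    with pytest.raises(ValueError):
        FarmEmissions(ch4=-1.0, n2o=0, co2_energy=0, co2_embedded=0, area_ha=10)
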