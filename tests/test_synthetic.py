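"""Generator contracts: seeded determinism, environmental constraints,
area-share targeting, nutrient-practice arithmetic and table round-trips."""

from __future__ import annotations

import numpy as np
import pytest

from farmgwp.synthetic import (
    CatchmentSpec,
    generate_catchments,
    generate_farm_population,
    generate_nutrient_practice,
    read_fixture_tables,
    write_fixture_tables,
)


def make_catchment(rainfall: float = 650.0, uaa: float = 80_000.0) -> CatchmentSpec:
    return CatchmentSpec(
        catchment_id="T001",
        total_area_km2=1500.0,
        utilized_agricultural_area_ha=uaa,
        mean_rainfall_mm=rainfall,
        drainage_mix={
            "free_draining": 0.4, "drained_arable": 0.3, "drained_arable_grass": 0.3
        },
        nvz_fraction=0.5,
    )


class TestCatchments:
    def test_areas_within_bounds_and_mean(self):
        specs = generate_catchments(500, seed=1)
        areas = np.array([c.total_area_km2 for c in specs])
        assert areas.min() >= 105 and areas.max() <= 4000
        assert 1100 < areas.mean() < 1900

    def test_drainage_normalised_and_deterministic(self):
        (one,) = generate_catchments(1, seed=3)
        assert sum(one.drainage_mix.values()) == pytest.approx(1.0, abs=1e-9)
        again = generate_catchments(1, seed=3)[0]
        assert one == again

    def test_rainfall_declines_eastward_on_average(self):
        specs = generate_catchments(400, seed=2)
        rain = np.array([c.mean_rainfall_mm for c in specs])
        assert rain.min() >= 550 and rain.max() <= 1800
        # gradient proxy: spread well beyond the noise scale
        assert rain.std() > 100

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            generate_catchments(0, seed=1)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            CatchmentSpec(
                catchment_id="X", total_area_km2=100.0,
                utilized_agricultural_area_ha=20_000.0,  # exceeds area x 100
                mean_rainfall_mm=800.0,
                drainage_mix={
                    "free_draining": 0.5, "drained_arable": 0.5,
                    "drained_arable_grass": 0.0,
                },
                nvz_fraction=0.2,
            )


class TestFarmPopulation:
    def test_high_rainfall_excludes_capped_types(self, profile_config):
        farms = generate_farm_population(
            make_catchment(rainfall=1100.0), profile_config["profiles"], seed=1,
            generator_config=profile_config["generator"],
        )
        types = {f.farm_type for f in farms}
        assert "cereals" not in types
        assert "lfa_grazing" not in types
        assert "dairy" in types

    def test_single_profile_population(self, profile_config):
        dairy_only = {"dairy": profile_config["profiles"]["dairy"]}
        farms = generate_farm_population(
            make_catchment(), dairy_only, seed=2,
            generator_config=profile_config["generator"],
        )
        assert farms and all(f.farm_type == "dairy" for f in farms)
        assert all(f.cohorts for f in farms)

    def test_seeded_determinism(self, profile_config):
        kw = dict(
            profiles=profile_config["profiles"], seed=11,
            generator_config=profile_config["generator"],
        )
        assert generate_farm_population(make_catchment(), **kw) == \
            generate_farm_population(make_catchment(), **kw)

    def test_area_shares_match_targets(self, profile_config):
        # all nine types feasible at 650 mm: realised area shares must track
        # the configured national targets
        farms = generate_farm_population(
            make_catchment(rainfall=650.0), profile_config["profiles"], seed=5,
            generator_config=profile_config["generator"],
        )
        total = sum(f.area_ha for f in farms)
        by_type = {}
        for f in farms:
            by_type[f.farm_type] = by_type.get(f.farm_type, 0.0) + f.area_ha
        for ftype, profile in profile_config["profiles"].items():
            realised = by_type.get(ftype, 0.0) / total
            assert realised == pytest.approx(profile.area_share, abs=0.03)

    def test_constraints_hold_over_large_population(self, profile_config):
        # rainfall caps and livestock-free structure over ~10^4 farms
        catchments = generate_catchments(250, seed=9)
        profiles = profile_config["profiles"]
        n_seen = 0
        for c in catchments:
            for f in generate_farm_population(
                c, profiles, seed=9, generator_config=profile_config["generator"]
            ):
                n_seen += 1
                cap = profiles[f.farm_type].rainfall_cap_mm
                if cap is not None:
                    assert f.rainfall_mm <= cap + 1e-9
                if not profiles[f.farm_type].has_livestock:
                    assert f.cohorts == ()
                assert sum(f.crops.values()) <= f.area_ha * (1 + 1e-9)
                assert f.holding_count >= 1
        assert n_seen >= 10_000

    def test_holding_total_rescaling(self, profile_config):
        gen_cfg = dict(profile_config["generator"])
        gen_cfg["holding_total_per_catchment"] = 1200
        farms = generate_farm_population(
            make_catchment(), profile_config["profiles"], seed=4,
            generator_config=gen_cfg,
        )
        assert sum(f.holding_count for f in farms) == 1200

    def test_empty_profiles_rejected(self):
        with pytest.raises(ValueError):
            generate_farm_population(make_catchment(), [], seed=1)


class TestNutrientPractice:
    def test_no_crops_no_fertilizer(self, reference_farms, factors):
        import dataclasses

        farm = reference_farms["lowland_grazing"]
        bare = dataclasses.replace(farm, crops={}, farm_id="bare")
        p = generate_nutrient_practice(bare, seed=1, factors=factors)
        assert p.fertilizer_n_rate == {}

    def test_no_livestock_no_manure(self, reference_farms, factors):
        p = generate_nutrient_practice(
            reference_farms["cereals"], seed=1, factors=factors
        )
        assert p.manure_n_applied == 0.0

    def test_dairy_manure_equals_excretion_times_retention(
        self, reference_farms, factors, profile_config
    ):
        farm = reference_farms["dairy"]
        p = generate_nutrient_practice(farm, seed=1, factors=factors)
        # hand arithmetic: mid-density cohorts on 120 ha at the configured
        # per-head excretion, half collected
        expected = (204 * 115.0 + 132 * 50.0) * 0.5
        assert p.manure_n_applied == pytest.approx(expected)


class TestFixtureTables:
    def test_round_trip(self, small_population, factors, profile_config, tmp_path):
        catchments, farms = small_population
        practices = {
            f.farm_id: generate_nutrient_practice(
                f, seed=7, factors=factors,
                profiles=profile_config["profiles"],
                generator_config=profile_config["generator"],
            )
            for f in farms
        }
        write_fixture_tables(farms, practices, tmp_path, catchments=catchments)
        farms2, practices2 = read_fixture_tables(tmp_path)
        assert farms2 == farms
        assert practices2 == practices

    def test_empty_population_writes_headers(self, tmp_path):
        files = write_fixture_tables([], {}, tmp_path)
        text = files["farms"].read_text().strip().splitlines()
        assert len(text) == 1 and text[0].startswith("farm_id,")

    def test_row_counts(self, profile_config, factors, tmp_path):
        c = make_catchment()
        farms = generate_farm_population(
            c, {"dairy": profile_config["profiles"]["dairy"]}, seed=3,
            generator_config=profile_config["generator"],
        )[:3]
        practices = {
            f.farm_id: generate_nutrient_practice(f, seed=3, factors=factors)
            for f in farms
        }
        files = write_fixture_tables(farms, practices, tmp_path, catchments=[c])
        assert len(files["farms"].read_text().strip().splitlines()) == 4
        assert len(files["catchments"].read_text().strip().splitlines()) == 2
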