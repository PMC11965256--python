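"""End-to-end pipeline: generate -> emissions -> scenarios -> GWP ->
aggregate -> co-benefits -> valuation, as one reproducible seeded run.

All randomness flows from the single run seed through deterministic
substreams, so two runs with the same config digest and seed produce
byte-identical result tables. Every output table is derivable from its
upstream table through the module APIs; the pipeline adds no arithmetic of
its own.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

import farmgwp
from farmgwp.aggregate import aggregate_catchment, farm_type_summary
from farmgwp.cobenefits import (
    WATER_POLLUTANTS,
    baseline_water_loads,
    biodiversity_score,
    mitigated_water_loads,
    scenario_uptakes,
)
from farmgwp.emissions import EmissionFactorSet, compute_farm_emissions
from farmgwp.gwp import (
    CarbonValueSeries,
    DEFAULT_COEFFICIENTS,
    contribution_shares,
    gwp_intensity,
    to_gwp,
    valuation,
)
from farmgwp.measures import load_measure_catalogue
from farmgwp.scenarios import BAU, MAX_FEASIBLE, apply_scenario, scenario_reduction
from farmgwp.synthetic import (
    catchments_to_frame,
    generate_catchments,
    generate_farm_population,
    generate_nutrient_practice,
    load_profiles,
    write_fixture_tables,
)

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "n_catchments": 10,
    "holding_total_per_catchment": None,
    "weighted_percentiles": True,
}


def _digest(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def load_config(path: str | Path | None) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        cfg.update(yaml.safe_load(Path(path).read_text()) or {})
    return cfg


def run_pipeline(
    config: str | Path | Mapping | None,
    seed: int,
    out_dir: str | Path,
) -> dict:
    """Run every stage and write result tables plus a machine-readable
    manifest under ``out_dir``. Returns the manifest."""
    t0 = time.time()
    cfg = dict(config) if isinstance(config, Mapping) else load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    profiles_cfg = load_profiles()
    gen_cfg = dict(profiles_cfg["generator"])
    if cfg.get("holding_total_per_catchment") is not None:
        gen_cfg["holding_total_per_catchment"] = cfg["holding_total_per_catchment"]
    factors = EmissionFactorSet.default()
    catalogue = load_measure_catalogue()
    weighted = bool(cfg.get("weighted_percentiles", True))

    def stage(name, fn, *args, **kwargs):
        try:
            result = fn(*args, **kwargs)
        except Exception:
            log.error("pipeline stage %r failed", name)
            raise
        return result

    # 1. synthetic population -------------------------------------------------
    n = int(cfg.get("n_catchments", 10))
    catchments = stage("generate_catchments", generate_catchments, n, seed)
    log.info("generated %d catchments", len(catchments))
    farms, practices = [], {}
    for c in catchments:
        members = stage(
            "generate_farms", generate_farm_population,
            c, profiles_cfg["profiles"], seed, gen_cfg,
        )
        farms.extend(members)
        for f in members:
            practices[f.farm_id] = generate_nutrient_practice(
                f, seed, factors, profiles_cfg["profiles"], gen_cfg
            )
    log.info("generated %d model farms", len(farms))
    files = write_fixture_tables(farms, practices, out, catchments=catchments)

    # 2. emissions and scenarios ---------------------------------------------
    rows = []
    gwp_rows = []
    for f in farms:
        base = stage(
            "emissions", compute_farm_emissions, f, practices[f.farm_id], factors
        )
        em = {
            "bau": apply_scenario(f, base, catalogue, BAU, seed),
            "max_feasible": apply_scenario(f, base, catalogue, MAX_FEASIBLE, seed),
        }
        for scen, e in em.items():
            rows.append(
                {
                    "farm_id": f.farm_id, "scenario": scen,
                    "ch4_kg": e.ch4, "n2o_kg": e.n2o,
                    "co2_energy_kg": e.co2_energy, "co2_embedded_kg": e.co2_embedded,
                    "ch4_kg_ha": e.ch4_per_ha, "n2o_kg_ha": e.n2o_per_ha,
                    "co2_energy_kg_ha": e.co2_energy_per_ha,
                    "co2_embedded_kg_ha": e.co2_embedded_per_ha,
                }
            )
            for horizon in (20, 100):
                for embedded in (False, True):
                    g = to_gwp(e, horizon, embedded)
                    shares = contribution_shares(e, horizon, embedded)
                    gwp_rows.append(
                        {
                            "farm_id": f.farm_id, "scenario": scen,
                            "horizon": horizon, "include_embedded": embedded,
                            "gwp_kg": g, "gwp_kg_ha": g / f.area_ha,
                            "share_co2": shares["co2"], "share_ch4": shares["ch4"],
                            "share_n2o": shares["n2o"],
                            "factor_set": factors.version,
                        }
                    )
    emissions_df = pd.DataFrame(rows)
    gwp_df = pd.DataFrame(gwp_rows)
    emissions_df.to_csv(out / "emissions.csv", index=False)
    gwp_df.to_csv(out / "gwp.csv", index=False)
    files["emissions"] = out / "emissions.csv"
    files["gwp"] = out / "gwp.csv"

    # 3. mitigation summary ---------------------------------------------------
    farm_by_id = {f.farm_id: f for f in farms}
    bau_g = gwp_df[(gwp_df.scenario == "bau") & (~gwp_df.include_embedded)]
    max_g = gwp_df[(gwp_df.scenario == "max_feasible") & (~gwp_df.include_embedded)]
    red_rows = []
    for horizon in (20, 100):
        b = bau_g[bau_g.horizon == horizon].set_index("farm_id")["gwp_kg"]
        m = max_g[max_g.horizon == horizon].set_index("farm_id")["gwp_kg"]
        for fid in b.index:
            r = scenario_reduction({"gwp": b[fid]}, {"gwp": m[fid]})["gwp"]
            red_rows.append(
                {"farm_id": fid, "horizon": horizon, "reduction_pct": r}
            )
    reductions_df = pd.DataFrame(red_rows)
    reductions_df.to_csv(out / "mitigation_reductions.csv", index=False)
    files["mitigation_reductions"] = out / "mitigation_reductions.csv"

    # 4. catchment aggregation ------------------------------------------------
    per_farm = (
        emissions_df[emissions_df.scenario == "bau"]
        .set_index("farm_id")[["ch4_kg", "n2o_kg", "co2_energy_kg", "co2_embedded_kg"]]
        .join(
            bau_g[bau_g.horizon == 20].set_index("farm_id")["gwp_kg"].rename("gwp20_kg")
        )
        .join(
            bau_g[bau_g.horizon == 100]
            .set_index("farm_id")["gwp_kg"]
            .rename("gwp100_kg")
        )
    )
    summary_rows = []
    for c in catchments:
        members = [f for f in farms if f.catchment_id == c.catchment_id]
        s = stage(
            "aggregate", aggregate_catchment, members, per_farm, c, weighted
        )
        for qty in s.totals:
            p5, p50, p95 = s.percentiles[qty]
            summary_rows.append(
                {
                    "catchment_id": c.catchment_id, "quantity": qty,
                    "total_kg": s.totals[qty], "per_area_kg_ha": s.per_area[qty],
                    "p5": p5, "p50": p50, "p95": p95,
                    "cv_pct": s.cv[qty], "iqr": s.iqr[qty],
                }
            )
    summary_df = pd.DataFrame(summary_rows)
    summary_df.to_csv(out / "catchment_summary.csv", index=False)
    files["catchment_summary"] = out / "catchment_summary.csv"

    ft_summary = farm_type_summary(farms, per_farm, weighted=weighted)
    ft_flat = ft_summary.copy()
    ft_flat.columns = ["_".join(c) for c in ft_flat.columns]
    ft_flat.to_csv(out / "farm_type_summary.csv")
    files["farm_type_summary"] = out / "farm_type_summary.csv"

    # 5. co-benefits ----------------------------------------------------------
    co_rows, bio_rows = [], []
    for f in farms:
        base_loads = stage(
            "water_loads", baseline_water_loads,
            f, practices[f.farm_id], profiles_cfg["water_export"],
        )
        bau_loads = mitigated_water_loads(f, base_loads, catalogue, BAU, seed)
        max_loads = mitigated_water_loads(f, base_loads, catalogue, MAX_FEASIBLE, seed)
        red = scenario_reduction(bau_loads.as_dict(), max_loads.as_dict())
        for pollutant in WATER_POLLUTANTS:
            co_rows.append(
                {
                    "farm_id": f.farm_id, "pollutant": pollutant,
                    "bau_load_kg": getattr(bau_loads, pollutant),
                    "mitigated_load_kg": getattr(max_loads, pollutant),
                    "reduction_pct": red[pollutant],
                }
            )
        for scen_name, scen in (("bau", BAU), ("max_feasible", MAX_FEASIBLE)):
            ups = scenario_uptakes(f, catalogue, scen, seed)
            bio = biodiversity_score(catalogue, ups)
            top = sorted(bio.contributions.items(), key=lambda kv: -kv[1])[:3]
            bio_rows.append(
                {
                    "farm_id": f.farm_id, "scenario": scen_name,
                    "score": bio.score,
                    "top_measures": ";".join(mid for mid, _ in top),
                }
            )
    pd.DataFrame(co_rows).to_csv(out / "water_cobenefits.csv", index=False)
    pd.DataFrame(bio_rows).to_csv(out / "biodiversity.csv", index=False)
    files["water_cobenefits"] = out / "water_cobenefits.csv"
    files["biodiversity"] = out / "biodiversity.csv"

    # 6. valuation ------------------------------------------------------------
    series = CarbonValueSeries()
    val_rows = []
    for c in catchments:
        members = [f for f in farms if f.catchment_id == c.catchment_id]
        production = sum(f.production_value_gbp * f.holding_count for f in members)
        g20 = sum(
            per_farm.loc[f.farm_id, "gwp20_kg"] * f.holding_count for f in members
        )
        intensity = gwp_intensity(g20, production)
        for label, cv in (
            ("low", series.low), ("central", series.central), ("high", series.high)
        ):
            v = valuation(g20, production, cv)
            val_rows.append(
                {
                    "catchment_id": c.catchment_id, "carbon_value_series": label,
                    "gwp20_intensity_kg_per_gbp": v.gwp_intensity,
                    "carbon_value_per_gbp": v.carbon_value_intensity,
                    "production_gbp_per_tonne": v.production_per_tonne,
                }
            )
    pd.DataFrame(val_rows).to_csv(out / "valuation.csv", index=False)
    files["valuation"] = out / "valuation.csv"

    manifest = {
        "package_version": farmgwp.__version__,
        "factor_set": factors.version,
        "seed": int(seed),
        "config": cfg,
        "config_digest": _digest(cfg),
        "n_catchments": len(catchments),
        "n_farms": len(farms),
        "files": {k: str(v.name) for k, v in files.items()},
    }
    # wall-clock goes to the log, not the manifest, so equal (config, seed)
    # runs produce byte-identical manifests as well as tables
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("pipeline complete: %d farms, %.1fs", len(farms), time.time() - t0)
    return manifest
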