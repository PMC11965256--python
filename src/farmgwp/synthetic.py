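"""Synthetic catchments, model farms and nutrient practice.

The generators emulate the statistical structure of the survey inputs used to
build model farms for English water management catchments: ~90 spatial units
of 105-4000 km2 (mean ~1500), nine robust farm types with national area-share
targets and environmental constraints (rainfall caps for cereals and LFA
grazing), livestock cohorts and crop areas per type, per-catchment holding
counts, and fertiliser/manure practice. Geography is abstract: a catchment is
an attribute bundle and the west-high / east-low rainfall gradient is a scalar
covariate. Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

DRAINAGE_CLASSES = ("free_draining", "drained_arable", "drained_arable_grass")

FARM_TYPES = (
    "cereals", "general_cropping", "horticulture", "lowland_grazing",
    "lfa_grazing", "dairy", "mixed", "pigs", "poultry",
)


def _packaged_yaml(name: str) -> dict:
    with resources.files("farmgwp.data").joinpath(name).open("r") as fh:
        return yaml.safe_load(fh)


def stable_substream(seed: int, *tokens: str) -> np.random.Generator:
    """Deterministic child RNG derived from a root seed and string tokens.

    CRC32 of the tokens keeps the derivation stable across processes
    (Python's ``hash`` is salted and unsuitable).
    """
    keys = [zlib.crc32(t.encode()) for t in tokens]
    return np.random.default_rng(np.random.SeedSequence([int(seed), *keys]))


@dataclass(frozen=True)
class CatchmentSpec:
    """One water-management-catchment-like spatial unit (attributes, no polygon)."""

    catchment_id: str
    total_area_km2: float
    utilized_agricultural_area_ha: float
    mean_rainfall_mm: float
    drainage_mix: Mapping[str, float]
    nvz_fraction: float

    def __post_init__(self) -> None:
        if self.total_area_km2 <= 0:
            raise ValueError("total_area_km2 must be positive")
        if self.utilized_agricultural_area_ha > self.total_area_km2 * 100 + 1e-6:
            raise ValueError("utilised agricultural area exceeds catchment area")
        if abs(sum(self.drainage_mix.values()) - 1.0) > 1e-9:
            raise ValueError("drainage proportions must sum to 1")
        if not 0.0 <= self.nvz_fraction <= 1.0:
            raise ValueError("nvz_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class FarmTypeProfile:
    """Structural description of one robust farm type used by the generator."""

    farm_type: str
    rainfall_cap_mm: float | None
    area_share: float
    mean_farm_size_ha: float
    production_value_gbp_per_ha: float
    crop_mix: Mapping[str, float]
    livestock_density: Mapping[str, tuple[float, float]]
    manure_system_split: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.farm_type not in FARM_TYPES:
            raise ValueError(f"unknown farm type {self.farm_type!r}")
        if self.crop_mix and abs(sum(self.crop_mix.values()) - 1.0) > 1e-9:
            raise ValueError(f"{self.farm_type}: crop_mix must sum to 1")
        for cat, (lo, hi) in self.livestock_density.items():
            if lo < 0 or hi < lo:
                raise ValueError(f"{self.farm_type}/{cat}: bad density range")

    @property
    def has_livestock(self) -> bool:
        return any(hi > 0 for _, hi in self.livestock_density.values())


@dataclass(frozen=True)
class ModelFarm:
    """One representative farm standing for ``holding_count`` real holdings."""

    farm_id: str
    catchment_id: str
    farm_type: str
    area_ha: float
    crops: Mapping[str, float]
    cohorts: tuple[tuple[str, int], ...]
    rainfall_mm: float
    drainage_class: str
    nvz: bool
    holding_count: int
    production_value_gbp: float

    def __post_init__(self) -> None:
        if self.area_ha <= 0:
            raise ValueError("farm area must be positive")
        if sum(self.crops.values()) > self.area_ha * (1 + 1e-9):
            raise ValueError("crop areas exceed farm area")
        if self.holding_count < 1:
            raise ValueError("holding_count must be >= 1")
        if self.drainage_class not in DRAINAGE_CLASSES:
            raise ValueError(f"unknown drainage class {self.drainage_class!r}")

    @property
    def total_head(self) -> int:
        return sum(n for _, n in self.cohorts)


@dataclass(frozen=True)
class NutrientPractice:
    """Fertiliser and manure management for one model farm."""

    fertilizer_n_rate: Mapping[str, float]  # kg N ha-1 by crop
    manure_n_applied: float                 # kg N yr-1 collected and land-applied
    spreading_method: str                   # broadcast | band | incorporated
    manure_system_split: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.fertilizer_n_rate.values()):
            raise ValueError("fertiliser rates must be >= 0")
        if self.manure_n_applied < 0:
            raise ValueError("manure_n_applied must be >= 0")
        if self.manure_system_split:
            if abs(sum(self.manure_system_split.values()) - 1.0) > 1e-9:
                raise ValueError("manure system split must sum to 1")


# ---------------------------------------------------------------------------
# configuration


def load_profiles(path: str | Path | None = None) -> dict:
    """Load farm-type profiles plus generator settings.

    Returns a dict with keys ``profiles`` (farm_type -> FarmTypeProfile),
    ``catchments``, ``generator`` and ``water_export`` (raw mappings).
    """
    raw = _packaged_yaml("farm_type_profiles.yaml") if path is None else yaml.safe_load(
        Path(path).read_text()
    )
    profiles = {}
    for name, p in raw["profiles"].items():
        profiles[name] = FarmTypeProfile(
            farm_type=name,
            rainfall_cap_mm=p.get("rainfall_cap_mm"),
            area_share=float(p["area_share"]),
            mean_farm_size_ha=float(p["mean_farm_size_ha"]),
            production_value_gbp_per_ha=float(p["production_value_gbp_per_ha"]),
            crop_mix=dict(p.get("crop_mix", {})),
            livestock_density={
                k: (float(v[0]), float(v[1]))
                for k, v in (p.get("livestock_density") or {}).items()
            },
            manure_system_split=dict(p.get("manure_system_split") or {}),
        )
    return {
        "profiles": profiles,
        "catchments": raw["catchments"],
        "generator": raw["generator"],
        "water_export": raw["water_export"],
    }


# ---------------------------------------------------------------------------
# generators


def generate_catchments(
    n: int, seed: int, config: Mapping | None = None
) -> list[CatchmentSpec]:
    """Draw ``n`` synthetic catchments.

    Areas are gamma-distributed with configurable mean (~1500 km2), rejected
    outside the configured [105, 4000] km2 range. Rainfall follows a linear
    west-high / east-low gradient proxy with noise; the nitrate-vulnerable-zone
    fraction rises toward the dry (eastern, arable) end, mirroring the
    designation pattern. Deterministic given (n, seed, config).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = dict((config or load_profiles()["catchments"]))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x63A7]))

    lo, hi = float(cfg["area_km2_min"]), float(cfg["area_km2_max"])
    mean = float(cfg["area_km2_mean"])
    shape = 2.0
    out: list[CatchmentSpec] = []
    for i in range(n):
        area = rng.gamma(shape, mean / shape)
        while not lo <= area <= hi:
            area = rng.gamma(shape, mean / shape)
        x = rng.uniform()  # 0 = west, 1 = east
        rain = (
            cfg["rainfall_mm_west"]
            + (cfg["rainfall_mm_east"] - cfg["rainfall_mm_west"]) * x
            + rng.normal(0.0, cfg["rainfall_mm_sd"])
        )
        rain = float(np.clip(rain, cfg["rainfall_mm_floor"], cfg["rainfall_mm_ceiling"]))
        uaa_lo, uaa_hi = cfg["uaa_fraction_range"]
        uaa = area * 100.0 * rng.uniform(uaa_lo, uaa_hi)
        mix = rng.dirichlet([2.0, 2.0, 2.0])
        nvz = float(np.clip(1.2 - rain / 1100.0 + rng.normal(0.0, 0.08), 0.0, 1.0))
        out.append(
            CatchmentSpec(
                catchment_id=f"C{i + 1:03d}",
                total_area_km2=float(area),
                utilized_agricultural_area_ha=float(uaa),
                mean_rainfall_mm=rain,
                drainage_mix=dict(zip(DRAINAGE_CLASSES, map(float, mix))),
                nvz_fraction=nvz,
            )
        )
    return out


def _feasible(profile: FarmTypeProfile, catchment: CatchmentSpec, gen_cfg: Mapping) -> bool:
    cap = profile.rainfall_cap_mm
    if cap is None:
        return True
    if profile.farm_type == "lfa_grazing" and not gen_cfg.get(
        "enforce_lfa_rainfall_cap", True
    ):
        return True
    return catchment.mean_rainfall_mm <= cap


def _rescale_to_total(counts: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder rescale of positive integer counts to a fixed sum,
    keeping every entry >= 1."""
    raw = counts / counts.sum() * total
    base = np.maximum(np.floor(raw).astype(int), 1)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(raw - np.floor(raw)), kind="stable")
        base[order[:short]] += 1
    elif short < 0:
        order = np.argsort(raw - np.floor(raw), kind="stable")
        for idx in order:
            if short == 0:
                break
            if base[idx] > 1:
                base[idx] -= 1
                short += 1
    return base


def generate_farm_population(
    catchment: CatchmentSpec,
    profiles: Sequence[FarmTypeProfile] | Mapping[str, FarmTypeProfile],
    seed: int,
    generator_config: Mapping | None = None,
) -> list[ModelFarm]:
    """Generate the model farms of one catchment.

    Farm-type area shares follow the configured national targets, renormalised
    over the types whose rainfall constraints admit the catchment; a profile
    whose cap excludes the catchment's rainfall yields zero farms of that type.
    Farm sizes are lognormal around the profile's typical size and rescaled so
    each type's summed area hits its share of the utilised agricultural area
    exactly. Holding counts are geometric (configurable mean), optionally
    rescaled to a fixed per-catchment total.
    """
    if isinstance(profiles, Mapping):
        profiles = list(profiles.values())
    if not profiles:
        raise ValueError("profiles must be non-empty")
    gen_cfg = dict(generator_config or load_profiles()["generator"])
    rng = stable_substream(seed, "farms", catchment.catchment_id)

    feasible = [p for p in profiles if _feasible(p, catchment, gen_cfg)]
    if not feasible:
        return []
    share_sum = sum(p.area_share for p in feasible)
    n_target = float(gen_cfg.get("farms_per_catchment_mean", 40))
    crop_util = float(gen_cfg.get("crop_utilisation", 0.97))

    farms: list[ModelFarm] = []
    for profile in feasible:
        share = profile.area_share / share_sum
        type_area = share * catchment.utilized_agricultural_area_ha
        n_farms = max(1, int(round(n_target * share)))
        sizes = rng.lognormal(np.log(profile.mean_farm_size_ha), 0.45, size=n_farms)
        sizes = sizes / sizes.sum() * type_area
        mean_holdings = float(gen_cfg.get("holding_count_mean", 30))
        holding = rng.geometric(1.0 / mean_holdings, size=n_farms)
        for j, area in enumerate(sizes):
            cap = profile.rainfall_cap_mm
            if profile.farm_type == "lfa_grazing" and not gen_cfg.get(
                "enforce_lfa_rainfall_cap", True
            ):
                cap = None
            rain = rng.normal(catchment.mean_rainfall_mm, 60.0)
            rain = float(np.clip(rain, 400.0, cap if cap is not None else 2500.0))
            drain = str(
                rng.choice(DRAINAGE_CLASSES, p=list(catchment.drainage_mix.values()))
            )
            cohorts = []
            for cat, (lo, hi) in profile.livestock_density.items():
                head = int(round(rng.uniform(lo, hi) * area))
                if hi > 0:
                    head = max(head, 1)
                if head > 0:
                    cohorts.append((cat, head))
            farms.append(
                ModelFarm(
                    farm_id=f"{catchment.catchment_id}-{profile.farm_type}-{j + 1:03d}",
                    catchment_id=catchment.catchment_id,
                    farm_type=profile.farm_type,
                    area_ha=float(area),
                    crops={c: float(s * area * crop_util) for c, s in profile.crop_mix.items()},
                    cohorts=tuple(cohorts),
                    rainfall_mm=rain,
                    drainage_class=drain,
                    nvz=bool(rng.uniform() < catchment.nvz_fraction),
                    holding_count=int(holding[j]),
                    production_value_gbp=float(area * profile.production_value_gbp_per_ha),
                )
            )
    total = gen_cfg.get("holding_total_per_catchment")
    if total is not None:
        counts = _rescale_to_total(
            np.array([f.holding_count for f in farms]), int(total)
        )
        farms = [
            replace(f, holding_count=int(c)) for f, c in zip(farms, counts)
        ]
    return farms


def generate_nutrient_practice(
    farm: ModelFarm,
    seed: int,
    factors: "Mapping | None" = None,
    profiles: Mapping[str, FarmTypeProfile] | None = None,
    generator_config: Mapping | None = None,
) -> NutrientPractice:
    """Draw fertiliser and manure practice for one farm.

    Per-crop fertiliser rates are normal around the configured national means
    (CV configurable, truncated at zero). Manure N applied equals total
    excreted N times the configured retained (collected) fraction; the
    remainder is deposited at pasture and handled through the system split.
    """
    from farmgwp.emissions import EmissionFactorSet  # local import, no cycle at load

    if factors is None:
        factors = EmissionFactorSet.default()
    if generator_config is None or profiles is None:
        cfg = load_profiles()
        generator_config = generator_config or cfg["generator"]
        profiles = profiles or cfg["profiles"]
    gen_cfg = dict(generator_config)
    profile = profiles[farm.farm_type]
    rng = stable_substream(seed, "practice", farm.farm_id)

    cv = float(gen_cfg.get("fert_rate_cv", 0.10))
    rates = {}
    for crop in farm.crops:
        mean = float(factors.crops[crop]["fert_n"])
        rates[crop] = float(max(0.0, rng.normal(mean, cv * mean))) if mean > 0 else 0.0

    excreted = sum(
        factors.excreted_n[cat] * head for cat, head in farm.cohorts
    )
    manure = excreted * float(gen_cfg.get("manure_retained_fraction", 0.5))

    probs = gen_cfg.get(
        "spreading_method_probs", {"broadcast": 0.7, "band": 0.2, "incorporated": 0.1}
    )
    method = str(rng.choice(list(probs), p=list(probs.values())))
    return NutrientPractice(
        fertilizer_n_rate=rates,
        manure_n_applied=float(manure),
        spreading_method=method,
        manure_system_split=dict(profile.manure_system_split),
    )


# ---------------------------------------------------------------------------
# fixture-table IO

_FARM_COLS = [
    "farm_id", "catchment_id", "farm_type", "area_ha", "rainfall_mm",
    "drainage_class", "nvz", "holding_count", "production_value_gbp",
]
_CATCHMENT_COLS = [
    "catchment_id", "total_area_km2", "utilized_agricultural_area_ha",
    "mean_rainfall_mm", "drainage_free_draining", "drainage_drained_arable",
    "drainage_drained_arable_grass", "nvz_fraction",
]


def catchments_to_frame(catchments: Sequence[CatchmentSpec]) -> pd.DataFrame:
    rows = [
        {
            "catchment_id": c.catchment_id,
            "total_area_km2": c.total_area_km2,
            "utilized_agricultural_area_ha": c.utilized_agricultural_area_ha,
            "mean_rainfall_mm": c.mean_rainfall_mm,
            **{f"drainage_{k}": v for k, v in c.drainage_mix.items()},
            "nvz_fraction": c.nvz_fraction,
        }
        for c in catchments
    ]
    return pd.DataFrame(rows, columns=_CATCHMENT_COLS)


def frame_to_catchments(df: pd.DataFrame) -> list[CatchmentSpec]:
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                CatchmentSpec(
                    catchment_id=str(row["catchment_id"]),
                    total_area_km2=float(row["total_area_km2"]),
                    utilized_agricultural_area_ha=float(
                        row["utilized_agricultural_area_ha"]
                    ),
                    mean_rainfall_mm=float(row["mean_rainfall_mm"]),
                    drainage_mix={
                        k: float(row[f"drainage_{k}"]) for k in DRAINAGE_CLASSES
                    },
                    nvz_fraction=float(row["nvz_fraction"]),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(f"catchment table row {i}: {exc}") from exc
    return out


def write_fixture_tables(
    farms: Sequence[ModelFarm],
    practices: Mapping[str, NutrientPractice],
    path: str | Path,
    catchments: Sequence[CatchmentSpec] | None = None,
) -> dict[str, Path]:
    """Write the farm population to delimiter-separated tables under ``path``.

    Emits ``farms.csv`` plus long-format companions ``crops.csv``,
    ``cohorts.csv``, ``fert_rates.csv`` and the per-farm ``practices.csv``;
    ``catchments.csv`` when catchment specs are supplied. Round-trips
    losslessly through :func:`read_fixture_tables`.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    farm_rows, crop_rows, cohort_rows, rate_rows, practice_rows = [], [], [], [], []
    for f in farms:
        farm_rows.append(
            {
                "farm_id": f.farm_id, "catchment_id": f.catchment_id,
                "farm_type": f.farm_type, "area_ha": f.area_ha,
                "rainfall_mm": f.rainfall_mm, "drainage_class": f.drainage_class,
                "nvz": int(f.nvz), "holding_count": f.holding_count,
                "production_value_gbp": f.production_value_gbp,
            }
        )
        crop_rows += [
            {"farm_id": f.farm_id, "crop": c, "area_ha": a} for c, a in f.crops.items()
        ]
        cohort_rows += [
            {"farm_id": f.farm_id, "category": c, "head": h} for c, h in f.cohorts
        ]
        p = practices.get(f.farm_id)
        if p is not None:
            practice_rows.append(
                {
                    "farm_id": f.farm_id,
                    "spreading_method": p.spreading_method,
                    "manure_n_applied_kg": p.manure_n_applied,
                    **{f"split_{k}": v for k, v in p.manure_system_split.items()},
                }
            )
            rate_rows += [
                {"farm_id": f.farm_id, "crop": c, "n_rate_kg_ha": r}
                for c, r in p.fertilizer_n_rate.items()
            ]
    files = {}
    tables = {
        "farms": pd.DataFrame(farm_rows, columns=_FARM_COLS),
        "crops": pd.DataFrame(crop_rows, columns=["farm_id", "crop", "area_ha"]),
        "cohorts": pd.DataFrame(cohort_rows, columns=["farm_id", "category", "head"]),
        "fert_rates": pd.DataFrame(
            rate_rows, columns=["farm_id", "crop", "n_rate_kg_ha"]
        ),
        "practices": pd.DataFrame(
            practice_rows,
            columns=[
                "farm_id", "spreading_method", "manure_n_applied_kg",
                "split_slurry", "split_solid", "split_pasture",
            ],
        ),
    }
    if catchments is not None:
        tables["catchments"] = catchments_to_frame(catchments)
    for name, df in tables.items():
        out = path / f"{name}.csv"
        df.to_csv(out, index=False)
        files[name] = out
    return files


def read_fixture_tables(
    path: str | Path,
) -> tuple[list[ModelFarm], dict[str, NutrientPractice]]:
    """Read tables written by :func:`write_fixture_tables`; validates schemas
    and reports offending row numbers."""
    path = Path(path)
    farms_df = pd.read_csv(path / "farms.csv", float_precision="round_trip")
    missing = [c for c in _FARM_COLS if c not in farms_df.columns]
    if missing:
        raise ValueError(f"farms.csv missing columns: {missing}")
    crops_df = pd.read_csv(path / "crops.csv", float_precision="round_trip")
    cohorts_df = pd.read_csv(path / "cohorts.csv", float_precision="round_trip")
    rates_df = pd.read_csv(path / "fert_rates.csv", float_precision="round_trip")
    practices_df = pd.read_csv(path / "practices.csv", float_precision="round_trip")

    crops_by = {k: g for k, g in crops_df.groupby("farm_id")}
    cohorts_by = {k: g for k, g in cohorts_df.groupby("farm_id")}
    rates_by = {k: g for k, g in rates_df.groupby("farm_id")}

    farms = []
    for i, row in farms_df.iterrows():
        try:
            cg = crops_by.get(row["farm_id"])
            hg = cohorts_by.get(row["farm_id"])
            farms.append(
                ModelFarm(
                    farm_id=str(row["farm_id"]),
                    catchment_id=str(row["catchment_id"]),
                    farm_type=str(row["farm_type"]),
                    area_ha=float(row["area_ha"]),
                    crops={} if cg is None else dict(zip(cg["crop"], cg["area_ha"])),
                    cohorts=()
                    if hg is None
                    else tuple(zip(hg["category"], (int(h) for h in hg["head"]))),
                    rainfall_mm=float(row["rainfall_mm"]),
                    drainage_class=str(row["drainage_class"]),
                    nvz=bool(row["nvz"]),
                    holding_count=int(row["holding_count"]),
                    production_value_gbp=float(row["production_value_gbp"]),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(f"farms.csv row {i}: {exc}") from exc

    practices = {}
    for i, row in practices_df.iterrows():
        try:
            fid = str(row["farm_id"])
            rg = rates_by.get(fid)
            split = {
                k.removeprefix("split_"): float(row[k])
                for k in ("split_slurry", "split_solid", "split_pasture")
                if k in row and pd.notna(row[k])
            }
            practices[fid] = NutrientPractice(
                fertilizer_n_rate={}
                if rg is None
                else dict(zip(rg["crop"], rg["n_rate_kg_ha"])),
                manure_n_applied=float(row["manure_n_applied_kg"]),
                spreading_method=str(row["spreading_method"]),
                manure_system_split=split,
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(f"practices.csv row {i}: {exc}") from exc
    return farms, practices
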