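"""The on-farm mitigation-measure catalogue.

The packaged catalogue merges three verbatim transcriptions of the printed
measure tables — baseline uptake ranges, single baseline uptake rates, and
the N2O / energy / biodiversity shortlist — with an implementer-supplied
defaults file (flagged synthetic) that adds applicability and efficacies for
pollutants the printed tables do not cover. Catalogue files carry the printed
sign convention (negative = reduction); sign normalisation to
reduction-positive happens at the scenario layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

log = logging.getLogger(__name__)

POLLUTANTS = ("ch4", "n2o", "co2_energy", "nitrate", "phosphorus", "sediment")

#: the shortlist prints one measure under an abbreviated name
_NAME_ALIASES = {
    "Cultivate land for crops in spring, retaining over-winter stubbles":
        "Cultivate land for crops in spring rather than autumn, retaining "
        "over-winter stubbles",
}


@dataclass(frozen=True)
class MeasureSpec:
    """One on-farm intervention with signed per-pollutant efficacies.

    ``efficacies`` uses the printed sign convention: negative percentages are
    reductions, positive ones increases (pollution swapping). ``baseline_uptake``
    is a (min, max) percentage range; equal endpoints denote a fixed rate.
    """

    measure_id: str
    name: str
    efficacies: Mapping[str, float]
    biodiversity_score: float
    baseline_uptake: tuple[float, float]
    max_uptake: float = 100.0
    applicability: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for pol, eff in self.efficacies.items():
            if not -100.0 <= eff <= 100.0:
                raise ValueError(
                    f"{self.name}: efficacy for {pol!r} outside [-100, 100]"
                )
        lo, hi = self.baseline_uptake
        if not (0.0 <= lo <= hi <= 100.0):
            raise ValueError(f"{self.name}: baseline uptake range invalid")
        if not 0.0 <= self.max_uptake <= 100.0:
            raise ValueError(f"{self.name}: max uptake outside [0, 100]")
        if self.biodiversity_score < 0:
            raise ValueError(f"{self.name}: biodiversity score must be >= 0")

    def applies_to(self, farm_type: str) -> bool:
        return not self.applicability or farm_type in self.applicability


def _data_path(name: str):
    return resources.files("farmgwp.data").joinpath(name)


def _parse_efficacy(value, how: str = "midpoint") -> float | None:
    """Parse a printed efficacy cell; ranges like ``-50 to 25`` resolve to the
    midpoint by default."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if not s:
        return None
    if " to " in s:
        lo, hi = (float(p) for p in s.split(" to "))
        if how == "midpoint":
            return (lo + hi) / 2.0
        raise ValueError(f"unknown range resolution {how!r}")
    return float(s)


def load_measure_catalogue(
    path: str | Path | None = None, range_resolution: str = "midpoint"
) -> list[MeasureSpec]:
    """Load the measure catalogue.

    With ``path=None`` the packaged catalogue is assembled from the verbatim
    uptake tables, the GHG/biodiversity shortlist and the synthetic efficacy
    defaults. A user path must point to a single CSV in the flat interchange
    schema (measure_id, name, applicable_farm_types, uptake_min, uptake_max,
    eff_<pollutant>..., biodiversity_score).
    """
    if path is not None:
        df = pd.read_csv(path, comment="#")
        if df.empty:
            log.warning("measure catalogue %s is empty", path)
            return []
        out = []
        for _, row in df.iterrows():
            eff = {
                p: float(row[f"eff_{p}"])
                for p in POLLUTANTS
                if f"eff_{p}" in row and pd.notna(row[f"eff_{p}"])
            }
            out.append(
                MeasureSpec(
                    measure_id=str(row["measure_id"]),
                    name=str(row["name"]),
                    efficacies=eff,
                    biodiversity_score=float(row.get("biodiversity_score", 0) or 0),
                    baseline_uptake=(float(row["uptake_min"]), float(row["uptake_max"])),
                    applicability=frozenset(
                        str(row["applicable_farm_types"]).split(";")
                    )
                    if pd.notna(row.get("applicable_farm_types"))
                    else frozenset(),
                )
            )
        return out

    with _data_path("measure_uptake_ranges.csv").open() as fh:
        ranges = pd.read_csv(fh)
    with _data_path("measure_uptake_rates.csv").open() as fh:
        rates = pd.read_csv(fh)
    with _data_path("measure_ghg_biodiversity.csv").open() as fh:
        shortlist = pd.read_csv(fh)
    with _data_path("measure_efficacy_defaults_synthetic.csv").open() as fh:
        defaults = pd.read_csv(fh, comment="#")

    uptake: dict[str, tuple[float, float]] = {}
    for _, row in ranges.iterrows():
        uptake[row["measure"]] = (float(row["uptake_min"]), float(row["uptake_max"]))
    for _, row in rates.iterrows():
        r = float(row["uptake_rate"])
        uptake[row["measure"]] = (r, r)

    printed: dict[str, dict] = {}
    for _, row in shortlist.iterrows():
        name = _NAME_ALIASES.get(row["measure"], row["measure"])
        entry: dict = {"biodiversity": float(row["biodiversity_score"])}
        n2o = _parse_efficacy(row["n2o_reduction_pct"], range_resolution)
        energy = _parse_efficacy(row["energy_reduction_pct"], range_resolution)
        if n2o is not None:
            entry["n2o"] = n2o
        if energy is not None:
            entry["co2_energy"] = energy
        printed[name] = entry

    catalogue: list[MeasureSpec] = []
    for i, row in defaults.iterrows():
        name = row["measure"]
        eff: dict[str, float] = {}
        for pol in ("ch4", "nitrate", "phosphorus", "sediment"):
            v = _parse_efficacy(row.get(f"eff_{pol}"), range_resolution)
            if v is not None:
                eff[pol] = v
        extra = printed.get(name, {})
        for pol in ("n2o", "co2_energy"):
            if pol in extra:
                eff[pol] = extra[pol]
        if name in uptake:
            base = uptake[name]
        elif pd.notna(row.get("uptake_min")) and pd.notna(row.get("uptake_max")):
            base = (float(row["uptake_min"]), float(row["uptake_max"]))
        else:
            raise ValueError(f"measure {name!r} has no baseline uptake")
        catalogue.append(
            MeasureSpec(
                measure_id=f"m{i + 1:02d}",
                name=name,
                efficacies=eff,
                biodiversity_score=extra.get("biodiversity", 0.0),
                baseline_uptake=base,
                applicability=frozenset(str(row["applicable_farm_types"]).split(";")),
            )
        )
    known = {m.name for m in catalogue}
    for name in uptake:
        if name not in known:
            raise ValueError(f"uptake table measure {name!r} missing efficacy row")
    return catalogue
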