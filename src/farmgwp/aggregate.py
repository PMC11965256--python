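"""Catchment aggregation and non-parametric dispersion statistics.

Model-farm results scale to catchment totals by holding counts, are
normalised by utilised agricultural area, and are summarised with weighted
percentiles and the non-parametric coefficient of variation

    CV = (P95 - P5) / median * 100 .

Percentiles interpolate linearly between adjacent order statistics of the
holding-count-expanded population, computed from cumulative weights without
materialising the expansion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from farmgwp.synthetic import CatchmentSpec, ModelFarm


@dataclass(frozen=True)
class CatchmentSummary:
    """Holding-count-scaled totals and dispersion statistics for one catchment."""

    catchment_id: str
    utilized_agricultural_area_ha: float
    totals: Mapping[str, float]      # kg yr-1 by quantity
    per_area: Mapping[str, float]    # kg ha-1 yr-1
    percentiles: Mapping[str, tuple[float, float, float]]  # (P5, P50, P95)
    cv: Mapping[str, float]          # %
    iqr: Mapping[str, float]


def weighted_percentile(
    values: Sequence[float], weights: Sequence[int] | None, q: float
) -> float:
    """Percentile of the population where observation i appears weights[i]
    times, with linear interpolation between adjacent order statistics.

    Exactly equals ``np.percentile(np.repeat(values, weights), q)`` for
    integer weights.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("values must be non-empty")
    if weights is None:
        w = np.ones(v.size, dtype=np.int64)
    else:
        w = np.asarray(weights)
        if np.any(w < 0) or w.size != v.size:
            raise ValueError("weights must be non-negative, one per value")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    keep = w > 0
    v, w = v[keep], w[keep]
    n = int(w.sum())
    if n == 0:
        raise ValueError("total weight is zero")
    cum = np.cumsum(w)

    def order_stat(k: int) -> float:  # k is 0-based into the expanded array
        return float(v[np.searchsorted(cum, k + 1)])

    pos = (n - 1) * q / 100.0
    lo = math.floor(pos)
    hi = math.ceil(pos)
    a = order_stat(lo)
    if hi == lo:
        return a
    return a + (pos - lo) * (order_stat(hi) - a)


def nonparametric_cv(
    values: Sequence[float], weights: Sequence[int] | None = None
) -> float:
    """(P95 - P5) / median * 100; NaN when the median is zero (undefined)."""
    p5 = weighted_percentile(values, weights, 5)
    p50 = weighted_percentile(values, weights, 50)
    p95 = weighted_percentile(values, weights, 95)
    if p50 == 0:
        return math.nan
    return (p95 - p5) / p50 * 100.0


def aggregate_catchment(
    farms: Sequence[ModelFarm],
    per_farm_results: pd.DataFrame,
    catchment: CatchmentSpec,
    weighted: bool = True,
) -> CatchmentSummary:
    """Aggregate per-farm quantities to one catchment.

    ``per_farm_results`` is indexed by farm_id with one numeric column per
    quantity. Totals multiply farm values by holding counts; per-area divides
    by the catchment's utilised agricultural area. Percentiles, CV and IQR
    are computed over member farms, holding-count weighted by default.
    """
    members = [f for f in farms if f.catchment_id == catchment.catchment_id]
    if any(f.catchment_id != catchment.catchment_id for f in farms):
        raise ValueError("farms contains members of another catchment")
    missing = [f.farm_id for f in members if f.farm_id not in per_farm_results.index]
    if missing:
        raise ValueError(f"missing results for farms: {missing}")
    ids = [f.farm_id for f in members]
    counts = np.array([f.holding_count for f in members])
    block = per_farm_results.loc[ids]

    totals, per_area, percentiles, cvs, iqrs = {}, {}, {}, {}, {}
    uaa = catchment.utilized_agricultural_area_ha
    for col in block.columns:
        vals = block[col].to_numpy(dtype=float)
        totals[col] = float(np.sum(vals * counts))
        per_area[col] = totals[col] / uaa
        w = counts if weighted else None
        p5 = weighted_percentile(vals, w, 5)
        p50 = weighted_percentile(vals, w, 50)
        p95 = weighted_percentile(vals, w, 95)
        percentiles[col] = (p5, p50, p95)
        cvs[col] = math.nan if p50 == 0 else (p95 - p5) / p50 * 100.0
        iqrs[col] = weighted_percentile(vals, w, 75) - weighted_percentile(vals, w, 25)
    return CatchmentSummary(
        catchment_id=catchment.catchment_id,
        utilized_agricultural_area_ha=uaa,
        totals=totals,
        per_area=per_area,
        percentiles=percentiles,
        cv=cvs,
        iqr=iqrs,
    )


def farm_type_summary(
    farms: Sequence[ModelFarm],
    per_farm_results: pd.DataFrame,
    weighted: bool = True,
) -> pd.DataFrame:
    """P5 / median / P95 by farm type and quantity.

    Returns a frame indexed by farm type with MultiIndex columns
    (quantity, statistic), holding-count weighted by default.
    """
    if per_farm_results.empty:
        raise ValueError("per_farm_results must be non-empty")
    by_type: dict[str, list[ModelFarm]] = {}
    for f in farms:
        by_type.setdefault(f.farm_type, []).append(f)
    rows = {}
    for ftype, members in sorted(by_type.items()):
        ids = [f.farm_id for f in members]
        counts = [f.holding_count for f in members] if weighted else None
        block = per_farm_results.loc[ids]
        row = {}
        for col in block.columns:
            vals = block[col].to_numpy(dtype=float)
            row[(col, "p5")] = weighted_percentile(vals, counts, 5)
            row[(col, "median")] = weighted_percentile(vals, counts, 50)
            row[(col, "p95")] = weighted_percentile(vals, counts, 95)
        row[("sample", "count")] = len(members)
        rows[ftype] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.columns = pd.MultiIndex.from_tuples(out.columns)
    out.index.name = "farm_type"
    return out
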