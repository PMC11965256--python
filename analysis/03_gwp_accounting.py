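"""Warming-potential structure: horizon ratios and per-gas shares.

For each farm type, compares GWP20 against GWP100 (methane-dominated grazing
systems should be more than double) and tabulates mean per-gas contribution
shares with and without embedded emissions.
"""

from pathlib import Path

import pandas as pd

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "pipeline"


def main() -> None:
    run = SCRATCH
    farms = pd.read_csv(run / "farms.csv")[["farm_id", "farm_type"]]
    gwp = pd.read_csv(run / "gwp.csv").merge(farms, on="farm_id")
    bau = gwp[(gwp.scenario == "bau")]

    wide = (
        bau[~bau.include_embedded]
        .pivot_table(index=["farm_id", "farm_type"], columns="horizon",
                     values="gwp_kg")
        .reset_index()
    )
    wide["ratio_20_100"] = wide[20] / wide[100]
    ratios = wide.groupby("farm_type")["ratio_20_100"].median().sort_values(
        ascending=False
    )

    shares = (
        bau.groupby(["farm_type", "horizon", "include_embedded"])[
            ["share_co2", "share_ch4", "share_n2o"]
        ]
        .mean()
        .round(1)
    )
    out = RESULTS / "gwp_shares_by_farm_type.csv"
    shares.to_csv(out)

    print("median GWP20 / GWP100 ratio by farm type:")
    print(ratios.round(2).to_string())
    doubled = ratios[ratios > 2.0].index.tolist()
    print(f"types with GWP20 more than double GWP100: {', '.join(doubled)}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
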