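"""Carbon-value arithmetic for farm production.

Evaluates the policy valuation chain from the published national inputs (a
business-as-usual GWP20 intensity of 4.2 kg CO2 eq per pound of production,
the 2020 carbon-value series, and the ~24% technically feasible mitigation)
and, separately, the same intensities for the synthetic population.
"""

import json
from pathlib import Path

import pandas as pd

from farmgwp.gwp import CarbonValueSeries, carbon_value_per_pound, pounds_per_tonne

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "pipeline"


def main() -> None:
    series = CarbonValueSeries()
    bau_intensity = 4.2
    mitigated = bau_intensity * (1 - 24.0 / 100.0)

    chain = {
        "bau": {
            label: carbon_value_per_pound(bau_intensity, value)
            for label, value in (
                ("low", series.low), ("central", series.central), ("high", series.high)
            )
        },
        "mitigated": {
            label: carbon_value_per_pound(mitigated, value)
            for label, value in (
                ("low", series.low), ("central", series.central), ("high", series.high)
            )
        },
        "production_per_tonne_gwp20": pounds_per_tonne(bau_intensity),
    }
    print("carbon value per pound of production (BAU):", chain["bau"])
    print("after ~24% technically feasible mitigation:", chain["mitigated"])
    print(f"production value per tonne CO2 eq: GBP {chain['production_per_tonne_gwp20']}")

    val = pd.read_csv(SCRATCH / "valuation.csv")
    central = val[val.carbon_value_series == "central"]
    print(
        "synthetic population: GWP20 intensity "
        f"{central.gwp20_intensity_kg_per_gbp.median():.2f} kg CO2 eq per GBP "
        f"(catchment median)"
    )
    out = RESULTS / "carbon_valuation.json"
    out.write_text(json.dumps(chain, indent=2) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
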