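#!/usr/bin/env python
"""Compare scenarios against BAU within each SSP world.

Reads the matrix tables written by 02_run_matrix.py, recomputes savings,
percent savings and annualized mitigation rates from the emission table
(cross-checking the stored summary), and reports plantation expansion per
scenario. Writes results/comparison.csv.
"""
import argparse
from pathlib import Path

import pandas as pd

from woodcarbon import (annual_establishment_rate, annualize, area_expansion,
                        percent_growth, percent_saving, scenario_saving)

SCENARIOS = ("BAU", "10pc", "50pc", "90pc")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--matrix", type=Path, default=Path("results/matrix"))
    parser.add_argument("--out", type=Path,
                        default=Path("results/comparison.csv"))
    args = parser.parse_args()

    emissions = pd.read_csv(args.matrix / "emissions.csv")
    land = pd.read_csv(args.matrix / "land.csv")
    horizon = int(emissions.year.max() - emissions.year.min())

    def c_cum(scenario: str, ssp: str) -> float:
        sub = emissions[(emissions.scenario == scenario)
                        & (emissions.ssp == ssp)
                        & (emissions.region_id == "GLOBAL")
                        & (emissions.component == "c")
                        & (emissions.year == emissions.year.max())]
        return float(sub.cumulative_gtco2.iloc[0])

    def plantation(scenario: str, ssp: str, year: int) -> float:
        sub = land[(land.scenario == scenario) & (land.ssp == ssp)
                   & (land.pool == "plantation") & (land.year == year)]
        return float(sub.area_mha.sum())

    rows = []
    for ssp in sorted(emissions.ssp.unique()):
        bau = c_cum("BAU", ssp)
        for scenario in SCENARIOS:
            c = c_cum(scenario, ssp)
            saving = scenario_saving(bau, c)
            p2020 = plantation(scenario, ssp, 2020)
            p2100 = plantation(scenario, ssp, 2100)
            rows.append({
                "scenario": scenario, "ssp": ssp,
                "c_cum_gt": round(c, 2),
                "saving_gt": round(saving, 2),
                "percent_saving": percent_saving(saving, bau),
                "annualized_gt_yr": annualize(saving, horizon),
                "plantation_2100_mha": round(p2100, 1),
                "plantation_expansion_mha": round(
                    area_expansion(p2100, p2020), 1),
                "establishment_rate_mha_yr": annual_establishment_rate(
                    p2100, p2020, horizon),
                "plantation_growth_pct": round(percent_growth(p2100, p2020)),
            })
    comparison = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    comparison.to_csv(args.out, index=False)
    print(comparison.to_string(index=False))
    print(f"\nwritten to {args.out}")


if __name__ == "__main__":
    main()
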