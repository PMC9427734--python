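#!/usr/bin/env python
"""Generate the synthetic regional inputs for all three SSP worlds.

Writes regions.csv, population.csv and parameters.csv per SSP under
results/fixtures/<ssp>/ and prints the calibration checkpoints: the 2020
global land-pool totals and the 2100 global urban shares.
"""
import argparse
from pathlib import Path

from woodcarbon import generate_fixtures
from woodcarbon.synthetic import write_population_csv


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--n-regions", type=int, default=12)
    parser.add_argument("--out", type=Path, default=Path("results/fixtures"))
    args = parser.parse_args()

    for ssp in ("SSP1", "SSP2", "SSP3"):
        fx = generate_fixtures(args.n_regions, ssp, args.seed)
        out = args.out / ssp
        out.mkdir(parents=True, exist_ok=True)
        fx.regions.write_csv(out / "regions.csv")
        write_population_csv(fx.population, out / "population.csv")
        fx.params.write_csv(out / "parameters.csv")

        urban = sum(t.urban[-1] for t in fx.population.values())
        total = sum(t.total[-1] for t in fx.population.values())
        print(f"{ssp}: urban share 2100 = {100 * urban / total:.1f}% | "
              f"plantations {fx.params.global_pool('plantation'):.0f} Mha, "
              f"cropland {fx.params.global_pool('cropland'):.0f} Mha, "
              f"natural forest "
              f"{fx.params.global_pool('primary_forest') + fx.params.global_pool('secondary_forest'):.0f} Mha")
    print(f"fixtures written to {args.out}/")


if __name__ == "__main__":
    main()
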