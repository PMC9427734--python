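#!/usr/bin/env python
"""Plot the scenario trajectories: plantation area and cumulative emissions.

Reruns the matrix for the requested seed and writes one two-panel figure
per SSP (plantation area by scenario; overall cumulative emissions by
scenario) under results/figures/.
"""
import argparse
from pathlib import Path

from woodcarbon import ScenarioConfig, generate_fixtures, run_matrix
from woodcarbon.engine import _write_plots


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results/figures"))
    args = parser.parse_args()

    fixtures = {ssp: generate_fixtures(12, ssp, args.seed)
                for ssp in ("SSP1", "SSP2", "SSP3")}
    _, results = run_matrix(fixtures,
                            base_config=ScenarioConfig(seed=args.seed))
    args.out.mkdir(parents=True, exist_ok=True)
    for path in _write_plots(results, args.out):
        print(f"wrote {path}")


if __name__ == "__main__":
    main()
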