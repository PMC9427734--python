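# woodcarbon

Scenario model of land use and cumulative CO2 emissions when new urban
dwellers are housed in engineered-wood (mass-timber) buildings instead of
conventional cement-and-steel buildings, 2020–2100.

Cities will absorb billions of new inhabitants this century. Building
their housing from engineered wood turns buildings into a long-term carbon
pool and avoids cement/steel process emissions — but the wood has to come
from somewhere, which means expanding forest plantations and harvesting
natural forests, with land-use-change emissions of their own. This package
lets land-system and carbon-cycle researchers explore that trade-off as a
closed, testable accounting model on synthetic regional data.

## Model core

* **Demand**: cumulative engineered-wood demand per region
  `M = (P_peak − P_2020) · M_w^c · CW · PR` (MtC), where PR is the share
  of new urban dwellers housed in wood (0 / 0.1 / 0.5 / 0.9 for the BAU /
  10pc / 50pc / 90pc scenarios), `CW = 0.476` tC/tDM; annualized with a
  sliding scale weighting years near the urbanization peak, harvested at
  50% efficiency.
* **Forests**: age-class pools (primary, secondary, plantation, other
  land) with Chapman–Richards growth; rotation by current-annual-increment
  maximization; anticipatory plantation establishment one rotation ahead
  of demand; protected areas excluded from harvest; strict land-area
  conservation.
* **Products**: IPCC tier-1 first-order-decay carbon pools,
  `C[t+1] = e^{−k}C[t] + ((1−e^{−k})/k)·inflow`, half-lives 35 y
  (industrial roundwood) and 60 y (engineered wood).
* **Ledger**: gross land-use-change emissions (+), regrowth (−), product
  storage credit (−) and decay release (+) combine into land (a.3),
  manufacturing (b.3 = wood b.1 + cement/steel b.2) and overall
  (c = a.3 + b.3) series; scenarios are differenced against the BAU of
  their SSP world.

## Worked example

Run the full 4 × 3 scenario matrix on the default 12-region fixtures:

```
python analysis/01_generate_inputs.py     # fixtures per SSP
python analysis/02_run_matrix.py          # all runs + tables
python analysis/03_scenario_comparison.py # savings vs BAU
python analysis/04_figures.py             # trajectory figures
```

`02_run_matrix.py` prints (SSP2 rows, seed 0):

```
scenario  ssp  a3_cum_gt  b3_cum_gt  c_cum_gt  saving_gt  percent_saving  annualized_gt_yr  plantation_area_2100_mha
     BAU SSP2    -163.34      22.23   -141.11       0.00               0              0.00                    189.40
    10pc SSP2    -187.47      21.47   -165.99      24.89              18              0.31                    256.18
    50pc SSP2    -280.80      18.44   -262.36     121.25              86              1.52                    523.30
    90pc SSP2    -364.02      15.41   -348.60     207.50             147              2.59                    784.32
```

Reading the 90pc row: land-side emissions (`a3_cum_gt`) are −364 Gt CO2
cumulative by 2100 — a net sink, because plantation and secondary-forest
regrowth plus carbon banked in buildings outweigh clearing, degradation
and harvest emissions. Manufacturing (`b3_cum_gt`) adds +15 Gt (mostly
wood processing; cement/steel nearly vanish at PR = 0.9). Overall, housing
90% of new urban dwellers in wood saves 207 Gt CO2 against BAU
(≈ 2.6 Gt/yr) but requires plantations to expand from 137 to 784 Mha.
Savings rise and overall emissions fall monotonically with PR, while the
plantation footprint grows — the central tension the model quantifies.
The same tables are written as CSV under `results/matrix/` (`emissions`,
`land`, `harvest`, `hwp`, `demand`, `summary`).

A `woodcarbon` CLI wraps the same pipeline
(`woodcarbon generate | run | matrix | report`, see `--help`).

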