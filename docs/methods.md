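# Methods

`woodcarbon` is a desk-scale scenario model of the land-use and carbon
consequences of housing new urban dwellers in mid-rise buildings whose
primary structure is engineered wood (cross-laminated timber and similar
products). It couples four pieces — a demand model, an age-class forest
simulator, first-order-decay product pools, and an emission ledger — and
runs them over a scenario matrix of four timber-uptake levels (BAU, 10pc,
50pc, 90pc) by three urbanization worlds (SSP1, SSP2, SSP3) on synthetic
regional fixtures.

## Demand for structural wood

Cumulative engineered-wood demand per region is

    M = (P_peak − P_2020) · M_w^c · CW · PR      [MtC],

where `P_peak − P_2020` is the new urban population (million) accumulated
until the regional urbanization peak, `M_w^c` the mean woody-biomass demand
per capita for primary structural and enclosure systems (tDM/person), `CW`
the carbon-to-wood ratio (default 0.476 tC/tDM, randomizable within
±0.04), and `PR` the scenario factor (0, 0.1, 0.5, 0.9). The cumulative
figure is spread over the years up to the peak with a sliding scale —
weights proportional to `(t − 2020)^p`, `p = 1` by default, so demand
concentrates toward the peak — and converted to a harvest requirement with
a 50% harvesting efficiency (two units of wood cut per unit installed).
Demand after the urbanization peak is zero by construction; post-peak
replacement construction is a documented non-goal. Industrial roundwood
and wood-fuel demand are exogenous series, identical across PR scenarios,
which isolates the effect of engineered-wood demand.

Whether the efficiency factor divides the cumulative figure or the annual
series is mathematically immaterial under the linear weighting; it is
applied annually.

## Forest dynamics

Each region carries six land pools: cropland, pasture, other land
(non-forest natural vegetation, < 20 tC/ha), primary forest, secondary
forest and plantations. Forest pools are age-structured at one-year cohort
resolution (five-year classes are a reporting view); stand carbon density
follows a Chapman–Richards curve `A(1 − e^{−k·age})^b`. Primary forest is
initialized entirely in the highest age class (at the asymptote);
secondary forest over a mature age window (40–120 years); plantations
uniformly over one rotation so that a cohort matures every year.

Rotation length maximizes the current annual increment on the 5-year grid
(ties toward the younger class); a configuration switch selects the
culmination of the mean annual increment instead, which never yields a
shorter rotation. Plantations are established anticipatorily: in year *t*
the model provisions the plantation-assigned demand of year *t + R*
(engineered-wood harvest plus a 34% share of industrial roundwood),
establishing `demand / density(R)` hectares on unprotected other land
first, then unprotected secondary forest. Clearing emits the standing
carbon of the converted land; established cohorts are locked until the
rotation elapses. If unprotected land runs out, the unprovisioned demand
is logged and implicitly rerouted to natural-forest harvest — the logged
reroutes are the model's proxy for harvest pressure on natural forests.

Harvest sourcing is a priority waterfall: mature plantations (age ≥ R,
oldest first), then unprotected secondary, then unprotected primary
forest. Other land supplies wood fuel only. Harvested plantation area is
replanted at age 0; harvested natural forest re-enters secondary forest at
age 0; protected areas (a regional share of natural forest and other land,
default drawn from [0.1, 0.4]) are never harvested, degraded or converted.
Unprotected natural forest additionally degrades at a constant 0.001/yr
(folding shifting cultivation into one historically motivated rate),
re-entering secondary forest at age 0. Wood fuel is assumed fully oxidized
in the harvest year. Cropland and pasture are held constant: the fixed
priority ordering stands in for the cost-minimizing land allocation that
full-scale land-system models solve, and cropland feedback is deliberately
decoupled. Total land area per region is
conserved by every operation to 1e−9 relative.

## Product pools

Carbon in harvested wood products follows the IPCC tier-1 first-order
decay update

    C[t+1] = e^{−k} C[t] + ((1 − e^{−k})/k) · inflow[t],   k = ln 2 / HL,

with half-lives of 35 years (industrial roundwood products) and 60 years
(engineered wood in buildings); stocks are zero until 2020. The inflow
term is the annual-average formulation, so the effective inflow of a year
is `((1 − e^{−k})/k) · inflow`; the decay outflow is the mass-balance
residual `(1 − e^{−k}) C[t]`, reported as a positive emission. End-of-life
disposal beyond decay and recycling cascades are not modeled. The
measured halving time of an isolated pool equals the configured half-life
exactly; the numerical comparison carries a 1e−12 relative guard because
`(e^{−k})^{60}` lands a few ulp above 0.5 in binary floating point.

## Emission ledger

Sign conventions (annual, MtCO2; cumulative series baselined at zero in
2020): gross land-use-change emissions are positive and comprise clearing
for establishment, natural-forest degradation and the booking of *all*
harvested carbon (including the efficiency losses and wood fuel); regrowth
across all age classes, protected and locked cohorts included, is
negative; a.1 is their sum. Double counting is avoided by the three-step
scheme: harvested carbon is first booked as emitted, the effective inflow
into the two product pools is then re-credited (negative), and decay
releases are added back (positive) — together a.2, so cumulative a.2
equals minus the standing pool stock. a.3 = a.1 + a.2. Manufacturing
emissions are b.1 (engineered wood) and b.2 (cement + steel) from annual
urban newcomers split PR / (1 − PR), with static emission factors (no
decarbonization pathway), b.3 = b.1 + b.2, and c = a.3 + b.3 overall.
Carbon crosses into CO2 exactly once (factor 44/12). Material CO2e
factors are treated as CO2 for ledger addition; carbonation re-uptake of
cement is not modeled.

Scenario comparisons difference each run against the BAU of its own SSP:
saving = c_BAU − c_scenario, percent saving against |c_BAU|, annualized
over the 80-year horizon. Reported percentages round half-up to integers
and rates half-up to two decimals — the convention the headline numbers
follow (71/80 → 0.89); note one reported rate in the motivating literature
(0.12 for 9/80) is inconsistent with any standard rounding of 0.1125.
Plantation expansion is reported both as end-minus-start (the differenced
convention, e.g. 425 − 276 = 149 Mha at full scale) and as a growth
percentage; a 143 Mha variant of that difference circulates in summary
text and is not adjudicated here.

## Synthetic study conditions

The generator defines the study conditions; all randomness flows from one
master seed through named `SeedSequence` streams.

* **Regions.** Default 12 regions partitioning 13,000 Mha (Dirichlet
  shares), protection shares uniform in [0.1, 0.4].
* **Land pools.** Named pools are allocated proportionally to regional
  land with mild lognormal jitter and renormalized so global totals scale
  with world land; at defaults the 2020 anchors are exact: plantations
  137 Mha, cropland 1595 Mha, natural forest 3629 Mha (60% primary),
  pasture 3000 Mha; other land closes each region's balance.
* **Population.** 7.8 billion in 2020 at 56% urban. Global totals reach
  8.2 / 9.0 / 11.5 billion by 2100 under SSP1/2/3 — chosen so that
  urbanization-driven construction demand ranks SSP1 > SSP2 > SSP3, the
  ordering the sensitivity analysis of such scenarios reports — and the
  2100 urban shares equal 92 / 80 / 58% exactly by construction (regional
  saturation levels are allocated to meet the global anchor). Urban
  headcounts rise along a normalized logistic to a regional peak year
  drawn from [2040, 2090], then stay flat.
* **Demand constants.** `M_w^c` = 11.5 tDM/person (≈ 5.5 tC per capita of
  structural carbon, the mid-rise figure in the building-sector
  literature; the underlying per-capita intensity is not printed in the
  motivating analysis and is a fixture constant, never an acceptance
  value). Materials per conventionally housed person: 10 t cement,
  1 t steel; emission factors 0.45 / 0.6 / 1.85 tCO2e/t for wood, cement,
  steel. Exogenous global wood demand: 80 MtC/yr of long-lived industrial
  roundwood — the series is scoped to the structural sawnwood/panel
  fraction because no pulp/paper pool exists in the model — plus
  400 MtC/yr wood fuel, split across regions by land share.
* **Growth curves.** Plantations A ∈ [80, 140] tC/ha, k ∈ [0.045, 0.075],
  b = 2 (rotations ≈ 15–25 y); natural forest A ∈ [100, 160],
  k ∈ [0.02, 0.04], b = 2.5; other land A = 8 tC/ha.

What the fixtures do *not* emulate: real country geography and trade,
cost-optimized land allocation, income-driven roundwood demand, climate
feedbacks, disturbances (fire, pests, storms), soil carbon, albedo, and
the absolute magnitudes of a full integrated-assessment run. Passing
tests therefore establish the internal accounting identities, calibration
anchors and scenario *orderings* (more timber uptake → larger plantation
area, lower overall cumulative emissions; building-pool carbon overtaking
the roundwood-product pool in the 50pc/90pc scenarios), not the absolute
Gt-scale results of any full-scale model.

## Numerical choices and problem sizes

Annual timestep over 2020–2100; one-year cohorts capped at 160 years (the
top cohort accumulates at the asymptote). Waterfall draws and clearings
break ties oldest-first for harvest (maximum carbon per hectare) and
youngest-first for conversion (minimum clearing emissions). Area and mass
balances are asserted at 1e−9 relative; degenerate inputs (zero demand,
zero-population regions, PR = 0) short-circuit to exact zeros. The default
analysis uses 12 regions and the full 4 × 3 matrix, which runs in a few
seconds; property tests sweep seeds 0–19 where calibration anchors are
asserted. An infeasible harvest (demand exceeding all harvestable carbon)
aborts the run naming the region and year.

## Known limitations

Savings percentages can exceed 100% when the BAU baseline is itself a
strong net sink, as happens under fixture-scale regrowth; the percentages
are reported against |c_BAU| as defined. Mature plantation conversion to
cropland is a dormant pathway (cropland is exogenous). The establishment
ledger provisions against scheduled maturities only, so surplus mature
stock can accumulate and plantation areas are conservative upper bounds
for the demand they serve.
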