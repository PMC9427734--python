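"""Scenario engine: full pipeline over the BAU/10pc/50pc/90pc x SSP matrix.

One scenario run executes, per region: demand scheduling, anticipatory
plantation establishment (one rotation ahead of demand), then an annual
loop of harvest -> degradation -> regrowth/ageing -> product-pool update,
with every flux booked in the emission ledger.  Global series are pure sums
over regions (no trade).  Runs are deterministic for a fixed config and
fixture seed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CO2_PER_C, SCENARIO_PR, GeneratorConfig, ScenarioConfig
from .demand import DemandParams, DemandSchedule, build_schedule
from .forest import (HarvestReport, LandState, degradation_emissions,
                     establish_plantations, harvest, init_land_state,
                     regrowth_uptake)
from .hwp import HWPPool
from .ledger import (BuildingMaterialParams, EmissionComponents,
                     assemble_components, manufacturing_emissions)
from .synthetic import (ParameterSet, PopulationTrajectory, RegionSet,
                        generate_parameters, generate_population,
                        generate_regions)

log = logging.getLogger(__name__)


@dataclass
class Fixtures:
    """Input bundle for one SSP world: regions, populations, parameters."""

    regions: RegionSet
    population: dict[str, PopulationTrajectory]
    params: ParameterSet
    ssp: str
    seed: int


def generate_fixtures(n_regions: int = 12, ssp: str = "SSP2", seed: int = 0,
                      gen: GeneratorConfig | None = None) -> Fixtures:
    """Generate a complete synthetic fixture set from one master seed."""
    gen = gen or GeneratorConfig()
    regions = generate_regions(n_regions, seed, gen)
    population = generate_population(regions, ssp, seed, gen)
    params = generate_parameters(regions, seed, gen)
    return Fixtures(regions=regions, population=population, params=params,
                    ssp=ssp, seed=seed)


@dataclass
class ScenarioResult:
    """All output tables of one scenario run plus a one-row summary."""

    config: ScenarioConfig
    components: EmissionComponents            # global
    region_components: dict[str, EmissionComponents]
    schedules: dict[str, DemandSchedule]
    land: pd.DataFrame                        # region, year, pool, area_mha
    harvest: pd.DataFrame
    hwp: pd.DataFrame
    reroutes: list[dict]                      # plantation shortfall log
    provenance: dict

    @property
    def years(self) -> np.ndarray:
        return self.components.years

    def plantation_area(self, year: int) -> float:
        sub = self.land[(self.land.pool == "plantation")
                        & (self.land.year == year)]
        return float(sub.area_mha.sum())

    def summary_row(self) -> dict:
        c = self.components
        end = -1
        return {
            "scenario": self.config.scenario,
            "ssp": self.config.ssp,
            "a1_cum_gt": float(c.cumulative("a1")[end]),
            "a2_cum_gt": float(c.cumulative("a2")[end]),
            "a3_cum_gt": float(c.cumulative("a3")[end]),
            "b1_cum_gt": float(c.cumulative("b1")[end]),
            "b2_cum_gt": float(c.cumulative("b2")[end]),
            "b3_cum_gt": float(c.cumulative("b3")[end]),
            "c_cum_gt": float(c.cumulative("c")[end]),
            "plantation_area_2100_mha": self.plantation_area(
                self.config.end_year),
        }

    def emissions_frame(self) -> pd.DataFrame:
        frames = [self.components.to_frame(self.config.scenario,
                                           self.config.ssp, "GLOBAL")]
        for rid, comp in self.region_components.items():
            frames.append(comp.to_frame(self.config.scenario,
                                        self.config.ssp, rid))
        return pd.concat(frames, ignore_index=True)


def run_scenario(config: ScenarioConfig, fixtures: Fixtures) -> ScenarioResult:
    """Run one scenario over one SSP fixture set."""
    config.validate()
    params = fixtures.params
    years = np.array(list(config.years))
    n_years = years.size
    pr = config.pr

    dparams = DemandParams(
        wood_per_capita=params.wood_per_capita,
        carbon_wood_ratio=params.carbon_wood_ratio,
        pr=pr,
        harvest_efficiency=config.harvest_efficiency,
        weight_exponent=config.weight_exponent,
    )
    materials = BuildingMaterialParams(
        wood_per_capita=params.wood_per_capita,
        cement_per_capita=params.cement_per_capita,
        steel_per_capita=params.steel_per_capita,
        ef_wood=params.ef_wood, ef_cement=params.ef_cement,
        ef_steel=params.ef_steel,
    )

    schedules: dict[str, DemandSchedule] = {}
    states: dict[str, LandState] = {}
    pools: dict[str, dict[str, HWPPool]] = {}
    maturity: dict[str, dict[int, float]] = {}
    fluxes: dict[str, dict[str, np.ndarray]] = {}
    region_land_rows: list[tuple] = []
    harvest_rows: list[tuple] = []
    hwp_rows: list[tuple] = []
    reroutes: list[dict] = []

    for region in fixtures.regions:
        rid = region.region_id
        traj = fixtures.population[rid]
        rp = params[rid]
        schedules[rid] = build_schedule(traj, dparams, rp.roundwood,
                                        rp.woodfuel, years=years)
        state = init_land_state(region, rp, config.rotation_rule,
                                config.max_cohort_age)
        states[rid] = state
        pools[rid] = {
            "industrial_roundwood": HWPPool("industrial_roundwood",
                                            config.half_life_roundwood),
            "engineered_wood": HWPPool("engineered_wood",
                                       config.half_life_engineered),
        }
        # anticipatory-supply ledger: carbon maturing on plantations per year
        rot = state.rotation
        density_rot = state.plantation.curve.density(float(rot))
        led: dict[int, float] = {}
        for age in range(rot + 1):
            area = state.plantation.areas[age]
            if area > 0:
                led[2020 + rot - age] = led.get(2020 + rot - age, 0.0) \
                    + area * density_rot
        maturity[rid] = led
        fluxes[rid] = {name: np.zeros(n_years) for name in
                       ("clearing", "degradation", "booking", "regrowth",
                        "credit", "release")}
        for pool, area in state.pool_areas().items():
            region_land_rows.append((rid, 2020, pool, area))

    year_index = {int(y): i for i, y in enumerate(years)}

    for year in years[1:]:
        yi = year_index[int(year)]
        for region in fixtures.regions:
            rid = region.region_id
            state = states[rid]
            sched = schedules[rid]
            fl = fluxes[rid]
            rot = state.rotation
            density_rot = state.plantation.curve.density(float(rot))

            # 1. anticipatory establishment for the year one rotation ahead
            target = int(year) + rot
            if target <= config.end_year:
                ti = year_index[target]
                plant_demand = sched.engineered_harvest[ti] \
                    + config.plantation_roundwood_share * sched.roundwood[ti]
                gap = plant_demand - maturity[rid].get(target, 0.0)
                if gap > 0:
                    est_area, clear_em, short = establish_plantations(
                        gap, state, config.land_priority)
                    fl["clearing"][yi] += clear_em
                    maturity[rid][target] = maturity[rid].get(target, 0.0) \
                        + est_area * density_rot
                    if short > 1e-9:
                        reroutes.append({
                            "region_id": rid, "year": int(year),
                            "target_year": target, "shortfall_mtc": short,
                        })
                        log.warning(
                            "plantation shortfall in %s for %d: %.3f MtC "
                            "rerouted to natural-forest harvest",
                            rid, target, short)

            # 2. harvest this year's demand
            report: HarvestReport = harvest(
                state,
                engineered_mtc=sched.engineered_harvest[yi],
                roundwood_mtc=sched.roundwood[yi],
                woodfuel_mtc=sched.woodfuel[yi],
            )
            fl["booking"][yi] += report.total_harvest * CO2_PER_C
            if report.replanted_area > 0 and int(year) + rot <= config.end_year:
                maturity[rid][int(year) + rot] = \
                    maturity[rid].get(int(year) + rot, 0.0) \
                    + report.replanted_area * density_rot
            for pool, mtc in report.harvest_by_pool.items():
                harvest_rows.append((rid, int(year), pool, mtc,
                                     report.cleared_by_pool.get(pool, 0.0)))

            # 3. degradation of unprotected natural forest
            fl["degradation"][yi] += degradation_emissions(
                state, config.degradation_rate)

            # 4. regrowth and ageing
            fl["regrowth"][yi] += regrowth_uptake(state, config.timestep)
            state.assert_no_negative()

            # 5. product pools: credit effective inflows, book decay releases
            inflows = {
                "industrial_roundwood": sched.roundwood[yi],
                "engineered_wood": sched.engineered_inflow[yi],
            }
            for product, pool in pools[rid].items():
                inflow = float(inflows[product])
                eff = pool.effective_inflow(inflow)
                pool.update(inflow)
                fl["credit"][yi] -= eff * CO2_PER_C
                fl["release"][yi] += pool.releases_c[-1] * CO2_PER_C
                hwp_rows.append((rid, int(year), product, pool.stock, inflow,
                                 pool.releases_c[-1] * CO2_PER_C))

            for pool, area in state.pool_areas().items():
                region_land_rows.append((rid, int(year), pool, area))

    # manufacturing emissions from annual newcomers, then assemble ledgers
    region_components: dict[str, EmissionComponents] = {}
    for region in fixtures.regions:
        rid = region.region_id
        traj = fixtures.population[rid]
        urban_on_grid = np.interp(years, traj.years, traj.urban)
        newcomers = np.diff(urban_on_grid, prepend=urban_on_grid[0])
        b1, b2 = manufacturing_emissions(newcomers, pr, materials)
        fl = fluxes[rid]
        region_components[rid] = assemble_components(
            years=years,
            clearing=fl["clearing"], degradation=fl["degradation"],
            harvest_booking=fl["booking"], regrowth=fl["regrowth"],
            storage_credit=fl["credit"], decay_release=fl["release"],
            b1=b1, b2=b2,
        )

    components = EmissionComponents.sum(list(region_components.values()))
    land_df = pd.DataFrame(region_land_rows,
                           columns=["region_id", "year", "pool", "area_mha"])
    harvest_df = pd.DataFrame(
        harvest_rows,
        columns=["region_id", "year", "source_pool", "harvest_mtc",
                 "cleared_mha"])
    hwp_df = pd.DataFrame(
        hwp_rows,
        columns=["region_id", "year", "product", "stock_mtc", "inflow_mtc",
                 "release_mtco2"])
    return ScenarioResult(
        config=config, components=components,
        region_components=region_components, schedules=schedules,
        land=land_df, harvest=harvest_df, hwp=hwp_df, reroutes=reroutes,
        provenance={"config_digest": config.digest(),
                    "fixture_seed": fixtures.seed, "ssp": fixtures.ssp},
    )


# --------------------------------------------------------------------------
# matrix
# --------------------------------------------------------------------------
def run_matrix(
    fixtures_by_ssp: dict[str, Fixtures],
    scenarios: tuple[str, ...] = ("BAU", "10pc", "50pc", "90pc"),
    base_config: ScenarioConfig | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], ScenarioResult]]:
    """Run the scenario x SSP matrix; BAU is the in-SSP differencing baseline.

    Returns (summary frame with one row per run, results keyed by
    (scenario, ssp)).
    """
    from .ledger import annualize, percent_saving, scenario_saving

    if "BAU" not in scenarios:
        raise ValueError("the matrix needs a BAU run per SSP as baseline")
    base = base_config or ScenarioConfig()
    results: dict[tuple[str, str], ScenarioResult] = {}
    rows: list[dict] = []
    for ssp, fixtures in fixtures_by_ssp.items():
        per_ssp: dict[str, ScenarioResult] = {}
        for scenario in scenarios:
            cfg = base.replace(scenario=scenario, ssp=ssp, seed=fixtures.seed)
            per_ssp[scenario] = run_scenario(cfg, fixtures)
            results[(scenario, ssp)] = per_ssp[scenario]
        c_bau = per_ssp["BAU"].summary_row()["c_cum_gt"]
        horizon = base.end_year - base.start_year
        for scenario in scenarios:
            row = per_ssp[scenario].summary_row()
            saving = scenario_saving(c_bau, row["c_cum_gt"])
            row["saving_gt"] = saving
            row["percent_saving"] = percent_saving(saving, c_bau) \
                if c_bau != 0 else 0
            row["annualized_gt_yr"] = annualize(saving, horizon)
            rows.append(row)
    return pd.DataFrame(rows), results


# --------------------------------------------------------------------------
# reporting
# --------------------------------------------------------------------------
def write_report(results: dict[tuple[str, str], ScenarioResult],
                 summary: pd.DataFrame, outdir: str | Path,
                 plots: bool = False) -> list[Path]:
    """Write all run tables plus the summary; optionally figures."""
    if not results:
        raise ValueError("no results to report")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, index=False)
        written.append(path)

    emissions = pd.concat([r.emissions_frame() for r in results.values()],
                          ignore_index=True)
    save(emissions, "emissions.csv")
    save(summary, "summary.csv")

    def tagged(getter) -> pd.DataFrame:
        frames = []
        for (scenario, ssp), r in results.items():
            df = getter(r).copy()
            df.insert(0, "ssp", ssp)
            df.insert(0, "scenario", scenario)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    save(tagged(lambda r: r.land), "land.csv")
    save(tagged(lambda r: r.harvest), "harvest.csv")
    save(tagged(lambda r: r.hwp), "hwp.csv")
    save(tagged(lambda r: pd.concat(
        [s.to_frame() for s in r.schedules.values()], ignore_index=True)),
        "demand.csv")

    if plots:
        written.extend(_write_plots(results, outdir))
    return written


def _write_plots(results, outdir: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    ssps = sorted({ssp for (_, ssp) in results})
    for ssp in ssps:
        fig, axes = plt.subplots(1, 2, figsize=(11, 4))
        for (scenario, s), r in results.items():
            if s != ssp:
                continue
            plant = (r.land[r.land.pool == "plantation"]
                     .groupby("year").area_mha.sum())
            axes[0].plot(plant.index, plant.values, label=scenario)
            axes[1].plot(r.years, r.components.cumulative("c"),
                         label=scenario)
        axes[0].set(title=f"Global plantation area ({ssp})",
                    xlabel="year", ylabel="Mha")
        axes[1].set(title=f"Overall cumulative emissions ({ssp})",
                    xlabel="year", ylabel="Gt CO2")
        for ax in axes:
            ax.legend()
        fig.tight_layout()
        path = outdir / f"figures_{ssp}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    return written
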