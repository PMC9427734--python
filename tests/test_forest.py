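import numpy as np
import pytest

import woodcarbon as wc
from woodcarbon import GrowthCurve, InfeasibleDemand, LandState
from woodcarbon.forest import AgeClassForest

PLANT_CURVE = GrowthCurve(100, 0.05, 2)   # rotation 15 under CAI
NAT_CURVE = GrowthCurve(130, 0.03, 2.5)
OTHER_CURVE = GrowthCurve(8, 0.1, 1.5)


def make_state(plantation=None, secondary=None, primary=None, other=None,
               protected_secondary=None, rotation=15) -> LandState:
    """Toy single-region land state from {age: area} cohort dicts."""
    def pool(name, curve, cohorts, protected=None):
        f = AgeClassForest(name, curve)
        for age, area in (cohorts or {}).items():
            f.add_area(area, age=age)
        for age, area in (protected or {}).items():
            f.add_area(area, age=age, protected=True)
        return f

    return LandState(
        region_id="TOY", year=2030, cropland=10.0, pasture=5.0,
        primary=pool("primary", NAT_CURVE, primary),
        secondary=pool("secondary", NAT_CURVE, secondary,
                       protected_secondary),
        plantation=pool("plantation", PLANT_CURVE, plantation),
        other=pool("other", OTHER_CURVE, other),
        rotation=rotation,
    )


def brute_force_waterfall(sources, demand):
    """Oracle: fill demand from (pool, age, area, density) cohorts in order,
    oldest cohorts first within each pool."""
    alloc: dict[str, float] = {}
    for pool, cohorts in sources:
        for age, area, dens in sorted(cohorts, reverse=True):
            if demand <= 1e-12 or dens <= 0:
                continue
            take = min(area * dens, demand)
            alloc[pool] = alloc.get(pool, 0.0) + take
            demand -= take
    return alloc


class TestHarvest:
    def test_zero_demand_leaves_state_unchanged(self):
        state = make_state(plantation={20: 1.0}, secondary={80: 5.0})
        before = state.total_area
        report = wc.harvest(state, 0.0, 0.0, 0.0)
        assert report.total_harvest == 0.0
        assert state.total_area == pytest.approx(before, rel=1e-12)

    def test_plantation_covers_demand_exactly(self):
        area = 1.0
        stock = area * PLANT_CURVE.density(20)
        state = make_state(plantation={20: area}, secondary={80: 50.0})
        report = wc.harvest(state, stock, 0.0, 0.0)
        assert report.harvest_by_pool.get("secondary", 0.0) == 0.0
        assert report.harvest_by_pool["plantation"] == pytest.approx(stock)
        # harvested plantation area is replanted at age 0
        assert report.replanted_area == pytest.approx(area)
        assert state.plantation.areas[0] == pytest.approx(area)

    def test_overflow_goes_to_secondary(self):
        stock = 1.0 * PLANT_CURVE.density(20)
        state = make_state(plantation={20: 1.0}, secondary={80: 50.0})
        report = wc.harvest(state, stock + 5.0, 0.0, 0.0)
        assert report.harvest_by_pool["secondary"] == pytest.approx(5.0)

    def test_matches_brute_force_waterfall(self):
        state = make_state(plantation={20: 0.6, 30: 0.4, 5: 2.0},
                           secondary={60: 1.5, 90: 0.5}, primary={160: 1.0})
        demand = 60.0
        report = wc.harvest(state, demand, 0.0, 0.0)
        oracle = brute_force_waterfall(
            [
                ("plantation", [(a, ar, PLANT_CURVE.density(a))
                                for a, ar in ((20, 0.6), (30, 0.4))]),
                ("secondary", [(a, ar, NAT_CURVE.density(a))
                               for a, ar in ((60, 1.5), (90, 0.5))]),
                ("primary", [(160, 1.0, NAT_CURVE.density(160))]),
            ],
            demand,
        )
        assert report.harvest_by_pool == pytest.approx(oracle)
        assert report.total_harvest == pytest.approx(demand)

    def test_immature_plantations_are_locked(self):
        # all plantation cohorts below rotation age: industrial demand must
        # fall through to secondary forest
        state = make_state(plantation={5: 10.0}, secondary={80: 50.0})
        immature = state.plantation.areas.copy()
        report = wc.harvest(state, 10.0, 0.0, 0.0)
        assert "plantation" not in report.harvest_by_pool
        # (replanting adds nothing because nothing was cut)
        assert np.array_equal(state.plantation.areas, immature)

    def test_woodfuel_prefers_other_land(self):
        state = make_state(other={160: 10.0}, secondary={80: 50.0})
        report = wc.harvest(state, 0.0, 0.0, 5.0)
        assert report.harvest_by_pool["other"] == pytest.approx(5.0)
        assert "secondary" not in report.harvest_by_pool

    def test_other_land_never_supplies_industrial_wood(self):
        state = make_state(other={160: 100.0}, secondary={80: 1.0})
        stock = 1.0 * NAT_CURVE.density(80)
        with pytest.raises(InfeasibleDemand):
            wc.harvest(state, stock + 50.0, 0.0, 0.0)

    def test_protected_area_never_harvested(self):
        state = make_state(secondary={80: 1.0},
                           protected_secondary={80: 100.0})
        protected_before = state.secondary.protected.copy()
        report = wc.harvest(state, 0.5 * NAT_CURVE.density(80), 0.0, 0.0)
        assert report.total_harvest > 0
        assert np.array_equal(state.secondary.protected, protected_before)

    def test_infeasible_demand_names_region_and_year(self):
        state = make_state(secondary={80: 0.01})
        with pytest.raises(InfeasibleDemand, match="TOY.*2030"):
            wc.harvest(state, 1e4, 0.0, 0.0)

    def test_harvest_conserves_land_area(self):
        state = make_state(plantation={20: 1.0}, secondary={80: 5.0},
                           other={160: 3.0})
        before = state.total_area
        wc.harvest(state, 30.0, 5.0, 2.0)
        assert state.total_area == pytest.approx(before, rel=1e-12)


class TestEstablishment:
    def test_zero_demand_is_noop(self):
        state = make_state(other={160: 10.0})
        before = state.total_area
        established, emissions, short = wc.establish_plantations(0.0, state)
        assert (established, emissions, short) == (0.0, 0.0, 0.0)
        assert state.total_area == pytest.approx(before)

    def test_area_is_demand_over_rotation_density(self):
        state = make_state(other={160: 10.0})
        demand = 10.0
        established, _, short = wc.establish_plantations(demand, state)
        assert established == pytest.approx(
            demand / PLANT_CURVE.density(15))
        assert short == 0.0
        assert state.plantation.areas[0] == pytest.approx(established)

    def test_carbon_free_land_clears_for_free(self):
        # other land at age 0 has zero standing carbon
        state = make_state(other={0: 10.0})
        _, emissions, _ = wc.establish_plantations(5.0, state)
        assert emissions == 0.0

    def test_clearing_emissions_track_standing_carbon(self):
        state = make_state(other={160: 10.0})
        established, emissions, _ = wc.establish_plantations(5.0, state)
        expected = established * OTHER_CURVE.density(160) * 44 / 12
        assert emissions == pytest.approx(expected)

    def test_shortfall_reported_when_land_runs_out(self):
        state = make_state(other={160: 0.001})
        demand = 100.0
        established, _, short = wc.establish_plantations(
            demand, state, priority=("other",))
        assert established == pytest.approx(0.001)
        assert short == pytest.approx(
            demand - 0.001 * PLANT_CURVE.density(15))

    def test_priority_other_before_secondary(self):
        state = make_state(other={160: 0.1}, secondary={80: 10.0})
        before_secondary = state.secondary.total_area
        wc.establish_plantations(0.1 * PLANT_CURVE.density(15), state)
        # fits on other land alone
        assert state.secondary.total_area == pytest.approx(before_secondary)

    def test_conserves_land_area(self):
        state = make_state(other={160: 10.0}, secondary={80: 10.0})
        before = state.total_area
        wc.establish_plantations(50.0, state)
        assert state.total_area == pytest.approx(before, rel=1e-12)


class TestRegrowthAndDegradation:
    def test_uptake_matches_cohort_growth(self):
        state = make_state(secondary={40: 1.0})
        expected_c = 1.0 * (NAT_CURVE.density(41) - NAT_CURVE.density(40))
        uptake = wc.regrowth_uptake(state)
        assert uptake == pytest.approx(-expected_c * 44 / 12)
        assert uptake <= 0

    def test_co2_scaling_of_five_tonne_increment(self):
        # 5 tC/ha over 1 Mha is 5 MtC, i.e. 18.33 MtCO2
        assert wc.co2_from_c(5.0) == pytest.approx(18.3333, abs=1e-4)

    def test_saturated_forest_takes_up_nothing(self):
        state = make_state(primary={160: 100.0})
        assert wc.regrowth_uptake(state) == pytest.approx(0.0, abs=1e-6)

    def test_ageing_advances_year_and_conserves_area(self):
        state = make_state(secondary={40: 1.0}, other={10: 2.0})
        before = state.total_area
        wc.regrowth_uptake(state)
        assert state.year == 2031
        assert state.total_area == pytest.approx(before, rel=1e-12)

    def test_degradation_zero_rate(self):
        state = make_state(secondary={80: 10.0})
        assert wc.degradation_emissions(state, 0.0) == 0.0

    def test_degradation_fraction_of_unprotected_stock(self):
        area = 100.0 / NAT_CURVE.density(160)   # 100 MtC standing
        state = make_state(secondary={160: area})
        emission = wc.degradation_emissions(state, 0.001)
        assert emission == pytest.approx(0.1 * 44 / 12, rel=1e-9)
        assert emission == pytest.approx(0.3667, abs=1e-4)

    def test_protected_stock_never_degrades(self):
        state = make_state(protected_secondary={160: 50.0})
        assert wc.degradation_emissions(state, 0.01) == 0.0

    def test_degradation_conserves_land(self):
        state = make_state(secondary={160: 5.0}, primary={160: 5.0})
        before = state.total_area
        wc.degradation_emissions(state, 0.01)
        assert state.total_area == pytest.approx(before, rel=1e-12)
        # degraded area re-enters secondary at age 0
        assert state.secondary.areas[0] > 0


class TestInitialization:
    def test_primary_starts_in_highest_age_class(self, fixtures_ssp2):
        region = fixtures_ssp2.regions.regions[0]
        params = fixtures_ssp2.params[region.region_id]
        state = wc.init_land_state(region, params)
        total = state.primary.areas + state.primary.protected
        assert total[:-1].sum() == 0.0
        assert total[-1] == pytest.approx(params.primary_forest)

    def test_initial_area_balance(self, fixtures_ssp2):
        for region in fixtures_ssp2.regions:
            params = fixtures_ssp2.params[region.region_id]
            state = wc.init_land_state(region, params)
            assert state.total_area == pytest.approx(region.total_land,
                                                     rel=1e-9)

    def test_protection_share_applied(self, fixtures_ssp2):
        region = fixtures_ssp2.regions.regions[0]
        params = fixtures_ssp2.params[region.region_id]
        state = wc.init_land_state(region, params)
        share = region.protection_share
        assert state.secondary.protected_area == pytest.approx(
            share * params.secondary_forest, rel=1e-9)
        assert state.plantation.protected_area == 0.0
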