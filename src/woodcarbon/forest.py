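"""Age-structured forest pools and land transitions.

Each forest pool (primary, secondary, plantation, other land) carries area
per one-year age cohort; carbon density per cohort comes from the pool's
growth curve, so pool carbon is ``sum(area_a * density(a))``.  Five-year
age-class aggregation is a reporting view; simulation is annual.

Rules of the land system:

* protected areas (a fixed share of natural forest and other land) grow and
  age but are never harvested, degraded or converted;
* primary forest starts in the highest age class (at the asymptotic
  density); harvested or degraded natural forest re-enters *secondary*
  forest at age 0;
* plantations are harvestable only at or above the rotation age, and
  harvested plantation area is replanted (re-enters age 0);
* other land supplies wood fuel only;
* total land area per region is conserved by every operation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import CO2_PER_C
from .growth import GrowthCurve, rotation_length
from .synthetic import Region, RegionParams


class InfeasibleDemand(RuntimeError):
    """Raised when demand exceeds all harvestable carbon in a region-year."""

    def __init__(self, region_id: str, year: int, shortfall: float):
        super().__init__(
            f"harvest demand infeasible in {region_id}, year {year}: "
            f"{shortfall:.3f} MtC unserved"
        )
        self.region_id = region_id
        self.year = year
        self.shortfall = shortfall


class AgeClassForest:
    """One forest pool: area (Mha) per one-year age cohort."""

    def __init__(self, pool: str, curve: GrowthCurve, max_age: int = 160):
        self.pool = pool
        self.curve = curve
        self.max_age = max_age
        self.areas = np.zeros(max_age + 1)       # harvestable cohorts
        self.protected = np.zeros(max_age + 1)   # never harvested
        self._density = curve.density(np.arange(max_age + 1).astype(float))
        self._density_next = curve.density(
            np.minimum(np.arange(max_age + 1) + 1, max_age).astype(float)
        )

    # ------------------------------------------------------------ queries
    @property
    def total_area(self) -> float:
        return float(self.areas.sum() + self.protected.sum())

    @property
    def protected_area(self) -> float:
        return float(self.protected.sum())

    def carbon_stock(self, include_protected: bool = True) -> float:
        """Total carbon (MtC)."""
        stock = float(self.areas @ self._density)
        if include_protected:
            stock += float(self.protected @ self._density)
        return stock

    def harvestable_carbon(self, min_age: int = 0) -> float:
        return float(self.areas[min_age:] @ self._density[min_age:])

    def class_areas(self, width: int = 5) -> dict[tuple[int, int], float]:
        """Aggregate areas into age classes of the given width (reporting)."""
        out: dict[tuple[int, int], float] = {}
        total = self.areas + self.protected
        for lo in range(0, self.max_age + 1, width):
            hi = min(lo + width - 1, self.max_age)
            out[(lo, hi)] = float(total[lo:hi + 1].sum())
        return out

    # --------------------------------------------------------- mutations
    def add_area(self, area: float, age: int = 0, protected: bool = False) -> None:
        if area < 0:
            raise ValueError("area must be >= 0")
        target = self.protected if protected else self.areas
        target[age] += area

    def harvest_carbon(self, amount: float, min_age: int = 0
                       ) -> tuple[float, float]:
        """Remove up to ``amount`` MtC, oldest (densest) cohorts first.

        Returns (carbon removed MtC, area cleared Mha).  The cleared area is
        *removed* from the pool; the caller routes it to its destination.
        Protected cohorts are untouched.
        """
        if amount <= 0:
            return 0.0, 0.0
        taken_c = 0.0
        taken_a = 0.0
        for age in range(self.max_age, min_age - 1, -1):
            if taken_c >= amount - 1e-12:
                break
            a = self.areas[age]
            d = self._density[age]
            if a <= 0 or d <= 0:
                continue
            avail = a * d
            take_c = min(avail, amount - taken_c)
            take_a = take_c / d
            self.areas[age] -= take_a
            taken_c += take_c
            taken_a += take_a
        return taken_c, taken_a

    def clear_area(self, area: float) -> tuple[float, float]:
        """Remove up to ``area`` Mha for land conversion, youngest first.

        Clearing for conversion takes the lowest-carbon cohorts first (the
        cheap land), mirroring cost minimization.  Returns (area removed,
        carbon cleared MtC).
        """
        if area <= 0:
            return 0.0, 0.0
        taken_a = 0.0
        cleared_c = 0.0
        for age in range(0, self.max_age + 1):
            if taken_a >= area - 1e-12:
                break
            a = self.areas[age]
            if a <= 0:
                continue
            take = min(a, area - taken_a)
            self.areas[age] -= take
            taken_a += take
            cleared_c += take * self._density[age]
        return taken_a, cleared_c

    def advance(self, dt: int = 1) -> float:
        """Age all cohorts by ``dt`` years; return growth uptake (MtC, >= 0).

        Uptake accrues to both harvestable and protected cohorts; the top
        cohort accumulates (already at the asymptote).
        """
        uptake = 0.0
        for _ in range(dt):
            growth = self._density_next - self._density
            uptake += float((self.areas + self.protected) @ growth)
            for arr_name in ("areas", "protected"):
                arr = getattr(self, arr_name)
                shifted = np.zeros_like(arr)
                shifted[1:] = arr[:-1]
                shifted[-1] += arr[-1]
                setattr(self, arr_name, shifted)
        return uptake


# --------------------------------------------------------------------------
# land state
# --------------------------------------------------------------------------
@dataclass
class LandState:
    """All land pools of one region at one point in time."""

    region_id: str
    year: int
    cropland: float
    pasture: float
    primary: AgeClassForest
    secondary: AgeClassForest
    plantation: AgeClassForest
    other: AgeClassForest
    rotation: int
    cropland_density: float = 5.0
    pasture_density: float = 7.0

    @property
    def total_area(self) -> float:
        return (self.cropland + self.pasture + self.primary.total_area
                + self.secondary.total_area + self.plantation.total_area
                + self.other.total_area)

    def pool_areas(self) -> dict[str, float]:
        return {
            "cropland": self.cropland,
            "pasture": self.pasture,
            "primary_forest": self.primary.total_area,
            "secondary_forest": self.secondary.total_area,
            "plantation": self.plantation.total_area,
            "other_land": self.other.total_area,
        }

    def assert_no_negative(self) -> None:
        for pool in (self.primary, self.secondary, self.plantation, self.other):
            if np.any(pool.areas < -1e-9) or np.any(pool.protected < -1e-9):
                raise AssertionError(f"negative area in {pool.pool}")


def init_land_state(region: Region, params: RegionParams,
                    rotation_rule: str = "CAI", max_age: int = 160,
                    secondary_age_range: tuple[int, int] = (40, 120),
                    ) -> LandState:
    """Initialize the 2020 land state of a region.

    Primary forest sits entirely in the highest age class; secondary forest
    is spread uniformly over a mature age window; other land sits at its
    (low) asymptotic density; plantations are spread uniformly over one
    rotation so a cohort matures every year.  The protected share applies to
    natural forest and other land.
    """
    p = region.protection_share
    rot = rotation_length(params.plantation_curve, rotation_rule)

    primary = AgeClassForest("primary", params.natural_curve, max_age)
    primary.add_area(params.primary_forest * (1 - p), age=max_age)
    primary.add_area(params.primary_forest * p, age=max_age, protected=True)

    secondary = AgeClassForest("secondary", params.natural_curve, max_age)
    lo, hi = secondary_age_range
    ages = np.arange(lo, hi + 1)
    per_age = params.secondary_forest / ages.size
    for age in ages:
        secondary.add_area(per_age * (1 - p), age=int(age))
        secondary.add_area(per_age * p, age=int(age), protected=True)

    other = AgeClassForest("other", params.other_curve, max_age)
    other.add_area(params.other_land * (1 - p), age=max_age)
    other.add_area(params.other_land * p, age=max_age, protected=True)

    plantation = AgeClassForest("plantation", params.plantation_curve, max_age)
    plant_ages = np.arange(0, rot + 1)
    per_age = params.plantation / plant_ages.size
    for age in plant_ages:
        plantation.add_area(per_age, age=int(age))

    return LandState(
        region_id=region.region_id, year=2020,
        cropland=params.cropland, pasture=params.pasture,
        primary=primary, secondary=secondary,
        plantation=plantation, other=other, rotation=rot,
        cropland_density=params.cropland_density,
        pasture_density=params.pasture_density,
    )


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------
@dataclass
class HarvestReport:
    """Outcome of one region-year harvest."""

    region_id: str
    year: int
    harvest_by_pool: dict[str, float] = field(default_factory=dict)   # MtC
    cleared_by_pool: dict[str, float] = field(default_factory=dict)   # Mha
    replanted_area: float = 0.0       # Mha of plantation re-entering age 0
    shortfall_mtc: float = 0.0        # demand rerouted/unserved

    @property
    def total_harvest(self) -> float:
        return float(sum(self.harvest_by_pool.values()))


def establish_plantations(demand_mtc: float, state: LandState,
                          priority: tuple[str, ...] = ("other", "secondary"),
                          ) -> tuple[float, float, float]:
    """Establish plantation area to serve ``demand_mtc`` at maturity.

    Area = demand / density(rotation), taken from unprotected pools in
    priority order (other land first by default).  Returns
    (established area Mha, clearing emissions MtCO2, shortfall MtC that
    could not be provisioned and must come from natural-forest harvest).
    """
    if demand_mtc <= 0:
        return 0.0, 0.0, 0.0
    density_rot = state.plantation.curve.density(float(state.rotation))
    needed_area = demand_mtc / density_rot

    pools = {"other": state.other, "secondary": state.secondary,
             "primary": state.primary}
    established = 0.0
    clearing_c = 0.0
    for name in priority:
        if established >= needed_area - 1e-12:
            break
        got_a, got_c = pools[name].clear_area(needed_area - established)
        established += got_a
        clearing_c += got_c
    if established > 0:
        state.plantation.add_area(established, age=0)
    shortfall_area = max(0.0, needed_area - established)
    shortfall_mtc = shortfall_area * density_rot
    return established, clearing_c * CO2_PER_C, shortfall_mtc


def harvest(state: LandState, engineered_mtc: float, roundwood_mtc: float,
            woodfuel_mtc: float) -> HarvestReport:
    """Serve one year's harvest demand from the region's pools.

    Industrial wood (engineered + roundwood) is sourced from mature
    plantations first, then unprotected secondary, then unprotected primary
    forest.  Wood fuel is sourced from unprotected other land first, then
    the same forest waterfall.  Harvested natural forest moves to secondary
    age 0; harvested plantations are replanted; harvested other land
    re-enters other land at age 0.
    """
    report = HarvestReport(state.region_id, state.year)
    taken = {p: 0.0 for p in ("plantation", "secondary", "primary", "other")}
    cleared = dict(taken)

    def draw(pool: AgeClassForest, name: str, amount: float,
             min_age: int = 0) -> float:
        got_c, got_a = pool.harvest_carbon(amount, min_age=min_age)
        taken[name] += got_c
        cleared[name] += got_a
        return got_c

    # industrial wood waterfall
    industrial = engineered_mtc + roundwood_mtc
    remaining = industrial
    remaining -= draw(state.plantation, "plantation", remaining,
                      min_age=state.rotation)
    remaining -= draw(state.secondary, "secondary", remaining)
    remaining -= draw(state.primary, "primary", remaining)
    unserved_industrial = max(0.0, remaining)

    # wood fuel: other land first, then forests, then mature plantations
    remaining = woodfuel_mtc
    remaining -= draw(state.other, "other", remaining)
    remaining -= draw(state.secondary, "secondary", remaining)
    remaining -= draw(state.primary, "primary", remaining)
    remaining -= draw(state.plantation, "plantation", remaining,
                      min_age=state.rotation)
    unserved = unserved_industrial + max(0.0, remaining)
    if unserved > 1e-6:
        raise InfeasibleDemand(state.region_id, state.year, unserved)

    # route cleared areas: replant plantations, natural -> secondary age 0,
    # other land regrows in place from age 0
    state.plantation.add_area(cleared["plantation"], age=0)
    state.secondary.add_area(cleared["secondary"] + cleared["primary"], age=0)
    state.other.add_area(cleared["other"], age=0)

    report.harvest_by_pool = {k: v for k, v in taken.items() if v > 0}
    report.cleared_by_pool = {k: v for k, v in cleared.items() if v > 0}
    report.replanted_area = cleared["plantation"]
    return report


def regrowth_uptake(state: LandState, dt: int = 1) -> float:
    """Advance all pools by ``dt`` years; return uptake flux (MtCO2, <= 0)."""
    uptake_c = 0.0
    for pool in (state.primary, state.secondary, state.plantation, state.other):
        uptake_c += pool.advance(dt)
    state.year += dt
    return -uptake_c * CO2_PER_C


def degradation_emissions(state: LandState, rate: float) -> float:
    """Degrade unprotected natural forest at a constant annual rate.

    A fraction ``rate`` of every unprotected primary/secondary cohort is
    cut back to secondary age 0; the lost carbon is returned as a positive
    emission (MtCO2/yr) for the gross land-use-change ledger.
    """
    if not 0.0 <= rate <= 0.05:
        raise ValueError("degradation rate must be in [0, 0.05]")
    if rate == 0.0:
        return 0.0
    lost_c = 0.0
    moved_area = 0.0
    for pool in (state.primary, state.secondary):
        degraded = pool.areas * rate
        lost_c += float(degraded @ pool._density)
        moved_area += float(degraded.sum())
        pool.areas -= degraded
    state.secondary.add_area(moved_area, age=0)
    return lost_c * CO2_PER_C
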