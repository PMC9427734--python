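"""Seeded synthetic regional fixtures: regions, populations, parameters.

The generator emulates the statistical structure the scenario analysis
assumes, so every downstream stage is testable without external downloads:

* a set of world regions partitioning ~13,000 Mha of land, each with a
  protected share of natural vegetation;
* urban/rural population trajectories 2020-2100 whose *global* urban share
  in 2100 is calibrated exactly to the SSP anchors (SSP1 92%, SSP2 80%,
  SSP3 58%), with per-region logistic urbanization peaking in a randomized
  year and held flat afterwards;
* parameter tables whose 2020 global land pools reproduce the anchor areas
  (plantations 137 Mha, cropland 1595 Mha, natural forest 3629 Mha).

All randomness flows from a single master seed through named
``numpy.random.SeedSequence`` streams, so identical inputs give
bit-identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import GeneratorConfig, SSP_LABELS
from .growth import GrowthCurve

# stream ids for seed splitting (documented scheme: SeedSequence([seed, id]))
_STREAM_REGIONS = 101
_STREAM_POPULATION = 202
_STREAM_PARAMETERS = 303


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class Region:
    """One synthetic world region."""

    region_id: str
    name: str
    total_land: float          # Mha
    protection_share: float    # fraction of natural forest / other land protected

    def __post_init__(self) -> None:
        if not self.total_land > 0:
            raise ValueError("total_land must be > 0")
        if not 0.0 <= self.protection_share <= 1.0:
            raise ValueError("protection_share must be in [0, 1]")


@dataclass(frozen=True)
class RegionSet:
    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValueError("region_id must be unique within a RegionSet")

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def ids(self) -> list[str]:
        return [r.region_id for r in self.regions]

    @property
    def total_land(self) -> float:
        return float(sum(r.total_land for r in self.regions))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": [r.region_id for r in self.regions],
                "name": [r.name for r in self.regions],
                "total_land_mha": [r.total_land for r in self.regions],
                "protection_share": [r.protection_share for r in self.regions],
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegionSet":
        return cls(
            tuple(
                Region(row.region_id, row.name, float(row.total_land_mha),
                       float(row.protection_share))
                for row in df.itertuples()
            )
        )

    @classmethod
    def read_csv(cls, path: str | Path) -> "RegionSet":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class PopulationTrajectory:
    """Annual urban/rural headcounts (million persons) for one region."""

    region_id: str
    years: np.ndarray           # calendar years, annual
    urban: np.ndarray           # million persons
    rural: np.ndarray           # million persons
    peak_year: int              # year t* of maximal urban headcount

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.urban = np.asarray(self.urban, dtype=float)
        self.rural = np.asarray(self.rural, dtype=float)
        if np.any(self.urban < 0) or np.any(self.rural < 0):
            raise ValueError("headcounts must be >= 0")
        if not (self.years[0] <= self.peak_year <= self.years[-1]):
            raise ValueError("peak_year must lie within the covered years")

    def value_at(self, year: int, which: str = "urban") -> float:
        idx = int(np.flatnonzero(self.years == year)[0])
        return float(getattr(self, which)[idx])

    @property
    def total(self) -> np.ndarray:
        return self.urban + self.rural

    @property
    def urban_share(self) -> np.ndarray:
        tot = self.total
        with np.errstate(invalid="ignore", divide="ignore"):
            share = np.where(tot > 0, self.urban / np.where(tot > 0, tot, 1.0), 0.0)
        return share


@dataclass
class RegionParams:
    """Per-region fixture parameters."""

    region_id: str
    # initial land-pool areas (Mha); other_land closes the area balance
    cropland: float
    pasture: float
    primary_forest: float
    secondary_forest: float
    plantation: float
    other_land: float
    # growth curves
    plantation_curve: GrowthCurve
    natural_curve: GrowthCurve
    other_curve: GrowthCurve
    # vegetation carbon density of non-forest pools (tC/ha)
    cropland_density: float = 5.0
    pasture_density: float = 7.0
    # exogenous demand series (MtC/yr), aligned on ParameterSet.years
    roundwood: np.ndarray = field(default_factory=lambda: np.zeros(0))
    woodfuel: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def total_land(self) -> float:
        return (self.cropland + self.pasture + self.primary_forest
                + self.secondary_forest + self.plantation + self.other_land)


@dataclass
class ParameterSet:
    """Fixture parameters: per-region tables plus global scalars."""

    years: np.ndarray
    regions: dict[str, RegionParams]
    # global demand scalars
    wood_per_capita: float      # M_w_c, tDM/person
    carbon_wood_ratio: float    # CW, tC/tDM
    # building material masses per newly housed person and emission factors
    cement_per_capita: float = 10.0   # t/person
    steel_per_capita: float = 1.0     # t/person
    ef_wood: float = 0.45             # tCO2e/t
    ef_cement: float = 0.6            # tCO2e/t
    ef_steel: float = 1.85            # tCO2e/t

    def __getitem__(self, region_id: str) -> RegionParams:
        return self.regions[region_id]

    def global_pool(self, pool: str) -> float:
        return float(sum(getattr(p, pool) for p in self.regions.values()))

    # ------------------------------------------------------------------ io
    def to_frame(self) -> pd.DataFrame:
        rows: list[tuple[str, str, float, str]] = []

        def add(rid: str, name: str, value: float, unit: str) -> None:
            rows.append((rid, name, float(value), unit))

        for rid, p in self.regions.items():
            for pool in ("cropland", "pasture", "primary_forest",
                         "secondary_forest", "plantation", "other_land"):
                add(rid, pool, getattr(p, pool), "Mha")
            for label, curve in (("plantation", p.plantation_curve),
                                 ("natural", p.natural_curve),
                                 ("other", p.other_curve)):
                add(rid, f"{label}_curve_A", curve.A, "tC/ha")
                add(rid, f"{label}_curve_k", curve.k, "1/yr")
                add(rid, f"{label}_curve_b", curve.b, "1")
            add(rid, "cropland_density", p.cropland_density, "tC/ha")
            add(rid, "pasture_density", p.pasture_density, "tC/ha")
            for year, rw, wf in zip(self.years, p.roundwood, p.woodfuel):
                add(rid, f"roundwood_{year}", rw, "MtC/yr")
                add(rid, f"woodfuel_{year}", wf, "MtC/yr")
        for name, value, unit in (
            ("wood_per_capita", self.wood_per_capita, "tDM/person"),
            ("carbon_wood_ratio", self.carbon_wood_ratio, "tC/tDM"),
            ("cement_per_capita", self.cement_per_capita, "t/person"),
            ("steel_per_capita", self.steel_per_capita, "t/person"),
            ("ef_wood", self.ef_wood, "tCO2e/t"),
            ("ef_cement", self.ef_cement, "tCO2e/t"),
            ("ef_steel", self.ef_steel, "tCO2e/t"),
        ):
            add("GLOBAL", name, value, unit)
        return pd.DataFrame(rows, columns=["region_id", "parameter", "value", "unit"])

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ParameterSet":
        gl = df[df.region_id == "GLOBAL"].set_index("parameter")["value"]
        years = sorted(
            int(p.rsplit("_", 1)[1])
            for p in df.parameter.unique()
            if p.startswith("roundwood_")
        )
        years_arr = np.asarray(years, dtype=int)
        regions: dict[str, RegionParams] = {}
        for rid, sub in df[df.region_id != "GLOBAL"].groupby("region_id", sort=False):
            v = sub.set_index("parameter")["value"]
            curves = {
                label: GrowthCurve(v[f"{label}_curve_A"], v[f"{label}_curve_k"],
                                   v[f"{label}_curve_b"])
                for label in ("plantation", "natural", "other")
            }
            regions[rid] = RegionParams(
                region_id=rid,
                cropland=v["cropland"], pasture=v["pasture"],
                primary_forest=v["primary_forest"],
                secondary_forest=v["secondary_forest"],
                plantation=v["plantation"], other_land=v["other_land"],
                plantation_curve=curves["plantation"],
                natural_curve=curves["natural"], other_curve=curves["other"],
                cropland_density=v["cropland_density"],
                pasture_density=v["pasture_density"],
                roundwood=np.array([v[f"roundwood_{y}"] for y in years]),
                woodfuel=np.array([v[f"woodfuel_{y}"] for y in years]),
            )
        return cls(
            years=years_arr, regions=regions,
            wood_per_capita=gl["wood_per_capita"],
            carbon_wood_ratio=gl["carbon_wood_ratio"],
            cement_per_capita=gl["cement_per_capita"],
            steel_per_capita=gl["steel_per_capita"],
            ef_wood=gl["ef_wood"], ef_cement=gl["ef_cement"],
            ef_steel=gl["ef_steel"],
        )

    @classmethod
    def read_csv(cls, path: str | Path) -> "ParameterSet":
        return cls.from_frame(pd.read_csv(path))


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------
def generate_regions(n_regions: int, seed: int,
                     gen: GeneratorConfig | None = None) -> RegionSet:
    """Sample a set of regions partitioning the world land area."""
    gen = gen or GeneratorConfig()
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    rng = _rng(seed, _STREAM_REGIONS)
    if n_regions == 1:
        shares = np.array([1.0])
    else:
        shares = rng.dirichlet(np.full(n_regions, 3.0))
    lo, hi = gen.protection_range
    protection = rng.uniform(lo, hi, size=n_regions)
    regions = tuple(
        Region(
            region_id=f"R{i + 1:02d}",
            name=f"Region {i + 1:02d}",
            total_land=float(shares[i] * gen.world_land_mha),
            protection_share=float(protection[i]),
        )
        for i in range(n_regions)
    )
    return RegionSet(regions)


def population_weights(regions: RegionSet, seed: int) -> np.ndarray:
    """Dirichlet population weights per region (deterministic in seed)."""
    rng = _rng(seed, _STREAM_POPULATION)
    return rng.dirichlet(np.full(len(regions), 2.0))


def generate_population(
    regions: RegionSet,
    ssp: str,
    seed: int,
    gen: GeneratorConfig | None = None,
    pop_weights: np.ndarray | None = None,
) -> dict[str, PopulationTrajectory]:
    """Generate per-region urban/rural trajectories for one SSP.

    Urban headcount rises along a normalized logistic from the 2020 level to
    a per-region saturation level reached at a randomized peak year in
    [2040, 2090], then stays flat.  Saturation levels are allocated so the
    global urban share of population in 2100 equals the SSP anchor exactly.
    """
    gen = gen or GeneratorConfig()
    if ssp not in SSP_LABELS:
        raise ValueError(f"unknown SSP label {ssp!r}")
    rng = _rng(seed, _STREAM_POPULATION)
    n = len(regions)
    weights = rng.dirichlet(np.full(n, 2.0)) if pop_weights is None \
        else np.asarray(pop_weights, dtype=float)
    if weights.shape != (n,) or np.any(weights < 0):
        raise ValueError("pop_weights must be nonnegative with one entry per region")

    years = np.arange(2020, 2101)
    x = (years - 2020) / 80.0
    # smooth monotone global total population (million)
    total_global = gen.pop_2020_million + (
        gen.pop_2100_million[ssp] - gen.pop_2020_million
    ) * (3 * x**2 - 2 * x**3)

    urban_2020_global = gen.urban_share_2020 * gen.pop_2020_million
    urban_2100_global = gen.urban_share_2100[ssp] * total_global[-1]

    lo, hi = gen.peak_year_range
    peak_years = rng.integers(lo, hi + 1, size=n)
    steepness_scale = rng.uniform(8.0, 12.0, size=n)

    out: dict[str, PopulationTrajectory] = {}
    for i, region in enumerate(regions):
        w = weights[i]
        peak = int(peak_years[i])
        base = w * urban_2020_global
        sat = w * urban_2100_global
        span = peak - 2020
        a = steepness_scale[i] / span
        mid = 2020 + span / 2.0
        f = 1.0 / (1.0 + np.exp(-a * (years - mid)))
        g = (f - f[0]) / (f[years == peak][0] - f[0])
        g = np.clip(np.where(years >= peak, 1.0, g), 0.0, 1.0)
        urban = base + (sat - base) * g
        rural = w * total_global - urban
        if w == 0:
            urban = np.zeros_like(urban)
            rural = np.zeros_like(rural)
        out[region.region_id] = PopulationTrajectory(
            region_id=region.region_id, years=years,
            urban=urban, rural=np.maximum(rural, 0.0), peak_year=peak,
        )
    return out


def generate_parameters(regions: RegionSet, seed: int,
                        gen: GeneratorConfig | None = None) -> ParameterSet:
    """Sample per-region land pools, growth curves and exogenous demand.

    Named pools are allocated proportionally to regional land area with a
    mild lognormal jitter, renormalized so global sums scale with total land
    area; at the default 13,000 Mha they hit the 2020 anchors exactly.
    ``other_land`` closes each region's area balance.
    """
    gen = gen or GeneratorConfig()
    if len(regions) == 0:
        raise ValueError("RegionSet must be nonempty")
    rng = _rng(seed, _STREAM_PARAMETERS)
    n = len(regions)
    land = np.array([r.total_land for r in regions])
    world = land.sum()

    pools = {
        "plantation": gen.plantation_mha,
        "cropland": gen.cropland_mha,
        "primary_forest": gen.natural_forest_mha * gen.primary_fraction,
        "secondary_forest": gen.natural_forest_mha * (1 - gen.primary_fraction),
        "pasture": gen.pasture_mha,
    }
    alloc: dict[str, np.ndarray] = {}
    for pool, anchor in pools.items():
        fraction = anchor / gen.world_land_mha  # share of world land in this pool
        jitter = rng.lognormal(mean=0.0, sigma=0.12, size=n)
        w = land * jitter
        alloc[pool] = fraction * world * (w / w.sum())

    named = sum(alloc.values())
    other = land - named
    if np.any(other < 0):
        raise ValueError("land-pool jitter produced a negative residual pool")

    curve_A_plant = rng.uniform(80.0, 140.0, size=n)
    curve_k_plant = rng.uniform(0.045, 0.075, size=n)
    curve_A_nat = rng.uniform(100.0, 160.0, size=n)
    curve_k_nat = rng.uniform(0.02, 0.04, size=n)

    years = np.arange(2020, 2101)
    land_w = land / world
    cw = 0.476
    if gen.randomize_cw:
        cw = float(rng.uniform(0.476 - 0.04, 0.476 + 0.04))

    regions_params: dict[str, RegionParams] = {}
    for i, region in enumerate(regions):
        rid = region.region_id
        regions_params[rid] = RegionParams(
            region_id=rid,
            cropland=float(alloc["cropland"][i]),
            pasture=float(alloc["pasture"][i]),
            primary_forest=float(alloc["primary_forest"][i]),
            secondary_forest=float(alloc["secondary_forest"][i]),
            plantation=float(alloc["plantation"][i]),
            other_land=float(other[i]),
            plantation_curve=GrowthCurve(float(curve_A_plant[i]),
                                         float(curve_k_plant[i]), 2.0),
            natural_curve=GrowthCurve(float(curve_A_nat[i]),
                                      float(curve_k_nat[i]), 2.5),
            other_curve=GrowthCurve(8.0, 0.1, 1.5),
            roundwood=np.full(years.size, gen.roundwood_mtc * land_w[i]),
            woodfuel=np.full(years.size, gen.woodfuel_mtc * land_w[i]),
        )
    return ParameterSet(
        years=years, regions=regions_params,
        wood_per_capita=11.5, carbon_wood_ratio=cw,
    )


# --------------------------------------------------------------------------
# population CSV io
# --------------------------------------------------------------------------
def population_to_frame(trajs: dict[str, PopulationTrajectory]) -> pd.DataFrame:
    frames = [
        pd.DataFrame(
            {
                "region_id": t.region_id,
                "year": t.years,
                "urban_million": t.urban,
                "rural_million": t.rural,
                "peak_year": t.peak_year,
            }
        )
        for t in trajs.values()
    ]
    return pd.concat(frames, ignore_index=True)


def write_population_csv(trajs: dict[str, PopulationTrajectory],
                         path: str | Path) -> None:
    population_to_frame(trajs).to_csv(path, index=False)


def read_population_csv(path: str | Path) -> dict[str, PopulationTrajectory]:
    df = pd.read_csv(path)
    out: dict[str, PopulationTrajectory] = {}
    for rid, sub in df.groupby("region_id", sort=False):
        sub = sub.sort_values("year")
        out[rid] = PopulationTrajectory(
            region_id=rid,
            years=sub.year.to_numpy(),
            urban=sub.urban_million.to_numpy(),
            rural=sub.rural_million.to_numpy(),
            peak_year=int(sub.peak_year.iloc[0]),
        )
    return out
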