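"""Emission ledger: component bookkeeping and scenario comparisons.

Sign conventions of the land/products/manufacturing ledger (all MtCO2):

* gross land-use change (clearing for plantation establishment, natural
  forest degradation, and the booking of *all* harvested carbon, including
  wood fuel burned within the year) is positive;
* forest and other-land regrowth is negative;
* a.1 = gross + regrowth (land and forest management);
* a.2 = product-pool storage credit (negative; harvested carbon re-credited
  into the industrial-roundwood and engineered-wood pools after having been
  booked as emitted) plus decay releases (positive) — the three-step scheme
  that avoids double counting;
* a.3 = a.1 + a.2 (land-use change emissions);
* b.1 = engineered-wood manufacturing, b.2 = cement + steel manufacturing,
  b.3 = b.1 + b.2; c = a.3 + b.3 (overall).

Cumulative series are baselined at 2020 (zero there).  Reported percentages
round half-up to integers and annual rates half-up to two decimals, the
convention the headline numbers follow.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CO2_PER_C

COMPONENTS = ("gross_luc", "regrowth", "a1", "a2", "a3", "b1", "b2", "b3", "c")


@dataclass
class BuildingMaterialParams:
    """Per-capita material masses (t/person) and emission factors (tCO2e/t)."""

    wood_per_capita: float      # engineered wood, tDM/person
    cement_per_capita: float
    steel_per_capita: float
    ef_wood: float
    ef_cement: float
    ef_steel: float

    def __post_init__(self) -> None:
        for name in ("wood_per_capita", "cement_per_capita", "steel_per_capita",
                     "ef_wood", "ef_cement", "ef_steel"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def manufacturing_emissions(newcomers_million, pr: float,
                            materials: BuildingMaterialParams
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Manufacturing emissions (b.1, b.2) in MtCO2/yr.

    A fraction PR of new urban dwellers is housed in engineered-wood
    buildings (driving b.1), the rest in conventional cement/steel buildings
    (driving b.2).  Emission factors are static: no decarbonization pathway
    for material production is assumed.
    """
    if not 0.0 <= pr <= 1.0:
        raise ValueError("PR must be in [0, 1]")
    new = np.maximum(np.asarray(newcomers_million, dtype=float), 0.0)
    b1 = pr * new * materials.wood_per_capita * materials.ef_wood
    b2 = (1.0 - pr) * new * (
        materials.cement_per_capita * materials.ef_cement
        + materials.steel_per_capita * materials.ef_steel
    )
    return b1, b2


@dataclass
class EmissionComponents:
    """Annual emission components (MtCO2/yr) on a common year grid.

    The first year of the grid (2020) carries zero flows so that cumulative
    series are baselined at zero in 2020.
    """

    years: np.ndarray
    gross_luc: np.ndarray
    regrowth: np.ndarray
    a2: np.ndarray
    b1: np.ndarray
    b2: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.years)
        for name in ("gross_luc", "regrowth", "a2", "b1", "b2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must align with years")
            setattr(self, name, arr)
        if np.any(self.gross_luc < -1e-9):
            raise ValueError("gross land-use change emissions must be >= 0")
        if np.any(self.regrowth > 1e-9):
            raise ValueError("regrowth must be <= 0")

    @property
    def a1(self) -> np.ndarray:
        return self.gross_luc + self.regrowth

    @property
    def a3(self) -> np.ndarray:
        return self.a1 + self.a2

    @property
    def b3(self) -> np.ndarray:
        return self.b1 + self.b2

    @property
    def c(self) -> np.ndarray:
        return self.a3 + self.b3

    def annual(self, component: str) -> np.ndarray:
        if component not in COMPONENTS:
            raise KeyError(component)
        return getattr(self, component)

    def cumulative(self, component: str) -> np.ndarray:
        """Cumulative series in Gt CO2, zero at 2020."""
        return np.cumsum(self.annual(component)) / 1000.0

    def to_frame(self, scenario: str, ssp: str,
                 region_id: str = "GLOBAL") -> pd.DataFrame:
        frames = []
        for comp in COMPONENTS:
            frames.append(pd.DataFrame({
                "scenario": scenario, "ssp": ssp, "region_id": region_id,
                "year": self.years, "component": comp,
                "annual_mtco2": self.annual(comp),
                "cumulative_gtco2": self.cumulative(comp),
            }))
        return pd.concat(frames, ignore_index=True)

    @staticmethod
    def sum(parts: list["EmissionComponents"]) -> "EmissionComponents":
        years = parts[0].years
        for p in parts[1:]:
            if not np.array_equal(p.years, years):
                raise ValueError("components must share the year grid")
        return EmissionComponents(
            years=years,
            gross_luc=np.sum([p.gross_luc for p in parts], axis=0),
            regrowth=np.sum([p.regrowth for p in parts], axis=0),
            a2=np.sum([p.a2 for p in parts], axis=0),
            b1=np.sum([p.b1 for p in parts], axis=0),
            b2=np.sum([p.b2 for p in parts], axis=0),
        )


def assemble_components(
    years: np.ndarray,
    clearing: np.ndarray,
    degradation: np.ndarray,
    harvest_booking: np.ndarray,
    regrowth: np.ndarray,
    storage_credit: np.ndarray,
    decay_release: np.ndarray,
    b1: np.ndarray,
    b2: np.ndarray,
) -> EmissionComponents:
    """Assemble the ledger from its raw flux series (all MtCO2/yr).

    ``harvest_booking`` is all harvested carbon booked as emitted (step 1),
    ``storage_credit`` the negative re-credit of pooled product carbon
    (step 2), and ``decay_release`` the positive decay outflow (step 3).
    """
    years = np.asarray(years)
    arrays = [np.asarray(a, dtype=float) for a in
              (clearing, degradation, harvest_booking, regrowth,
               storage_credit, decay_release, b1, b2)]
    if any(a.shape != years.shape for a in arrays):
        raise ValueError("all flux series must align with the year grid")
    (clearing, degradation, harvest_booking, regrowth,
     storage_credit, decay_release, b1, b2) = arrays
    if np.any(storage_credit > 1e-9):
        raise ValueError("storage credit must be <= 0")
    if np.any(decay_release < -1e-9):
        raise ValueError("decay release must be >= 0")
    return EmissionComponents(
        years=years,
        gross_luc=clearing + degradation + harvest_booking,
        regrowth=regrowth,
        a2=storage_credit + decay_release,
        b1=b1, b2=b2,
    )


# --------------------------------------------------------------------------
# scenario comparison arithmetic (Gt CO2)
# --------------------------------------------------------------------------
def _round_half_up(x: float, decimals: int = 0) -> float:
    factor = 10.0 ** decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def overall_cumulative(a3_cum: float, b3_cum: float) -> float:
    """Overall cumulative emissions c = a.3 + b.3 (Gt CO2)."""
    return a3_cum + b3_cum


def scenario_saving(c_bau: float, c_scenario: float) -> float:
    """Cumulative saving of a scenario against BAU (Gt CO2)."""
    return c_bau - c_scenario


def percent_saving(saving: float, baseline_magnitude: float) -> int:
    """Saving as a percent of the BAU cumulative magnitude (integer)."""
    if baseline_magnitude == 0:
        raise ValueError("baseline magnitude must be nonzero")
    return int(_round_half_up(100.0 * saving / abs(baseline_magnitude)))


def annualize(saving: float, years: int) -> float:
    """Average annual saving over the horizon (Gt CO2/yr, two decimals)."""
    if years <= 0:
        raise ValueError("years must be > 0")
    return _round_half_up(saving / years, 2)


def building_net_balance(production_cum: float, storage_cum: float) -> float:
    """Net building-sector balance: production emissions + storage (Gt CO2)."""
    return production_cum + storage_cum


def area_expansion(area_end: float, area_start: float) -> float:
    """Absolute area expansion (Mha)."""
    return area_end - area_start


def annual_establishment_rate(area_end: float, area_start: float,
                              years: int) -> float:
    """Average newly established area per year (Mha/yr, one decimal)."""
    if years <= 0:
        raise ValueError("years must be > 0")
    return _round_half_up((area_end - area_start) / years, 1)


def percent_growth(area_end: float, area_start: float) -> float:
    """Relative growth of an area in percent."""
    if area_start == 0:
        raise ValueError("start area must be nonzero")
    return 100.0 * (area_end - area_start) / area_start


def co2_from_c(mtc) -> np.ndarray | float:
    """Convert carbon mass to CO2 mass (factor 44/12)."""
    return np.asarray(mtc, dtype=float) * CO2_PER_C if np.ndim(mtc) else mtc * CO2_PER_C


def c_from_co2(mtco2) -> np.ndarray | float:
    """Convert CO2 mass to carbon mass (factor 12/44)."""
    return np.asarray(mtco2, dtype=float) / CO2_PER_C if np.ndim(mtco2) else mtco2 / CO2_PER_C
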