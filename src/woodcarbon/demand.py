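"""Engineered-wood demand and annual harvest schedules.

Cumulative engineered-wood demand per region is the new urban population up
to the regional peak year times the per-capita structural wood mass, the
carbon-to-wood ratio and the scenario factor PR:

    M = (P_peak - P_2020) * M_w_c * CW * PR        [MtC]

The cumulative figure is spread over 2021..peak_year with a sliding scale
that weights years nearer the peak more heavily (linear weights by default),
and converted to a harvest requirement with the engineered-wood harvesting
efficiency (default 50%: two units of wood must be cut for one unit entering
a building).  All bookkeeping is in carbon mass; CO2 conversion happens
once, in the emission ledger.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import PopulationTrajectory


@dataclass(frozen=True)
class DemandParams:
    """Parameters of the engineered-wood demand calculation."""

    wood_per_capita: float          # M_w_c, tDM/person
    carbon_wood_ratio: float        # CW, tC/tDM
    pr: float                       # scenario factor, 0 (BAU) .. 0.9
    harvest_efficiency: float = 0.5
    weight_exponent: float = 1.0    # sliding-scale weight (t - base)^p

    def __post_init__(self) -> None:
        if not 0.0 <= self.pr <= 1.0:
            raise ValueError("PR must be in [0, 1]")
        if not 0.0 < self.harvest_efficiency <= 1.0:
            raise ValueError("harvest_efficiency must be in (0, 1]")
        if not (self.wood_per_capita > 0 and self.carbon_wood_ratio > 0):
            raise ValueError("M_w_c and CW must be > 0")


@dataclass
class DemandSchedule:
    """Annual demand series for one region (MtC/yr), aligned on ``years``."""

    region_id: str
    years: np.ndarray
    engineered_inflow: np.ndarray   # carbon entering buildings
    engineered_harvest: np.ndarray  # harvest needed = inflow / efficiency
    roundwood: np.ndarray           # exogenous industrial roundwood
    woodfuel: np.ndarray            # exogenous wood fuel

    def __post_init__(self) -> None:
        n = len(self.years)
        for name in ("engineered_inflow", "engineered_harvest",
                     "roundwood", "woodfuel"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must align with years")
            if np.any(arr < 0):
                raise ValueError(f"{name} must be >= 0")
            setattr(self, name, arr)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": self.region_id,
                "year": self.years,
                "engineered_inflow_mtc": self.engineered_inflow,
                "engineered_harvest_mtc": self.engineered_harvest,
                "roundwood_mtc": self.roundwood,
                "woodfuel_mtc": self.woodfuel,
            }
        )


def cumulative_wood_demand(traj: PopulationTrajectory,
                           params: DemandParams) -> float:
    """Cumulative engineered-wood carbon demand 2020..peak (MtC).

    Million persons x tDM/person x tC/tDM = MtC.  Clamped at zero if the
    urban population declines.
    """
    if 2020 not in traj.years:
        raise ValueError("trajectory must cover the base year 2020")
    delta_p = traj.value_at(traj.peak_year) - traj.value_at(2020)
    return max(0.0, delta_p) * params.wood_per_capita \
        * params.carbon_wood_ratio * params.pr


def annualize_demand(cumulative: float, base_year: int, peak_year: int,
                     weight_exponent: float = 1.0) -> pd.Series:
    """Spread a cumulative demand over (base_year, peak_year] (MtC/yr).

    Weights are proportional to (t - base_year)**p, normalized to sum to
    one, so the series is strictly increasing toward the peak year and sums
    to the cumulative figure.
    """
    if cumulative < 0:
        raise ValueError("cumulative demand must be >= 0")
    if peak_year <= base_year:
        if cumulative == 0:
            return pd.Series(dtype=float)
        raise ValueError("peak_year must exceed base_year for positive demand")
    years = np.arange(base_year + 1, peak_year + 1)
    weights = (years - base_year).astype(float) ** weight_exponent
    return pd.Series(cumulative * weights / weights.sum(), index=years)


def apply_harvest_efficiency(inflow, efficiency: float):
    """Harvest requirement for a building-inflow series: inflow/efficiency."""
    if efficiency <= 0:
        raise ValueError("efficiency must be > 0")
    return np.asarray(inflow, dtype=float) / efficiency


def build_schedule(
    traj: PopulationTrajectory,
    params: DemandParams,
    roundwood: np.ndarray,
    woodfuel: np.ndarray,
    years: np.ndarray | None = None,
) -> DemandSchedule:
    """Merge the engineered-wood schedule with exogenous demand series.

    The exogenous roundwood and wood-fuel series pass through unchanged, so
    they are identical across PR scenarios by construction.
    """
    years = traj.years if years is None else np.asarray(years, dtype=int)
    roundwood = np.asarray(roundwood, dtype=float)
    woodfuel = np.asarray(woodfuel, dtype=float)
    if roundwood.shape != years.shape or woodfuel.shape != years.shape:
        raise ValueError("exogenous series must align with the year grid")
    if not np.array_equal(np.intersect1d(years, traj.years), years):
        raise ValueError("trajectory must cover the scheduling years")

    cumulative = cumulative_wood_demand(traj, params)
    inflow = np.zeros(years.size)
    if cumulative > 0:
        annual = annualize_demand(cumulative, 2020, traj.peak_year,
                                  params.weight_exponent)
        idx = np.searchsorted(years, annual.index.to_numpy())
        inflow[idx] = annual.to_numpy()
    harvest = apply_harvest_efficiency(inflow, params.harvest_efficiency)
    return DemandSchedule(
        region_id=traj.region_id, years=years,
        engineered_inflow=inflow, engineered_harvest=harvest,
        roundwood=roundwood, woodfuel=woodfuel,
    )
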