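"""Harvested-wood-product carbon pools with first-order decay.

Each product pool (industrial roundwood, half-life 35 y; engineered wood in
buildings, half-life 60 y) follows the IPCC tier-1 stock update

    C[t+1] = exp(-k) * C[t] + ((1 - exp(-k)) / k) * inflow[t],   k = ln2/HL

where the inflow term is the annual-average formulation: wood delivered
during year t already decays within the year, so the *effective* inflow is
((1-exp(-k))/k) * inflow < inflow.  The decay outflow of a year is the
mass-balance residual C[t] + effective_inflow - C[t+1] = (1-exp(-k))*C[t],
reported as a positive CO2 release.  Stocks are zero until 2020.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

from .config import CO2_PER_C

HALF_LIFE_ROUNDWOOD = 35.0
HALF_LIFE_ENGINEERED = 60.0


def decay_constant(half_life: float) -> float:
    """First-order decay constant k = ln(2)/half-life (1/yr)."""
    if half_life <= 0:
        raise ValueError("half_life must be > 0")
    return math.log(2.0) / half_life


@dataclass
class HWPPool:
    """One first-order-decay product carbon stock (MtC)."""

    product: str                 # "industrial_roundwood" | "engineered_wood"
    half_life: float
    stock: float = 0.0
    # per-step history, appended by update()
    stocks: list[float] = field(default_factory=list)
    inflows: list[float] = field(default_factory=list)
    releases_c: list[float] = field(default_factory=list)   # MtC/yr

    def __post_init__(self) -> None:
        self.k = decay_constant(self.half_life)
        if self.stock < 0:
            raise ValueError("initial stock must be >= 0")

    @property
    def retention(self) -> float:
        """One-year survival factor exp(-k)."""
        return math.exp(-self.k)

    def effective_inflow(self, inflow: float) -> float:
        """Annual-average inflow term ((1 - exp(-k))/k) * inflow (MtC)."""
        return (1.0 - self.retention) / self.k * inflow

    def update(self, inflow: float) -> tuple[float, float]:
        """Advance one year; return (next stock, stock change) in MtC.

        The within-year decay release (MtC) is recorded in ``releases_c``.
        """
        if inflow < 0:
            raise ValueError("inflow must be >= 0")
        eff = self.effective_inflow(inflow)
        new_stock = self.retention * self.stock + eff
        release = self.stock + eff - new_stock   # = (1 - exp(-k)) * stock
        delta = new_stock - self.stock
        self.stocks.append(new_stock)
        self.inflows.append(inflow)
        self.releases_c.append(release)
        self.stock = new_stock
        return new_stock, delta


def update_pool(pool: HWPPool, inflow: float) -> tuple[float, float]:
    """Functional alias for :meth:`HWPPool.update`."""
    return pool.update(inflow)


def decay_release(pool: HWPPool) -> float:
    """Most recent annual decay release (MtCO2/yr, >= 0)."""
    if not pool.releases_c:
        return 0.0
    return pool.releases_c[-1] * CO2_PER_C


def measured_half_life(half_life: float, initial_stock: float = 100.0,
                       max_years: int = 1000) -> int:
    """Years an isolated stock takes to halve under the annual update.

    Iterates the stock equation with zero inflow and returns the first year
    at which the stock is at or below half the initial value.  The
    comparison carries a 1e-12 relative guard because exp(-k)**half_life
    lands a few ulp above 0.5 in floating point.
    """
    pool = HWPPool("probe", half_life, stock=initial_stock)
    target = 0.5 * initial_stock * (1.0 + 1e-12)
    for year in range(1, max_years + 1):
        pool.update(0.0)
        if pool.stock <= target:
            return year
    raise RuntimeError("stock did not halve within max_years")
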