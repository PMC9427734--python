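"""Scenario configuration.

Every externally stated constant of the model lives here rather than being
hard-coded at its point of use: the carbon-to-wood ratio (0.476 tC/tDM), the
50% harvesting efficiency for engineered wood, the product half-lives (35 y
for industrial roundwood, 60 y for engineered wood), and the scenario factor
PR (share of new urban dwellers housed in wooden buildings: 0 for BAU, then
0.1 / 0.5 / 0.9).  Configs round-trip through YAML so a run is fully
described by one structured text file.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Scenario label -> PR, the fraction of new urban population housed in
#: engineered-wood buildings.
SCENARIO_PR: dict[str, float] = {"BAU": 0.0, "10pc": 0.1, "50pc": 0.5, "90pc": 0.9}

SSP_LABELS = ("SSP1", "SSP2", "SSP3")

CO2_PER_C = 44.0 / 12.0  # mass conversion tCO2 per tC


@dataclass
class ScenarioConfig:
    """Full configuration of one scenario run."""

    scenario: str = "BAU"
    ssp: str = "SSP2"
    seed: int = 0

    # horizon
    start_year: int = 2020
    end_year: int = 2100
    timestep: int = 1  # years

    # demand
    carbon_wood_ratio: float = 0.476       # CW, tC per tDM
    carbon_wood_spread: float = 0.04       # +/- range when randomized
    wood_per_capita: float = 11.5          # M_w_c, tDM per person
    harvest_efficiency: float = 0.5        # engineered-wood harvest efficiency
    weight_exponent: float = 1.0           # sliding-scale weight (t - 2020)^p

    # harvested-wood-product pools
    half_life_roundwood: float = 35.0      # years
    half_life_engineered: float = 60.0     # years

    # forest dynamics
    rotation_rule: str = "CAI"             # CAI | MAI
    land_priority: tuple[str, ...] = ("other", "secondary")
    degradation_rate: float = 0.001        # 1/yr, unprotected natural forest
    plantation_roundwood_share: float = 0.34  # roundwood share provisioned on plantations
    max_cohort_age: int = 160              # years tracked before pooling at the top

    # building materials (per newly housed urban person)
    cement_per_capita: float = 10.0        # t/person, conventional building
    steel_per_capita: float = 1.0          # t/person, conventional building
    ef_wood: float = 0.45                  # tCO2e/t engineered wood processed
    ef_cement: float = 0.6                 # tCO2e/t
    ef_steel: float = 1.85                 # tCO2e/t

    @property
    def pr(self) -> float:
        """Scenario factor PR implied by the scenario label."""
        try:
            return SCENARIO_PR[self.scenario]
        except KeyError:
            raise ValueError(f"unknown scenario label {self.scenario!r}") from None

    @property
    def years(self) -> range:
        return range(self.start_year, self.end_year + 1)

    def validate(self) -> None:
        if self.scenario not in SCENARIO_PR:
            raise ValueError(f"unknown scenario label {self.scenario!r}")
        if self.ssp not in SSP_LABELS:
            raise ValueError(f"unknown SSP label {self.ssp!r}")
        if self.start_year != 2020:
            raise ValueError("horizon must start in 2020")
        if not 0.0 < self.harvest_efficiency <= 1.0:
            raise ValueError("harvest_efficiency must be in (0, 1]")
        if self.rotation_rule not in ("CAI", "MAI"):
            raise ValueError("rotation_rule must be 'CAI' or 'MAI'")
        if not 0.0 <= self.degradation_rate <= 0.05:
            raise ValueError("degradation_rate must be in [0, 0.05]")

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["land_priority"] = list(self.land_priority)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "land_priority" in d:
            d["land_priority"] = tuple(d["land_priority"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        """Stable hash of the full configuration, for provenance blocks."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def replace(self, **kw) -> "ScenarioConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic-data generator.

    Anchors: 2020 global land pools of 137 Mha plantations, 1595 Mha cropland
    and 3629 Mha natural forest; global urban population shares of 92 / 80 /
    58 % by 2100 under SSP1 / SSP2 / SSP3.
    """

    n_regions: int = 12
    world_land_mha: float = 13000.0
    protection_range: tuple[float, float] = (0.1, 0.4)

    # 2020 global land-pool anchors (Mha)
    plantation_mha: float = 137.0
    cropland_mha: float = 1595.0
    natural_forest_mha: float = 3629.0
    primary_fraction: float = 0.6          # of natural forest
    pasture_mha: float = 3000.0

    # population study conditions
    pop_2020_million: float = 7800.0
    urban_share_2020: float = 0.56
    pop_2100_million: dict[str, float] = field(
        default_factory=lambda: {"SSP1": 8200.0, "SSP2": 9000.0, "SSP3": 11500.0}
    )
    urban_share_2100: dict[str, float] = field(
        default_factory=lambda: {"SSP1": 0.92, "SSP2": 0.80, "SSP3": 0.58}
    )
    peak_year_range: tuple[int, int] = (2040, 2090)

    # exogenous wood demand, global totals (MtC/yr); roundwood covers only the
    # long-lived sawnwood/panel fraction (no pulp/paper pool is modeled)
    roundwood_mtc: float = 80.0
    woodfuel_mtc: float = 400.0

    randomize_cw: bool = False
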