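import pytest
from hypothesis import HealthCheck, settings

import woodcarbon as wc

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

SCENARIOS = ("BAU", "10pc", "50pc", "90pc")


@pytest.fixture(scope="session")
def regions():
    return wc.generate_regions(12, seed=0)


@pytest.fixture(scope="session")
def fixtures_ssp2():
    return wc.generate_fixtures(n_regions=12, ssp="SSP2", seed=0)


@pytest.fixture(scope="session")
def matrix():
    """Full default scenario x SSP matrix at seed 0: (summary, results)."""
    fixtures = {ssp: wc.generate_fixtures(12, ssp, 0)
                for ssp in ("SSP1", "SSP2", "SSP3")}
    return wc.run_matrix(fixtures)


@pytest.fixture(scope="session")
def ssp2_runs(matrix):
    """Scenario -> ScenarioResult for the SSP2 column of the matrix."""
    _, results = matrix
    return {scenario: results[(scenario, "SSP2")] for scenario in SCENARIOS}
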