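"""Shared fixtures: synthetic study systems at two scales.

The large "recovery" scenario (one 20-km high-traffic road, 20,000
residences, full 2007-2016 calendar) feeds the parameter-recovery,
calibration, decay, and design-validity suites; everything geometric (roads,
wind, pregnancy windows, exposure, matches) is built once per session and
only the outcome stage is redrawn per replicate.  The small scenario is a
fast strongly-prevailing-wind system for matching and model-mechanics tests.
"""

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import downwind as dw

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


RECOVERY_CONFIG = dw.SimulationConfig(
    seed=3,
    n_residences=20_000,
    n_roads=1,
    road_length_m=20_000.0,
    high_traffic_share=1.0,
)

SMALL_CONFIG = dw.SimulationConfig(
    seed=11,
    n_residences=800,
    n_roads=1,
    road_length_m=4_000.0,
    high_traffic_share=1.0,
    curved_share=0.0,
    wind_concentration=4.0,
    study_years=(2010, 2014),
)


@pytest.fixture(scope="session")
def recovery_scenario() -> dw.Scenario:
    return dw.build_scenario(RECOVERY_CONFIG)


@pytest.fixture(scope="session")
def term_matches(recovery_scenario) -> pd.DataFrame:
    matches, _ = dw.match_cohort(recovery_scenario.cohort, restrict_weeks=(37, 42))
    return matches


@pytest.fixture(scope="session")
def small_scenario() -> dw.Scenario:
    return dw.build_scenario(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_matches(small_scenario) -> pd.DataFrame:
    matches, _ = dw.match_cohort(small_scenario.cohort, restrict_weeks=(37, 42))
    return matches


@pytest.fixture(scope="session")
def small_matches_all(small_scenario) -> pd.DataFrame:
    """Matches over the unrestricted cohort (for PTB/very-PTB outcomes)."""
    matches, _ = dw.match_cohort(small_scenario.cohort)
    return matches


@pytest.fixture(scope="session")
def small_records(small_scenario) -> pd.DataFrame:
    return dw.gen_births(small_scenario.config, small_scenario.cohort, seed=101).set_index(
        "residence_id"
    )
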