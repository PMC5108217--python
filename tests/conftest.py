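import numpy as np
import pandas as pd
import pytest

from gxevar import (
    McmcSettings,
    ModelSpec,
    PriorSpec,
    SimConfig,
    TemperatureSeries,
    build_design,
    default_facility_series,
    gibbs_sample,
    simulate_emergence_outcomes,
    simulate_hatch_phenotypes,
)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig()


@pytest.fixture(scope="session")
def hatch_table(sim_config):
    return simulate_hatch_phenotypes(sim_config, seed=11)


@pytest.fixture(scope="session")
def facility_series(sim_config):
    return default_facility_series(sim_config, seed=11)


@pytest.fixture(scope="session")
def emergence_table(sim_config, hatch_table, facility_series):
    return simulate_emergence_outcomes(hatch_table, sim_config, facility_series, seed=12)


@pytest.fixture(scope="session")
def hatch_fit(hatch_table):
    """One moderate fit of the full hatch model, reused across tests."""
    design = build_design(hatch_table, ModelSpec("body_length_mm"))
    draws = gibbs_sample(
        design, PriorSpec(), McmcSettings(6000, 1000, 5, seed=21)
    )
    return design, draws


def constant_series(temp: float, days: int, per_day: int = 24,
                    start: str = "2012-05-01") -> TemperatureSeries:
    n = days * per_day
    ts = pd.Timestamp(start) + pd.Timedelta(24 / per_day, "h") * np.arange(n + 1)
    return TemperatureSeries(ts, np.full(n + 1, temp))
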