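import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import overwinter as ow

settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def sim_config():
    """Default generator configuration (the emulated pier-record regime)."""
    return ow.ClimateSimConfig(seed=1)


@pytest.fixture(scope="session")
def clean_pair(sim_config):
    """Gap-free noisy air/water pair plus truth, shared across tests."""
    return ow.generate_pair(sim_config, with_gaps=False)


@pytest.fixture(scope="session")
def final_transfer(clean_pair):
    """Final-stage transfer function fitted on the full clean pair."""
    air, water, _ = clean_pair
    af = ow.fit_harmonic(air, M=1)
    wf = ow.fit_harmonic(water, M=1)
    return ow.build_transfer(af, wf)


def make_series(values, start="2000-01-01", variable="water", source="obs"):
    values = np.asarray(values, dtype=float)
    dates = pd.date_range(start, periods=len(values), freq="D")
    return ow.DailySeries(dates, values, variable=variable, source=source)


@pytest.fixture
def make_daily():
    return make_series
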