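import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cpforage.models import MCMCSettings
from cpforage.synthetic import SimConfig, default_study_area, simulate_study

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_config():
    """Small, clean study: 10-min cadence, no truncation, no land trips."""
    return SimConfig(seed=11).clean(n_birds_per_colony_year=4, fix_interval_min=10.0)


@pytest.fixture(scope="session")
def clean_study(clean_config):
    return simulate_study(clean_config)


@pytest.fixture(scope="session")
def study_area():
    return default_study_area()


@pytest.fixture(scope="session")
def fast_mcmc():
    """Reduced run lengths for unit tests of the samplers."""
    return MCMCSettings(chains=2, iterations=1600, warmup=800, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_fixes(times_min, positions, bird_id="b1"):
    """Helper: a fix table from minutes-offsets and (lon, lat) pairs."""
    t0 = np.datetime64("2018-07-10T06:00:00")
    return pd.DataFrame(
        {
            "bird_id": bird_id,
            "timestamp": [t0 + np.timedelta64(int(m * 60), "s") for m in times_min],
            "lon": [p[0] for p in positions],
            "lat": [p[1] for p in positions],
        }
    )
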