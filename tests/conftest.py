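import numpy as np
import pandas as pd
import pytest

from phenocast.config import SyntheticConfig
from phenocast.synthetic import simulate_dataset, simulate_flowering_records
from phenocast.config import FULL_DATA_COEFFICIENTS


def hourly_weather(temps, start="2021-07-01", latitude=-37.8, station="TEST"):
    """Hourly weather frame from a flat temperature array."""
    ts = pd.date_range(start, periods=len(temps), freq="h")
    return pd.DataFrame({"station": station, "latitude": latitude,
                         "timestamp": ts, "temp_c": np.asarray(temps, float)})


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(seed=42, n_years=3, start_year=2019,
                           n_orchards_per_region=1, n_vines_per_orchard=6)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def eq1_records():
    """2000 covariate-level records drawn from the final full-data model."""
    rng = np.random.default_rng(2024)
    return simulate_flowering_records(2000, FULL_DATA_COEFFICIENTS, rng)
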