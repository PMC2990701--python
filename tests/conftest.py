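import numpy as np
import pandas as pd
import pytest

from snakemap import SyntheticConfig, simulate_cases, simulate_municipalities


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    return SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def municipalities(default_config) -> pd.DataFrame:
    return simulate_municipalities(default_config)


@pytest.fixture(scope="session")
def cases_and_truth(municipalities, default_config):
    return simulate_cases(municipalities, default_config)


@pytest.fixture()
def tiny_municipalities() -> pd.DataFrame:
    """Ten municipalities: two well-separated altitude/location groups."""
    rng = np.random.default_rng(7)
    n = 10
    group = np.repeat([0, 1], 5)
    return pd.DataFrame(
        {
            "municipality_id": np.arange(1, n + 1),
            "population": np.full(n, 10_000),
            "pct_rural": rng.uniform(20, 80, n),
            "altitude_m": np.where(group == 0, 100.0, 1100.0) + rng.normal(0, 10, n),
            "precipitation_mm_y": 2000.0 + rng.normal(0, 20, n),
            "x_km": np.where(group == 0, 0.0, 500.0) + rng.normal(0, 5, n),
            "y_km": rng.normal(0, 5, n),
        }
    )
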