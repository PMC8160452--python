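import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_exclusion_cohort():
    """Six hand-written records: three clean, one collected at 50 h, one
    screen-positive, one missing birth weight."""
    return pd.DataFrame({
        "id": [f"r{i}" for i in range(6)],
        "site": "toy",
        "sex": ["M", "F", "M", "F", "M", "F"],
        "birth_weight_g": [3400.0, 3100.0, 3600.0, 3300.0, 3500.0, np.nan],
        "ga_weeks": [39.0, 38.5, 40.1, 37.2, 41.0, 39.5],
        "collection_age_hours": [24.0, 30.0, 40.0, 50.0, 26.0, 28.0],
        "screen_positive": [0, 0, 0, 0, 1, 0],
        "ALA": [250.0, 260.0, 240.0, 255.0, 900.0, 251.0],
        "TSH": [5.0, 4.0, 6.0, 5.5, 4.5, 5.2],
    })


@pytest.fixture(scope="session")
def small_cohort():
    """A moderately sized generated cohort shared by read-only tests."""
    from metaga import SyntheticConfig, generate_cohort

    return generate_cohort(SyntheticConfig(n_infants=4000, seed=77))
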