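import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from careaccess.config import ScenarioConfig, default_scenario

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_scenario() -> ScenarioConfig:
    """Two countries, two quarters, small enough for per-test generation."""
    return default_scenario(
        countries=["AA", "BB"],
        quarters=[(2019, 2), (2020, 2)],
        n_users_per_country=400,
        trips_per_user_mean=1.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_trips(tiny_scenario):
    from careaccess.synthetic_data import generate_trips

    return generate_trips(tiny_scenario)


def make_trips_df(times, user_ids=None, country="AA", year=2019, quarter=2,
                  mode="passenger_vehicle"):
    """Hand-built minimal trip table around a vector of travel times."""
    times = np.asarray(times, dtype=float)
    n = times.size
    if user_ids is None:
        user_ids = [f"u{i}" for i in range(n)]
    return pd.DataFrame(
        {
            "user_id": user_ids,
            "country": country,
            "year": year,
            "quarter": quarter,
            "mode": mode,
            "travel_time_min": times,
            "distance_km": times / 60.0 * 40.0,
            "origin_cell": "cell0",
            "facility_id": "fac0",
        }
    )
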