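import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_campus_spec():
    """A two-venue campus small enough for fast end-to-end runs."""
    from healthpass.synthetic_campus import CampusSpec, VenueSpec

    return CampusSpec(
        n_visitors=200,
        venues=(
            VenueSpec("hall", capacity=60, arrival_rate=4.0, mean_dwell=10.0),
            VenueSpec("cafe", capacity=10, arrival_rate=2.0, mean_dwell=1.5),
        ),
        transition_matrix=((0.7, 0.3), (0.6, 0.4)),
        I0=0.10,
        horizon_days=25,
        seed=7,
        continue_prob=0.4,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240501)
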