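import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import zsustain as zs

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def atlas17():
    return zs.DEFAULT_ATLAS


@pytest.fixture(scope="session")
def spec17(atlas17):
    return zs.event_spec_for(atlas17)


@pytest.fixture(scope="session")
def toy_spec3():
    """Three biomarkers, one waypoint each: 6 possible sequences."""
    return zs.ZScoreEventModelSpec(
        biomarkers=("a", "b", "c"), waypoints=(1.0,), z_max=1.0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """Small planted cohort reused by harmonization/pipeline tests."""
    cfg = zs.SimulationConfig(n_patients=200, n_controls=200, seed=42)
    return zs.generate_clinical(zs.generate_cohort(cfg), cfg), cfg
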