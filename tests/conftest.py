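import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")

from preevac import (
    AttributeDistributions,
    CoefficientSet,
    default_coefficients,
    default_distributions,
    default_scene,
    sample_population,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def coeffs():
    """The calibrated coefficient set shipped with the package."""
    return default_coefficients()


@pytest.fixture
def scene():
    return default_scene()


@pytest.fixture
def small_population():
    return sample_population(default_distributions(200, seed=11))


def homogeneous_distributions(n):
    """Degenerate distributions: every agent has the same attribute vector."""
    return AttributeDistributions(
        probs={
            "age": (0, 1, 0, 0, 0),
            "gen": (0, 1),
            "edu": (0, 1, 0),
            "time": (0, 1, 0, 0),
            "group": (1, 0, 0, 0),
            "zone": (0, 1, 0, 0, 0),
            "mode": (0, 0, 0, 0, 0, 1, 0),
        },
        n=n,
    )
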