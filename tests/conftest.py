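import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ltpasim import ModelParams

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def tiny_params() -> ModelParams:
    """A fast, fully featured world for unit tests."""
    return ModelParams(
        grid_side=12,
        n_persons=60,
        prop_ltpa_sites=0.1,
        perception_radius=4.0,
        k_network=3,
        horizon_weeks=8,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
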