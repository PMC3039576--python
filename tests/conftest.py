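import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gotlm.model import ModelConfig
from gotlm.synthetic import generate, preset

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def separable_dataset():
    """The separable preset: graded GO quality C > P > F, weak sequence signal."""
    return generate(preset("separable", seed=7))


@pytest.fixture(scope="session")
def null_dataset():
    """Labels detached from all features; accuracy should sit at chance."""
    return generate(preset("null", seed=7))


@pytest.fixture(scope="session")
def small_config():
    """A single-point grid, enough for fast end-to-end runs."""
    return ModelConfig(cvk_grid=(3,), gamma_grid=(0.25,), c_grid=(8.0,), seed=7)
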