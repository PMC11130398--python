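import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from lilrcnv.simulate import SimulationConfig, build_toy_locus  # noqa: E402


@pytest.fixture(scope="session")
def locus():
    """One toy locus shared by the whole suite (seed 3, defaults)."""
    return build_toy_locus(SimulationConfig(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(11)
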