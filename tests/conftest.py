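import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mrcovadj import ScenarioConfig

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def small_config():
    """A cheap scenario for structural (non-statistical) checks."""
    return ScenarioConfig("B", 1, n_individuals=2_000, seed=3)


def make_config(structure="B", confounding=1, **kwargs):
    kwargs.setdefault("seed", 3)
    return ScenarioConfig(structure, confounding, **kwargs)
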