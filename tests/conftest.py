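import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tdobserve as td

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def task():
    """Standard observing task: q=0.5, rewards 1.0 / 0.04."""
    return td.build_observing_task()


@pytest.fixture
def eng():
    """Default valence-family disengagement parameters."""
    return td.EngagementParams()


@pytest.fixture
def eng_off():
    """Disengagement disabled (hazard scale 0)."""
    return td.EngagementParams.off()


@pytest.fixture
def policy():
    return td.PolicyParams(beta=10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
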