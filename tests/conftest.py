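import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pairfeedsim import GROUP_PF, INDIVIDUAL_PF, DesignConfig

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_group_cfg():
    return DesignConfig(m_per_group=8, n_days=15, design=GROUP_PF, n_reps=50, seed=7)


@pytest.fixture
def small_indiv_cfg():
    return DesignConfig(m_per_group=8, n_days=15, design=INDIVIDUAL_PF, n_reps=50, seed=7)
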