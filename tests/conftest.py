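import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import boutline as bl

settings.register_profile(
    "boutline",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("boutline")


SMALL_CFG = bl.SimConfig(n_groups_per_treatment=1, group_size=4, seed=7)


@pytest.fixture(scope="session")
def small_study():
    """One small simulated study (2 groups of 4) plus its ground truth."""
    table, truth = bl.simulate_study(SMALL_CFG)
    return table, truth


@pytest.fixture(scope="session")
def prepared_study(small_study):
    """The small study after normalization and period labeling."""
    table, truth = small_study
    table = bl.assign_periods(bl.normalize_events(table))
    return table, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220408)
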