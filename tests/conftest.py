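import numpy as np
import pytest

from connhier import CohortConfig, make_cohort, make_node_space


@pytest.fixture(scope="session")
def node_space():
    return make_node_space(200, seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """16-subject, 2-site cohort with default planted effects (shared)."""
    cfg = CohortConfig(n_per_group_per_site=4, master_seed=3)
    space, manifest, connectomes, _ = make_cohort(cfg)
    return space, manifest, connectomes


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
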