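import numpy as np
import pytest

from statenergy.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort shared by unit tests (not the default study scale)."""
    cfg = CohortConfig(group_sizes={"HC": 6, "CP": 6, "CI": 6},
                       n_regions=40, n_frames=120)
    return generate_cohort(cfg, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
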