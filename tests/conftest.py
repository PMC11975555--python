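import numpy as np
import pytest

from tegcoag import cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_cfg():
    return cohort.default_config()


@pytest.fixture(scope="session")
def default_registry(default_cfg):
    return cohort.generate_cohort(default_cfg, seed=7)


@pytest.fixture(scope="session")
def eligible_cohort_df(default_registry):
    eligible, _ = cohort.apply_exclusions(default_registry)
    return eligible.to_dataframe()
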