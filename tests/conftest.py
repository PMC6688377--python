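import numpy as np
import pytest

from orthocost import CohortParams, LABIAL, LINGUAL, ScenarioConfig

#: fixed a priori for every seeded test in the suite
TEST_SEED = 20190809


@pytest.fixture
def rng():
    return np.random.default_rng(TEST_SEED)


@pytest.fixture
def small_labial_config():
    """A labial scenario small enough for per-test pipelines."""
    return ScenarioConfig(
        intervention=LABIAL,
        fee_factor=3.5,
        repair_median=180.0,
        cohort=CohortParams(n_sim=20_000),
        seed=TEST_SEED,
    )


@pytest.fixture
def small_lingual_config():
    return ScenarioConfig(
        intervention=LINGUAL,
        fee_factor=3.5,
        repair_median=180.0,
        cohort=CohortParams(n_sim=20_000),
        seed=TEST_SEED,
    )
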