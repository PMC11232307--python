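import numpy as np
import pytest

from trialmed.config import default_config
from trialmed.simulate import simulate_trial

#: reduced sampler settings for tests that only need a correct posterior,
#: not a fine-grained one
FAST_SAMPLER = {"n_draws": 1000}


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def trial_complete():
    """Moderate-size fully observed trial under the default study conditions."""
    return simulate_trial(default_config(n=2000), seed=11, with_missingness=False)


@pytest.fixture(scope="session")
def trial_missing():
    """Trial-size dataset with the default MAR attrition applied."""
    return simulate_trial(default_config(), seed=13)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
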