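import numpy as np
import pytest

from tapsync import CONDITIONS, TapperParams, simulate_tapper


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_free_trial():
    """A perfect tapper: every 2nd beat from beat 3, zero phase."""
    params = TapperParams(noise_free=True, mean_phase=0.0)
    return simulate_tapper(CONDITIONS["A"], params, seed=0)
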