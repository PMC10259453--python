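import numpy as np
import pytest

from stnvalue.config import SimConfig
from stnvalue.synthetic import generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Small but complete simulated dataset shared across tests."""
    cfg = SimConfig(n_sessions=6, trials_per_session=60, n_neurons=12,
                    encoding_gain=0.5, seed=11)
    return generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def homogeneous_trains(rate_hz, n_trials, t_start, t_stop, rng):
    """Exact homogeneous Poisson spike trains (for oracles)."""
    dur = t_stop - t_start
    counts = rng.poisson(rate_hz * dur, n_trials)
    return [np.sort(t_start + rng.uniform(0.0, dur, c)) for c in counts]
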