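import numpy as np
import pytest

from lfpconn import core_io, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_trialset(rng):
    """2 trials x 2 channels x 8 samples with mixed labels."""
    data = rng.standard_normal((2, 2, 8))
    channels = [
        core_io.ChannelInfo("T1", "proximal", 0.0, 1.0),
        core_io.ChannelInfo("T2", "distal"),
    ]
    trials = [
        core_io.TrialInfo("tr0", "A", "in", "correct"),
        core_io.TrialInfo("tr1", "B", "out", "incorrect"),
    ]
    return core_io.TrialSet(data=data, fs=1000.0, channels=channels, trials=trials)


@pytest.fixture
def white_noise_trialset(rng):
    """30 trials of 3-channel white noise, labels cycled over odors."""
    spec = simulate.VARSpec(P=3, order=1, coeffs=[np.zeros((3, 3))], innov_cov=np.eye(3))
    return simulate.simulate_var_trials(spec, R=30, T=256, fs=1000.0, seed=7)
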