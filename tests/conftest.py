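import numpy as np
import pytest

from gpla.preprocess import AnalyticLFP, RawLFP
from gpla.coupling import SpikeTrainSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_tone_lfp(freq=20.0, fs=500.0, duration=4.0, n_channels=1, amplitude=1.0,
                  n_trials=1, phase=0.0):
    """Real cosine tone on every channel."""
    t = np.arange(int(duration * fs)) / fs
    sig = amplitude * np.cos(2 * np.pi * freq * t + phase)
    trials = [np.tile(sig, (n_channels, 1)) for _ in range(n_trials)]
    return RawLFP(trials=trials, fs=fs)


def make_analytic_tone(freq=20.0, fs=500.0, duration=4.0, n_channels=1,
                       amplitude=1.0, n_trials=1, band=None, phases=None):
    """Complex analytic tone, bypassing the filter (for exact-phase tests)."""
    t = np.arange(int(duration * fs)) / fs
    if phases is None:
        phases = np.zeros(n_channels)
    trials = []
    for _ in range(n_trials):
        sig = np.stack(
            [amplitude * np.exp(1j * (2 * np.pi * freq * t + p)) for p in phases]
        )
        trials.append(sig)
    if band is None:
        band = (freq - 5, freq + 5)
    return AnalyticLFP(trials=trials, band=band, fs=fs)


def spikes_at(indices, trial_length, fs, n_trials=1):
    """Single-unit spike set with the same indices in every trial."""
    idx = np.asarray(indices, dtype=np.int64)
    return SpikeTrainSet(
        trains=[[idx.copy() for _ in range(n_trials)]],
        trial_length=trial_length,
        fs=fs,
    )
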