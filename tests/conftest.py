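import numpy as np
import pytest

from mimenet.signal_io import MultichannelRecording
from mimenet.synthetic_data import CouplingSpec, gen_coupled_linear


def ar1_pair(seed: int, coupling: float, n: int = 2000, a: float = 0.5,
             lag: int = 1, burn: int = 50):
    """Driver AR(1) x and driven y_t = a*y_{t-1} + coupling*x_{t-lag} + e."""
    rng = np.random.default_rng(seed)
    total = n + burn
    x = np.zeros(total)
    y = np.zeros(total)
    ex = rng.normal(size=total)
    ey = rng.normal(size=total)
    for t in range(lag, total):
        x[t] = a * x[t - 1] + ex[t]
        y[t] = a * y[t - 1] + coupling * x[t - lag] + ey[t]
    return x[burn:], y[burn:]


def eeg_like_pair(seed: int, n_samples: int = 2000):
    """Two independent band-limited channels mimicking scalp recordings."""
    spec = CouplingSpec(n_channels=2, couplings=[], base_process="bandlimited",
                        fs=100, duration_s=n_samples / 100, seed=seed)
    rec, _ = gen_coupled_linear(spec)
    return rec.data[0], rec.data[1]


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_recording():
    rng = np.random.default_rng(42)
    data = rng.normal(size=(4, 600))
    return MultichannelRecording(data, fs=100.0,
                                 channel_labels=["F3", "F4", "C3", "C4"],
                                 subject_id="S1")
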