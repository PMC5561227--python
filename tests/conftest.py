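import numpy as np
import pytest
from scipy.signal import lfilter

from caltrace.tracesim import ar2_coefficients


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def unit_transients(spike_times_s, duration_s, fs=65.0, amps=None):
    """Noiseless trace with peak-normalized AR(2) transients at given times."""
    g1, g2 = ar2_coefficients(0.5, 1.0, fs)
    n = int(duration_s * fs)
    drive = np.zeros(n)
    amps = amps if amps is not None else [1.0] * len(spike_times_s)
    for t, a in zip(spike_times_s, amps):
        drive[int(t * fs)] += a
    imp = np.zeros(n)
    imp[0] = 1.0
    peak = lfilter([1.0], [1.0, -g1, -g2], imp).max()
    return lfilter([1.0 / peak], [1.0, -g1, -g2], drive)


@pytest.fixture
def make_transient_trace():
    return unit_transients
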