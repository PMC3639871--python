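import numpy as np
import pytest

from clgfnet.signals import SignalSet


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def sinusoid_set(freqs_hz, fs=1000.0, duration=2.0, amplitudes=None,
                 phases=None):
    """Multichannel pure-tone test signal; freqs_hz is one entry per
    channel (an entry may itself be a list of components)."""
    t = np.arange(int(round(duration * fs))) / fs
    rows = []
    for i, f in enumerate(freqs_hz):
        comps = np.atleast_1d(f)
        amp = 1.0 if amplitudes is None else amplitudes[i]
        ph = 0.0 if phases is None else phases[i]
        rows.append(sum(amp * np.sin(2 * np.pi * c * t + ph) for c in comps))
    return SignalSet(np.array(rows), fs)
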