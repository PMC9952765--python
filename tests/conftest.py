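import numpy as np
import pytest

from csimotion import CSIRecording


@pytest.fixture
def rng():
    return np.random.default_rng(20230228)


@pytest.fixture
def make_recording(rng):
    """Factory for small random CSI recordings (continuous-valued, so rows
    never repeat by chance)."""

    def _make(T=100, n_streams=2, fs=1000.0, seed=None):
        r = rng if seed is None else np.random.default_rng(seed)
        S = 30 * n_streams
        samples = r.normal(size=(T, S)) + 1j * r.normal(size=(T, S))
        streams = [(0, k) for k in range(n_streams)]
        return CSIRecording(samples, fs=fs, streams=streams)

    return _make
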