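import numpy as np
import pytest

from beatmeter import stimulus as st


@pytest.fixture(scope="session")
def duple_env_spectrum():
    """Envelope power spectrum (0.01 Hz grid) of a 120 s tiled duple stream."""
    pattern = st.build_accent_pattern("duple", 32, 10.0)
    stim = st.synthesize_stimulus(pattern)
    tiled = st.tile_to_duration(stim, 120.0)
    return st.spectrum_of(st.envelope(tiled), resolution_hz=0.01)


@pytest.fixture(scope="session")
def triple_env_spectrum():
    pattern = st.build_accent_pattern("triple", 33, 10.0)
    stim = st.synthesize_stimulus(pattern)
    tiled = st.tile_to_duration(stim, 120.0)
    return st.spectrum_of(st.envelope(tiled), resolution_hz=0.01)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
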