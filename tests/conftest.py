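import numpy as np
import pytest

from statecoupler import synthgen
from statecoupler.recording import Recording


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def white_recording(rng):
    data = rng.standard_normal((3, 5000))
    return Recording(
        data=data,
        fs=250.0,
        channel_labels=["c0", "c1", "lfp"],
        channel_roles=["cortical", "cortical", "lfp"],
    )


@pytest.fixture
def two_state_gated():
    """Two-state recording with a 20-Hz coupling active only in state 1."""
    fs = 100.0
    T = 60000
    spec = synthgen.MarkovSpec.uniform_sticky(2, 0.999)
    states = synthgen.sample_state_sequence(spec, T, 3)
    coupling = synthgen.CouplingSpec(
        "c0", "lfp0", frozenset({1}), synthgen.OscillatorSpec(20.0, 6.0, 1.5), 0.8
    )
    rec, truth = synthgen.synthesize_recording(
        states, {}, [coupling], noise_sd=1.0, fs=fs, seed=7
    )
    return rec, truth, states, coupling
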