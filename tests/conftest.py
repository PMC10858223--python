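import numpy as np
import pytest

import popsync as ps


@pytest.fixture(scope="session")
def gamma_decomp():
    """Gamma decomposition of a clean 60 s, 40 Hz sinusoid at 1250 Hz."""
    fs = 1250.0
    t = np.arange(int(60 * fs)) / fs
    return ps.lfp.wavelet_band(np.sin(2 * np.pi * 40.0 * t), fs, "gamma")


@pytest.fixture(scope="session")
def baseline_session():
    """600 s, 12 E units, 2 Hz, planted events at 0.4/s with gain 5."""
    return ps.synth.gen_spike_session(
        n_excitatory=12, n_inhibitory=0, duration=600.0, base_rate=2.0,
        popevent_rate=0.4, popevent_duration=0.15, popevent_gain=5.0, seed=7,
    )


@pytest.fixture(scope="session")
def whole_session_epochs():
    return ps.EventIntervalSet([[0.0, 600.0]], label="wake")
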