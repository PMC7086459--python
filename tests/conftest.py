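import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture
def two_class_epochs():
    """EEG-like epochs with genuine class contrast (mu attenuation)."""
    from driftbci.synthgen import default_signal_scenario, simulate_eeg_epochs

    return simulate_eeg_epochs(default_signal_scenario(seed=7))
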