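import numpy as np
import pytest

from catm import nn
from catm.synthetic import SyntheticSpec, generate_recording, planted_band_effects


@pytest.fixture
def float64_engine():
    """Run the autodiff engine in float64 for numerical gradient checks."""
    old = nn.DEFAULT_DTYPE
    nn.set_default_dtype(np.float64)
    yield
    nn.set_default_dtype(old)


@pytest.fixture(scope="session")
def small_spec():
    """A reduced DEAP-shaped spec with a strong planted band effect."""
    return SyntheticSpec(
        n_subjects=1,
        n_trials=20,
        n_channels=32,
        n_eeg_channels=32,
        stimulus_s=12.0,
        band_effects=planted_band_effects(2.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_recording(small_spec):
    return generate_recording(small_spec, "s01")
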