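import numpy as np
import pytest

from coeruleus import PhantomSpec, generate_phantom


@pytest.fixture
def noiseless_spec():
    """Phantom with no noise and no slice drift: planted values are exact."""
    return PhantomSpec(noise_sd=0.0, slice_drift_range=(1.0, 1.0))


@pytest.fixture
def noiseless_phantom(noiseless_spec):
    return generate_phantom(noiseless_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
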