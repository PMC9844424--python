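import numpy as np
import pytest

from dixonfat import phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """One noiseless, bias-free 128 px phantom with its ground truth."""
    spec = phantom.PhantomSpec(image_size=128, noise_sd=0.0, bias_amplitude=0.0)
    return phantom.generate_phantom(spec, seed=7)


@pytest.fixture(scope="session")
def noisy_phantom():
    """One phantom at the default noise/bias settings."""
    spec = phantom.PhantomSpec(image_size=128)
    return phantom.generate_phantom(spec, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
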