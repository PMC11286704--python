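import numpy as np
import pytest

from pftquant.synthetic import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free default phantom with all six confounders."""
    pair, truth = generate_phantom(PhantomConfig(seed=11, noise_sd=0.0))
    return pair, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default (noisy) phantom with all six confounders."""
    pair, truth = generate_phantom(PhantomConfig(seed=11))
    return pair, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
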