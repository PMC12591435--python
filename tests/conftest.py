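import numpy as np
import pytest

from hmfgraph.model import Hyperparameters, sample_moments
from hmfgraph.simulate import generate_scale_free, sample_mvn


@pytest.fixture(scope="session")
def small_dataset():
    """p=20, n=100 fixed-weight scale-free dataset with its truth."""
    net = generate_scale_free(20, "fixed", seed=7)
    Y = sample_mvn(net, 100, seed=8)
    return net, Y


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    from hmfgraph.model import gem_fit

    _, Y = small_dataset
    return gem_fit(sample_moments(Y), Hyperparameters(alpha=0.5))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
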