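import numpy as np
import pytest

from budsort.pipeline import train_default_model


@pytest.fixture(scope="session")
def knn_model():
    """Default self-trained classifier: 30 synthetic samples/class, k=3."""
    return train_default_model(seed=1234, noise_sigma=3.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
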