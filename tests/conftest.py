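import numpy as np
import pytest

from lowlight.experiments import train_glyph_classifier


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def trained_glyph_net():
    """A small glyph classifier trained once and shared across tests.

    Four classes keep the training quick while leaving the task non-trivial
    at low light.
    """
    net, fixtures, losses = train_glyph_classifier(
        seed=7, n_classes=4, n_per_class=30, epochs=60)
    return net, fixtures, losses
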