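import numpy as np
import pytest

from oculoscore.synthetic import generate_annotated_images


@pytest.fixture(scope="session")
def small_dataset():
    """A dozen synthetic photographs with ground truth (session-cached)."""
    return generate_annotated_images(12, seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
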