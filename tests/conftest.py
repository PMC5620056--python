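import numpy as np
import pytest

from discrn.types import ScaleGrid


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def grid3():
    return ScaleGrid((3, 5, 7))


@pytest.fixture()
def random_image(rng):
    """A 33x33 textured test image with broad intensity range."""
    return rng.normal(128.0, 30.0, size=(33, 33))
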