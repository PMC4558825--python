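import numpy as np
import pytest

from uniline.reference import load_bundled_tree


@pytest.fixture(scope="session")
def mt_tree():
    return load_bundled_tree("mt")


@pytest.fixture(scope="session")
def y_tree():
    return load_bundled_tree("y")


@pytest.fixture()
def rng():
    return np.random.default_rng(20150903)
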