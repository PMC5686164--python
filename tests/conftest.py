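import numpy as np
import pytest

from ipdnet.io import make_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def ring4():
    return make_fixture("ring4")


@pytest.fixture
def star5():
    return make_fixture("star5")


@pytest.fixture
def two_triangles():
    return make_fixture("two_triangles")
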