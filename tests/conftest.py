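import numpy as np
import pytest

from droughtkit import datasets


@pytest.fixture
def iris_table():
    """The packaged ten-cultivar, six-index membership matrix."""
    return datasets.load_iris_membership()


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
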