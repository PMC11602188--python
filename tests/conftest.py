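import numpy as np
import pytest

from stickreach import StickGeometry, linear_relation


@pytest.fixture(scope="session")
def geom():
    return StickGeometry()


@pytest.fixture(scope="session")
def relation02():
    """Linear baseline relation with slope 0.2 (typical participant)."""
    return linear_relation(0.2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
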