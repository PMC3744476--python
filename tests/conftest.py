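import numpy as np
import pytest

from fairycircles.geometry import SpatialWindow


@pytest.fixture
def window100():
    """100 x 100 m survey window, euclidean distances."""
    return SpatialWindow(0.0, 100.0, 0.0, 100.0)


@pytest.fixture
def torus100():
    """100 x 100 m window with periodic (toroidal) distances."""
    return SpatialWindow(0.0, 100.0, 0.0, 100.0, distance_mode="toroidal")


@pytest.fixture
def rng():
    return np.random.default_rng(20130815)
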