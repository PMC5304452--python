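import numpy as np
import pytest

from phonosim.geometry import DuctSpec, FoldSpec
from phonosim.grid import GridSpec


@pytest.fixture
def channel_grid():
    """Uniform 2D grid spanning the default duct."""
    duct = DuctSpec()
    return GridSpec(
        [np.linspace(-0.0105, 0.0105, 49), np.linspace(duct.y_min, duct.y_max, 97)]
    )


@pytest.fixture
def duct_spec():
    return DuctSpec()


@pytest.fixture
def fold_spec():
    return FoldSpec()


@pytest.fixture
def rng():
    return np.random.default_rng(7)
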