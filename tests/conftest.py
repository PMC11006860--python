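import numpy as np
import pytest

from phaseseg.fields import GridSpec, ImageField, PhaseField


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid8():
    return GridSpec.from_shape((8, 8))


@pytest.fixture
def random_field8(rng, grid8):
    values = rng.uniform(-0.5, 2.5, grid8.shape)
    return PhaseField(values=values, k_phases=2, grid=grid8)


@pytest.fixture
def two_plateau():
    """Left half I0 = 0.2 / phi = 0, right half I0 = 0.8 / phi = 1."""
    grid = GridSpec.from_shape((16, 16))
    img = np.full(grid.shape, 0.2)
    img[:, 8:] = 0.8
    phi = np.zeros(grid.shape)
    phi[:, 8:] = 1.0
    return (
        ImageField(values=img, grid=grid),
        PhaseField(values=phi, k_phases=2, grid=grid),
    )
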