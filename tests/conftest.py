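import numpy as np
import pytest

from afspectra.cube_io import DEFAULT_AXIS, SpectralCube
from afspectra.synthetic_scene import SceneConfig, render_microspheres, render_section


@pytest.fixture(scope="session")
def axis():
    return DEFAULT_AXIS


@pytest.fixture(scope="session")
def section():
    """One default synthetic cross-section with its ground truth."""
    return render_section(SceneConfig(seed=101))


@pytest.fixture(scope="session")
def microsphere_field():
    """One default zero-drift microsphere reference field."""
    return render_microspheres(seed=202)


@pytest.fixture
def random_cube(axis):
    rng = np.random.default_rng(7)
    data = rng.integers(0, 4096, size=(16, 16, axis.n_channels), dtype=np.uint16)
    return SpectralCube(data, axis)
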