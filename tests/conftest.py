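import numpy as np
import pytest

from scarseg.core import VoxelGeometry
from scarseg.phantom import PhantomSpec, generate_slice


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def unit_geometry():
    return VoxelGeometry(1.0, 1.0, 8.0)


@pytest.fixture
def clean_spec():
    """Noise- and bias-free phantom: piecewise-constant intensities."""
    return PhantomSpec(grid_size=96, pixel_spacing_mm=1.5, noise_sd=0.0, bias_amplitude=0.0)


@pytest.fixture
def clean_slice(clean_spec):
    return generate_slice(clean_spec)


@pytest.fixture
def noisy_slice():
    return generate_slice(PhantomSpec(grid_size=96, pixel_spacing_mm=1.5, seed=7))
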