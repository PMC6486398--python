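import numpy as np
import pytest

from habitatseg.synthetic import PhantomSpec, make_phantom
from habitatseg.volume_io import ROIMask


@pytest.fixture(scope="session")
def default_phantom():
    """One default-geometry subject bundle (~1.1e4 CE voxels), shared."""
    return make_phantom(PhantomSpec(seed=42))


@pytest.fixture(scope="session")
def fitted_habitat(default_phantom):
    from habitatseg.habitat import HabitatModel

    b = default_phantom
    return HabitatModel.from_raw(b.adc, b.rcbv, b.ce, b.nawm).fit()


def make_mask(arr, voxel_dims=(1.0, 1.0, 1.0), label="other"):
    return ROIMask(data=np.asarray(arr, dtype=bool), voxel_dims=voxel_dims, label=label)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
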