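import numpy as np
import pytest

from pcct_cardiac.acquisition import AcquisitionConfig, acquire, log_normalize
from pcct_cardiac.physics import DynamicPhantomConfig, make_dynamic_phantom


@pytest.fixture(scope="session")
def water_disk_phantom():
    """Static uniform water disk (no iodine, no vials, no texture)."""
    return make_dynamic_phantom(DynamicPhantomConfig(
        grid_n=48, voxel_mm=0.25, dlvv_ml=1e-6, slvv_ml=1e-6,
        blood_iodine_mg_ml=0.0, vials=False, tissue_texture=0.0))


@pytest.fixture(scope="session")
def water_disk_sino(water_disk_phantom):
    """Noiseless log-mode sinogram of the water disk (120 views)."""
    return log_normalize(acquire(water_disk_phantom, AcquisitionConfig(
        views=120, noise=False)))


@pytest.fixture(scope="session")
def beating_sino():
    """Noisy 1000-view scan of a beating phantom at 450 bpm."""
    phantom = make_dynamic_phantom(DynamicPhantomConfig(
        grid_n=48, voxel_mm=0.25, heart_rate_bpm=450.0, vials=False), seed=1)
    sino = log_normalize(acquire(phantom, AcquisitionConfig(views=1000, seed=2)))
    return phantom, sino


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
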