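import numpy as np
import pytest

from mtmesh.synth import make_fixture_network, render_network
from mtmesh.volume import VoxelVolume


@pytest.fixture(scope="session")
def two_parallel_model():
    return make_fixture_network("two_parallel")


@pytest.fixture(scope="session")
def two_parallel_render(two_parallel_model):
    """Noisy two-channel render of the two-parallel-filament fixture."""
    return render_network(two_parallel_model, snr=10.0, seed=3)


@pytest.fixture(scope="session")
def noiseless_cylinder_render(two_parallel_model):
    return render_network(two_parallel_model, snr=np.inf, seed=0)


@pytest.fixture()
def ramp_volume():
    """16-bit linear ramp along x at 0.1 um isotropic spacing."""
    data = np.tile(np.linspace(0, 65535, 64, dtype=np.uint16), (8, 8, 1))
    return VoxelVolume(data=data, spacing=(0.1, 0.1, 0.1), bit_depth=16)


def antialiased_sphere(radius_um=1.2, pitch_um=0.12, margin_um=0.4):
    """Sphere occupancy with a one-voxel linear edge (how blurred data looks)."""
    n = int(2 * (radius_um + margin_um) / pitch_um) + 1
    c = (n - 1) / 2.0
    zz, yy, xx = np.meshgrid(*(np.arange(n),) * 3, indexing="ij")
    d = np.sqrt((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) * pitch_um
    occ = np.clip((radius_um - d) / pitch_um + 0.5, 0.0, 1.0)
    data = np.round(occ * 1000).astype(np.uint16)
    return VoxelVolume(data=data, spacing=(pitch_um,) * 3, bit_depth=16)
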