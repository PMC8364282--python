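import pytest

from virtualcone.geometry import Aperture, MachineGeometry
from virtualcone.kernels import (KernelModelParams, make_grid,
                                 make_treatment_kernel, synthesize_kernel)


@pytest.fixture(scope="session")
def smoke_machine():
    """Coarse 1-mm-voxel geometry for fast checks."""
    return MachineGeometry(voxel_size=1.0)


@pytest.fixture(scope="session")
def reduced_machine():
    """0.5-mm-voxel geometry used for the replication analyses."""
    return MachineGeometry(voxel_size=0.5)


@pytest.fixture(scope="session")
def params():
    return KernelModelParams()


@pytest.fixture(scope="session")
def smoke_aperture():
    return Aperture(2, 2.0)


@pytest.fixture(scope="session")
def smoke_kernel(smoke_aperture, smoke_machine, params):
    """Smoothed treatment kernel for the 2 x 5 mm2 aperture at 1-mm voxels."""
    return make_treatment_kernel(smoke_aperture, smoke_machine, params)


@pytest.fixture(scope="session")
def smoke_kernel_raw(smoke_aperture, smoke_machine, params):
    """Unsmoothed kernel (sharper edges; used by interpolation oracles)."""
    return synthesize_kernel(smoke_aperture, smoke_machine, params)


@pytest.fixture(scope="session")
def smoke_roi():
    """±10 mm region-of-interest grid at 1-mm voxels."""
    return make_grid(20.0, 1.0)
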