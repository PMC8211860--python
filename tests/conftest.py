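import numpy as np
import pytest

from voxsaxs.formfactors import (
    VoxelModel,
    apoferritin_model,
    ferritin_model,
    octahedron_frame,
)


@pytest.fixture(scope="session")
def frame():
    return octahedron_frame()


@pytest.fixture(scope="session")
def ferritin_voxel(frame):
    return VoxelModel(frame, ferritin_model())


@pytest.fixture(scope="session")
def empty_voxel(frame):
    return VoxelModel(frame)


@pytest.fixture(scope="session")
def apoferritin_voxel(frame):
    return VoxelModel(frame, apoferritin_model())


@pytest.fixture(scope="session")
def q_lattice():
    """Standard lattice-scenario grid: 0.002-0.08 A^-1, 600 log points."""
    return np.geomspace(0.002, 0.08, 600)
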