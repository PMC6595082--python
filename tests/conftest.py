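import numpy as np
import pytest

from longivol import LabelVolume, ShapeSpec, TriangleMesh, make_segmentation

# unit cube [0,1]^3 as 12 outward-oriented triangles
_CUBE_VERTS = np.array([
    [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
    [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
], dtype=float)
_CUBE_FACES = np.array([
    [0, 2, 1], [0, 3, 2],          # bottom (z=0), outward -z
    [4, 5, 6], [4, 6, 7],          # top (z=1), outward +z
    [0, 1, 5], [0, 5, 4],          # y=0, outward -y
    [2, 3, 7], [2, 7, 6],          # y=1, outward +y
    [1, 2, 6], [1, 6, 5],          # x=1, outward +x
    [3, 0, 4], [3, 4, 7],          # x=0, outward -x
])


def unit_cube_mesh() -> TriangleMesh:
    return TriangleMesh(_CUBE_VERTS.copy(), _CUBE_FACES.copy())


@pytest.fixture
def unit_cube() -> TriangleMesh:
    return unit_cube_mesh()


@pytest.fixture(scope="session")
def ellipsoid_spec() -> ShapeSpec:
    return ShapeSpec(kind="ellipsoid", semi_axes=(12.0, 8.0, 6.0), spacing=1.0)


@pytest.fixture(scope="session")
def ellipsoid_seg(ellipsoid_spec) -> LabelVolume:
    return make_segmentation(ellipsoid_spec)


def make_mask(voxels, shape=(8, 8, 8), affine=None) -> LabelVolume:
    """Tiny helper: a LabelVolume with the given foreground voxel indices."""
    data = np.zeros(shape, dtype=np.uint8)
    for v in voxels:
        data[tuple(v)] = 1
    return LabelVolume(data, np.eye(4) if affine is None else affine)
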