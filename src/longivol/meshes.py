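"""Triangle-mesh volumetry.

Structure volumes are carried across time points by closed triangle meshes in
world millimetres: the baseline segmentation is converted to a surface once
(marching cubes) and every subsequent transform — rigid, affine or a dense
non-linear deformation — moves the vertices directly, so no resampling of the
label image is ever needed. The enclosed volume is the sum of signed
tetrahedra spanned by the origin and each oriented triangle (divergence
theorem), which is exact for any closed, consistently oriented surface and
invariant to translation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .segmentation import LabelVolume

log = logging.getLogger(__name__)

__all__ = [
    "TriangleMesh",
    "AffineTransform",
    "extract_mesh",
    "mesh_volume",
    "apply_affine",
]


@dataclass
class TriangleMesh:
    """A triangle surface with vertices in world millimetres.

    ``faces`` index into ``vertices`` with consistent winding; an
    outward-oriented closed mesh has positive signed volume.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def is_closed(self) -> bool:
        """True iff every directed edge is matched by its reverse exactly once.

        This simultaneously checks 2-manifoldness (each undirected edge on
        exactly two faces) and consistent orientation.
        """
        if self.n_faces == 0:
            return False
        f = self.faces
        directed = np.concatenate(
            [f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]], axis=0
        )
        fwd, counts = np.unique(directed, axis=0, return_counts=True)
        if np.any(counts != 1):
            return False
        rev = fwd[:, ::-1]
        # every directed edge must appear reversed somewhere
        fwd_set = {(int(a), int(b)) for a, b in fwd}
        return all((int(a), int(b)) in fwd_set for a, b in rev)

    def with_vertices(self, vertices: np.ndarray) -> "TriangleMesh":
        return TriangleMesh(vertices=np.asarray(vertices, float), faces=self.faces.copy())

    def flipped(self) -> "TriangleMesh":
        return TriangleMesh(vertices=self.vertices.copy(), faces=self.faces[:, ::-1].copy())


@dataclass
class AffineTransform:
    """4x4 homogeneous world-mm -> world-mm transform."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("affine matrix must be 4x4")
        if not np.allclose(self.matrix[3], (0, 0, 0, 1)):
            raise ValueError("last row must be (0,0,0,1)")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("singular affine")

    @property
    def det3(self) -> float:
        return float(np.linalg.det(self.matrix[:3, :3]))


def signed_volume(mesh: TriangleMesh) -> float:
    """Sum of signed tetrahedra (origin, v0, v1, v2) over all faces, in mm^3."""
    v = mesh.vertices
    f = mesh.faces
    v0, v1, v2 = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    return float(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0)


def mesh_volume(mesh: TriangleMesh, *, check_closed: bool = True) -> float:
    """Enclosed volume of a closed, consistently oriented mesh (mm^3).

    A negative total signed volume indicates inward orientation; the
    magnitude is returned and a warning logged, because downstream volume
    change needs positive volumes.

    Raises
    ------
    ValueError
        "open surface" if the mesh is not closed / consistently oriented.
    """
    if check_closed and not mesh.is_closed():
        raise ValueError("open surface: mesh is not a closed oriented 2-manifold")
    vol = signed_volume(mesh)
    if vol < 0:
        log.warning(
            "negative signed volume (%.3f mm^3): mesh is inward-oriented, "
            "reporting magnitude",
            vol,
        )
        return -vol
    return vol


def extract_mesh(seg: LabelVolume, iso_level: float = 0.5) -> TriangleMesh:
    """Marching-cubes isosurface of a binary segmentation, in world mm.

    The label grid is padded with one zero layer before extraction so that
    foreground touching the array boundary still yields a closed surface;
    vertex coordinates are then mapped through the volume's affine. Faces are
    re-wound if necessary so the returned mesh is outward-oriented (positive
    signed volume).

    Parameters
    ----------
    seg
        Binary segmentation; must contain at least one foreground voxel.
    iso_level
        Isosurface level in the binary field; 0.5 is the unbiased midpoint.
    """
    if seg.voxel_count == 0:
        raise ValueError("empty label: cannot extract a surface")
    if not 0.0 < iso_level < 1.0:
        raise ValueError("iso_level must lie strictly between 0 and 1")
    touches = (
        seg.data[0].any() or seg.data[-1].any()
        or seg.data[:, 0].any() or seg.data[:, -1].any()
        or seg.data[:, :, 0].any() or seg.data[:, :, -1].any()
    )
    if touches:
        log.warning("foreground touches the grid boundary; padding before extraction")
    padded = np.pad(seg.data.astype(float), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=iso_level)
    verts -= 1.0  # undo pad offset -> original voxel-index space
    world = seg.voxel_to_world(verts)
    mesh = TriangleMesh(world, faces)
    if signed_volume(mesh) < 0:
        mesh = mesh.flipped()
    return mesh


def apply_affine(mesh: TriangleMesh, t: AffineTransform) -> TriangleMesh:
    """Map mesh vertices exactly through an affine transform (no resampling).

    The enclosed volume scales by |det| of the 3x3 block. If the transform
    is orientation-reversing (det < 0) the face winding is flipped so the
    result stays outward-oriented.
    """
    m = t.matrix
    verts = mesh.vertices @ m[:3, :3].T + m[:3, 3]
    out = mesh.with_vertices(verts)
    if t.det3 < 0:
        out = out.flipped()
    return out
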