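"""Binary label volumes and voxel-overlap measures.

A :class:`LabelVolume` is a 3-D binary segmentation on a regular grid with a
voxel-to-world affine (NIfTI convention, world coordinates in millimetres).
It is the common operand of mesh extraction, Jacobian integration and the
Jaccard overlap index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

__all__ = ["LabelVolume", "jaccard_index"]


@dataclass
class LabelVolume:
    """A binary 3-D segmentation with world-space geometry.

    Parameters
    ----------
    data
        3-D array of {0, 1} labels (any integer dtype; stored as uint8).
    affine
        4x4 voxel-index -> world-mm homogeneous transform.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"label volume must be 3-D, got shape {data.shape}")
        uniq = np.unique(data)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("label volume must be binary {0,1}")
        self.data = data.astype(np.uint8)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing (mm) along each index axis: column norms of the affine."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3, |det| of the 3x3 affine block."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    def volume(self) -> float:
        """Voxel-count volume in mm^3 (foreground voxels x voxel volume)."""
        return self.voxel_count * self.voxel_volume

    def same_grid(self, other: "LabelVolume", atol: float = 1e-6) -> bool:
        return self.data.shape == other.data.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (n,3) voxel indices (0-based, may be fractional) to world mm."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]


def jaccard_index(a: LabelVolume, b: LabelVolume) -> float:
    """Overlap |A∩B| / |A∪B| between two segmentations on the same grid.

    Returns a fraction in [0, 1]; 1 iff the masks are identical and non-empty.

    Raises
    ------
    ValueError
        If the grids differ or both masks are empty ("undefined overlap").
    """
    if not a.same_grid(b):
        raise ValueError("jaccard_index requires identical grids")
    am = a.data.astype(bool)
    bm = b.data.astype(bool)
    union = int(np.logical_or(am, bm).sum())
    if union == 0:
        raise ValueError("undefined overlap: both masks empty")
    inter = int(np.logical_and(am, bm).sum())
    return inter / union
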