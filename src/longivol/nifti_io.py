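"""File formats: NIfTI-1 volumes and vector fields, PLY/STL meshes.

Vector displacement fields use the X×Y×Z×1×3 NIfTI layout with the
``vector`` intent code (the convention popularized by the ANTs ecosystem);
a plain X×Y×Z×3 layout is accepted as a fallback on read. All mesh files
carry world-mm coordinates.
"""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh

from .fields import BASELINE_TO_FOLLOWUP, DisplacementField
from .meshes import TriangleMesh, signed_volume
from .segmentation import LabelVolume

log = logging.getLogger(__name__)

__all__ = [
    "load_label_volume", "save_label_volume",
    "load_displacement_field", "save_displacement_field",
    "load_mesh", "save_mesh",
]


def load_label_volume(path) -> LabelVolume:
    """Read a binary segmentation from NIfTI; any nonzero value becomes 1."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D label image, got shape {data.shape}")
    if not np.all(np.isin(np.unique(data), (0, 1))):
        log.warning("label image %s has non-binary values; thresholding nonzero -> 1",
                    path)
    return LabelVolume((data != 0).astype(np.uint8), np.asarray(img.affine))


def save_label_volume(seg: LabelVolume, path) -> None:
    img = nib.Nifti1Image(seg.data.astype(np.uint8), seg.affine)
    nib.save(img, str(path))


def save_displacement_field(fld: DisplacementField, path) -> None:
    """Write as X×Y×Z×1×3 float32 with NIfTI intent 'vector'."""
    data = fld.vectors.astype(np.float32)[:, :, :, None, :]
    img = nib.Nifti1Image(data, fld.affine)
    img.header.set_intent("vector")
    nib.save(img, str(path))


def load_displacement_field(path, direction: str = BASELINE_TO_FOLLOWUP) -> DisplacementField:
    """Read a dense vector field; accepts X×Y×Z×1×3 or X×Y×Z×3 layouts."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim == 5 and data.shape[3] == 1 and data.shape[4] == 3:
        vectors = data[:, :, :, 0, :]
    elif data.ndim == 4 and data.shape[3] == 3:
        log.info("reading %s with fallback X×Y×Z×3 vector layout", path)
        vectors = data
    else:
        raise ValueError(f"not a displacement field: shape {data.shape}")
    return DisplacementField(vectors, np.asarray(img.affine), direction=direction)


def save_jacobian(jac, path) -> None:
    """Write a Jacobian determinant map as a scalar NIfTI volume."""
    img = nib.Nifti1Image(jac.data.astype(np.float32), jac.affine)
    nib.save(img, str(path))


def save_mesh(mesh: TriangleMesh, path) -> None:
    """Write a mesh as PLY (ascii or binary by extension handling) or STL."""
    path = Path(path)
    tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    if path.suffix.lower() not in (".ply", ".stl"):
        raise ValueError(f"unsupported mesh format {path.suffix!r}")
    tm.export(str(path))


def load_mesh(path) -> TriangleMesh:
    """Read a PLY mesh; faces are re-wound outward if needed."""
    tm = trimesh.load(str(path), process=False)
    mesh = TriangleMesh(np.asarray(tm.vertices, float),
                        np.asarray(tm.faces, np.int64))
    if signed_volume(mesh) < 0:
        mesh = mesh.flipped()
    return mesh
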