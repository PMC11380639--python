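"""Bone segmentation of CT-like volumes by Hounsfield thresholding.

Replicates the virtual-dissection step of the modeling workflow: soft tissue
is excluded by a Hounsfield-unit window (default 226 to 48,060 HU, bounds
inclusive), the bone mask is converted to a triangle surface by marching
cubes, and the raw surface is cleaned by keeping the largest connected
component and dropping degenerate faces.  Per-patient manual adjustment of
the selection is out of scope — thresholds are configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
import trimesh
from skimage import measure

HU_BONE_MIN = 226.0
HU_BONE_MAX = 48060.0

__all__ = [
    "HUVolume",
    "threshold_bone",
    "extract_surface",
    "clean_mesh",
    "load_nifti",
    "HU_BONE_MIN",
    "HU_BONE_MAX",
]


class SegmentationError(ValueError):
    pass


@dataclass
class HUVolume:
    """Scalar CT-like volume in Hounsfield units with mm spacing."""

    voxels: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise SegmentationError("voxels must be a non-empty 3D grid")
        if any(s <= 0 for s in self.spacing):
            raise SegmentationError("spacing must be positive on all axes")


def load_nifti(path) -> HUVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return HUVolume(np.asanyarray(img.dataobj, dtype=float), spacing, origin)


def threshold_bone(volume: HUVolume, hu_min: float = HU_BONE_MIN, hu_max: float = HU_BONE_MAX) -> np.ndarray:
    """Boolean bone mask: true exactly where ``hu_min <= HU <= hu_max``."""
    if hu_min > hu_max:
        raise SegmentationError("hu_min must not exceed hu_max")
    return (volume.voxels >= hu_min) & (volume.voxels <= hu_max)


def extract_surface(mask: np.ndarray, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> trimesh.Trimesh:
    """Marching-cubes iso-surface of a binary mask, in mm, outward normals.

    The mask is zero-padded so surfaces touching the grid edge close
    properly.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise SegmentationError("empty mask: no bone voxels to extract")
    if mask.all():
        raise SegmentationError("full mask: no surface inside the volume")
    padded = np.pad(mask.astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    verts = verts - np.asarray(spacing, dtype=float) + np.asarray(origin, dtype=float)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:  # enforce outward orientation
        mesh.invert()
    return mesh


def clean_mesh(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Keep the largest connected component; drop zero-area faces and
    unreferenced vertices.  Idempotent."""
    out = mesh.copy()
    out.update_faces(out.area_faces > 0.0)
    parts = out.split(only_watertight=False)
    if len(parts) > 1:
        out = max(parts, key=lambda p: p.area)
    out.remove_unreferenced_vertices()
    return out
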