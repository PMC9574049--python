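"""4-D fMRI volumes and voxel/mm coordinate geometry.

A :class:`Volume4D` is the unit of input for the whole pipeline: a 4-D BOLD
array in (x, y, z, t) order together with the 4x4 voxel-index -> mm affine
and the repetition time. NIfTI reading/writing goes through nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume4D",
    "voxel_to_mm",
    "mm_to_voxel",
    "voxel_sizes_from_affine",
    "check_axis_aligned",
    "load_volume4d",
    "save_volume4d",
    "load_mask",
    "save_mask",
]


@dataclass
class Volume4D:
    """A 4-D BOLD series: ``data[x, y, z, t]`` plus affine and TR (seconds)."""

    data: np.ndarray
    affine: np.ndarray
    tr_s: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4-D data, got shape {self.data.shape}")
        if self.data.shape[3] < 1:
            raise ValueError("need at least one time frame")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def with_data(self, data: np.ndarray) -> "Volume4D":
        return replace(self, data=data)


def voxel_to_mm(voxel_index, affine: np.ndarray) -> np.ndarray:
    """Map a 0-based voxel index triple to mm via the homogeneous affine."""
    idx = np.asarray(voxel_index, dtype=np.float64)
    return affine[:3, :3] @ idx + affine[:3, 3]


def mm_to_voxel(coord_mm, affine: np.ndarray) -> np.ndarray:
    """Inverse of :func:`voxel_to_mm`; returns fractional voxel indices."""
    inv = np.linalg.inv(affine)
    xyz = np.asarray(coord_mm, dtype=np.float64)
    return inv[:3, :3] @ xyz + inv[:3, 3]


def voxel_sizes_from_affine(affine: np.ndarray) -> np.ndarray:
    """Per-axis voxel edge lengths in mm (column norms of the 3x3 block)."""
    return np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0))


def check_axis_aligned(affine: np.ndarray, atol: float = 1e-6) -> None:
    """Raise if the affine mixes axes (shear/rotation).

    Separable per-axis smoothing is only meaningful when each voxel axis maps
    to a single world axis.
    """
    block = np.asarray(affine, dtype=np.float64)[:3, :3]
    for j in range(3):
        col = np.abs(block[:, j])
        if np.sort(col)[:2].sum() > atol * max(col.max(), 1.0):
            raise ValueError(
                "affine has off-axis (shear/rotation) terms; only "
                "axis-aligned affines are supported"
            )


def load_volume4d(path, tr_s: float | None = None) -> Volume4D:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim == 3:
        data = data[..., np.newaxis]
    if tr_s is None:
        zooms = img.header.get_zooms()
        tr_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
    return Volume4D(data=data, affine=np.asarray(img.affine), tr_s=tr_s)


def save_volume4d(vol: Volume4D, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    img.header.set_zooms((*voxel_sizes_from_affine(vol.affine), vol.tr_s))
    nib.save(img, str(path))
    return path


def load_mask(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 3-D binary mask; returns (bool array, affine)."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise ValueError(f"mask must be 3-D, got shape {data.shape}")
    return data > 0.5, np.asarray(img.affine)


def save_mask(mask: np.ndarray, affine: np.ndarray, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine)
    nib.save(img, str(path))
    return path
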