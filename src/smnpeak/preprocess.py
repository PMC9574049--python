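"""Minimal BOLD preprocessing: initial-volume discard and Gaussian smoothing.

The pipeline assumes its inputs are already in a common (MNI-like) space;
slice-timing and motion correction are out of scope. What remains is
dropping the first volumes acquired before T1 equilibration and spatial
smoothing with a fixed-FWHM Gaussian kernel.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from .volume import Volume4D, check_axis_aligned, voxel_sizes_from_affine

__all__ = ["FWHM_TO_SIGMA", "discard_initial_volumes", "smooth_gaussian"]

#: sigma = FWHM / (2 sqrt(2 ln 2)) = FWHM / 2.35482
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def discard_initial_volumes(vol: Volume4D, n_discard: int) -> Volume4D:
    """Drop the first ``n_discard`` frames; remaining frames are untouched."""
    if not (0 <= n_discard < vol.n_volumes):
        raise ValueError(
            f"n_discard must be in [0, {vol.n_volumes}), got {n_discard}")
    if n_discard == 0:
        return vol
    return vol.with_data(vol.data[..., n_discard:].copy())


def smooth_gaussian(vol: Volume4D, fwhm_mm: float) -> Volume4D:
    """Smooth each frame with a separable Gaussian of the given FWHM (mm).

    The kernel sigma is converted to voxel units per axis from the affine,
    so anisotropic voxels are handled. Boundaries use nearest-edge
    (constant-replication) padding so results are bit-stable. ``fwhm_mm = 0``
    is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be non-negative, got {fwhm_mm}")
    if fwhm_mm == 0:
        return vol
    check_axis_aligned(vol.affine)
    voxel_mm = voxel_sizes_from_affine(vol.affine)
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_mm
    out = np.empty_like(vol.data)
    for t in range(vol.n_volumes):
        gaussian_filter(vol.data[..., t], sigma=sigma_vox, mode="nearest",
                        output=out[..., t])
    return vol.with_data(out)
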