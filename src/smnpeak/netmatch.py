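"""Identify the sensorimotor-network component(s) of a decomposition.

Each z-scored component map is binarized at ``z > z_threshold`` and compared
with the binary SMN mask via the Dice coefficient. The component with the
largest Dice is the candidate SMN; single-subject ICA sometimes splits the
network into a left and a right component, so a laterality index (Dice with
the left vs right mask half) decides between a single bilateral component
and a left/right pair. Runs whose best Dice stays below a floor are flagged
unidentified rather than raising -- downstream statistics treat them as
missing observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ica import ICADecomposition
from .volume import voxel_to_mm

__all__ = ["SMNSelection", "dice_coefficient", "mask_halves", "identify_smn"]


@dataclass
class SMNSelection:
    """Outcome of SMN identification for one decomposition.

    mode is 'bilateral' (one component covers both sides), 'split' (distinct
    left and right components) or 'unidentified' (best Dice below the floor).
    """

    mode: str
    bilateral_component: int | None = None
    left_component: int | None = None
    right_component: int | None = None
    dice_top1: float = 0.0
    dice_top2: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("bilateral", "split", "unidentified"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "bilateral" and self.bilateral_component is None:
            raise ValueError("bilateral mode needs a component index")
        if self.mode == "split":
            if self.left_component is None or self.right_component is None:
                raise ValueError("split mode needs both side components")
            if self.left_component == self.right_component:
                raise ValueError("split sides must be distinct components")
        if self.dice_top2 > self.dice_top1 + 1e-12:
            raise ValueError("dice_top1 must be >= dice_top2")


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A&B| / (|A| + |B|); 0 when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask grids differ: {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 0.0
    return 2.0 * int((a & b).sum()) / total


def mask_halves(mask: np.ndarray, affine: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a mask at mm x = 0: (left half x<0, right half x>0).

    Voxels whose center sits exactly at x = 0 belong to neither half.
    """
    mask = np.asarray(mask, dtype=bool)
    ii = np.arange(mask.shape[0])
    x_mm = np.array([voxel_to_mm((i, 0, 0), affine)[0] for i in ii])
    left = mask & (x_mm < 0)[:, np.newaxis, np.newaxis]
    right = mask & (x_mm > 0)[:, np.newaxis, np.newaxis]
    return left, right


def identify_smn(decomposition: ICADecomposition, smn_mask: np.ndarray,
                 z_threshold: float = 1.0, dice_floor: float = 0.10,
                 laterality_cut: float = 0.5) -> SMNSelection:
    """Select the SMN component(s) by Dice ranking and a laterality rule.

    Components are binarized at signed ``z > z_threshold`` (maps must be
    z-scored and sign-aligned). The laterality index of a component is
    (D_L - D_R) / (D_L + D_R) with D_L, D_R its Dice against the left/right
    mask halves. If the top-ranked component is not strongly lateralized
    (|laterality| <= laterality_cut) the run is bilateral; otherwise the best
    remaining component lateralized to the opposite side (and above the Dice
    floor) completes a left/right split. A lateralized top component with no
    qualifying partner falls back to bilateral mode.
    """
    for i, comp in enumerate(decomposition.components):
        if not (comp.zscored and comp.sign_aligned):
            raise ValueError(
                f"component {i} is not z-scored/sign-aligned; apply "
                "zscore_align first")
    smn_mask = np.asarray(smn_mask, dtype=bool)
    left_mask, right_mask = mask_halves(smn_mask, decomposition.affine)

    n = decomposition.n_components
    dice_full = np.empty(n)
    laterality = np.empty(n)
    for i, comp in enumerate(decomposition.components):
        binary = comp.zmap > z_threshold
        dice_full[i] = dice_coefficient(binary, smn_mask)
        d_l = dice_coefficient(binary, left_mask)
        d_r = dice_coefficient(binary, right_mask)
        laterality[i] = 0.0 if d_l + d_r == 0 else (d_l - d_r) / (d_l + d_r)

    # rank by Dice, ties broken by lower component index
    order = np.lexsort((np.arange(n), -dice_full))
    top1 = int(order[0])
    dice_top1 = float(dice_full[top1])
    dice_top2 = float(dice_full[order[1]]) if n > 1 else 0.0

    if dice_top1 < dice_floor:
        return SMNSelection(mode="unidentified", dice_top1=dice_top1,
                            dice_top2=dice_top2)

    lat1 = laterality[top1]
    if abs(lat1) <= laterality_cut:
        return SMNSelection(mode="bilateral", bilateral_component=top1,
                            dice_top1=dice_top1, dice_top2=dice_top2)

    want_sign = -np.sign(lat1)
    for idx in order[1:]:
        idx = int(idx)
        if (dice_full[idx] >= dice_floor
                and abs(laterality[idx]) > laterality_cut
                and np.sign(laterality[idx]) == want_sign):
            left_c, right_c = (top1, idx) if lat1 > 0 else (idx, top1)
            return SMNSelection(mode="split", left_component=left_c,
                                right_component=right_c,
                                dice_top1=dice_top1, dice_top2=dice_top2)
    return SMNSelection(mode="bilateral", bilateral_component=top1,
                        dice_top1=dice_top1, dice_top2=dice_top2)
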