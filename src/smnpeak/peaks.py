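"""Peak-voxel extraction from identified SMN components.

The peak is the voxel with maximal z inside one side of the SMN mask
(left half searched in the bilateral component or the left split component,
likewise for the right), reported both as a 0-based voxel index and in mm
coordinates via the affine. Ties go to the lexicographically smallest
(x, y, z) index so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ica import ICADecomposition
from .netmatch import SMNSelection, mask_halves
from .volume import voxel_to_mm

__all__ = ["PeakRecord", "extract_peak", "peak_table", "voxel_to_mm"]

PEAK_COLUMNS = ["subject", "visit", "scanner", "condition", "n_components",
                "side", "i", "j", "k", "x_mm", "y_mm", "z_mm", "peak_z",
                "missing"]


@dataclass
class PeakRecord:
    """One peak observation for one (run, side)."""

    subject: object
    visit: str
    scanner: str
    condition: str
    n_components: int
    side: str
    voxel_index: tuple[int, int, int] | None = None
    coord_mm: tuple[float, float, float] | None = None
    peak_z: float = float("nan")
    missing: bool = False
    meta: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        idx = self.voxel_index or (None, None, None)
        mm = self.coord_mm or (None, None, None)
        return {"subject": self.subject, "visit": self.visit,
                "scanner": self.scanner, "condition": self.condition,
                "n_components": self.n_components, "side": self.side,
                "i": idx[0], "j": idx[1], "k": idx[2],
                "x_mm": mm[0], "y_mm": mm[1], "z_mm": mm[2],
                "peak_z": self.peak_z, "missing": self.missing}


def extract_peak(selection: SMNSelection, decomposition: ICADecomposition,
                 smn_mask: np.ndarray, side: str, **labels) -> PeakRecord:
    """Locate the maximal-z voxel of the selected SMN map within one mask half.

    In bilateral mode both sides are searched in the single bilateral
    component's map; in split mode each side uses its own component. Keyword
    labels (subject, visit, ...) are carried into the returned record.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    if selection.mode == "unidentified":
        raise ValueError("cannot extract a peak from an unidentified run")

    if selection.mode == "bilateral":
        comp_idx = selection.bilateral_component
    else:
        comp_idx = (selection.left_component if side == "left"
                    else selection.right_component)
    zmap = decomposition.components[comp_idx].zmap

    left_mask, right_mask = mask_halves(smn_mask, decomposition.affine)
    region = left_mask if side == "left" else right_mask
    if not region.any():
        raise ValueError(f"the {side} half of the SMN mask is empty")

    search = np.where(region, zmap, -np.inf)
    flat = int(np.argmax(search))   # first occurrence in C order = lexicographic
    idx = np.unravel_index(flat, zmap.shape)
    mm = voxel_to_mm(idx, decomposition.affine)
    defaults = {"subject": None, "visit": "", "scanner": "", "condition": "",
                "n_components": decomposition.n_components}
    defaults.update(labels)
    return PeakRecord(side=side, voxel_index=tuple(int(i) for i in idx),
                      coord_mm=tuple(float(v) for v in mm),
                      peak_z=float(zmap[idx]), missing=False, **defaults)


def peak_table(records) -> pd.DataFrame:
    """Stack PeakRecords into the cohort peak table (the inter-stage CSV)."""
    rows = [r.as_row() for r in records]
    frame = pd.DataFrame(rows, columns=PEAK_COLUMNS)
    return frame
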