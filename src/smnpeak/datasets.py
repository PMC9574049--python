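"""Bundled reference data.

``load_reference_distances`` returns the per-subject intra-scanner (V1 vs
V2) Euclidean peak-distance tables, in mm, from a published 21-subject
test-retest study of the single-subject ICA-derived sensorimotor network
(one table per total-component setting: 20, 30, 40). They serve as desk
inputs for the distance summaries: the subject column is the published
subject label, the remaining columns are condition_side cells, and "-"
marks a run whose SMN component could not be identified (kept as NaN).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_reference_distances", "DISTANCE_CELLS"]

DISTANCE_CELLS = ("EO_left", "EO_right", "EC_left", "EC_right")


def load_reference_distances(n_components: int) -> pd.DataFrame:
    """Per-subject peak-distance table (mm) for 20, 30 or 40 components."""
    if n_components not in (20, 30, 40):
        raise ValueError("reference tables exist for 20, 30 and 40 components")
    ref = resources.files("smnpeak.data") / f"distances_{n_components}components.tsv"
    with resources.as_file(ref) as path:
        frame = pd.read_csv(path, sep="\t", na_values=["-"])
    return frame
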