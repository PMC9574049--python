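"""Test-retest reliability of peak coordinates.

Two families of statistics quantify how reproducible the SMN peak location
is across repeated sessions:

* the one-way intraclass correlation ICC(1,1) = (MSb - MSw) /
  (MSb + (K-1) MSw), computed separately for the x, y and z coordinate,
  with negative estimates truncated to 0 *before* the three axes are
  averaged (a negative one-way ICC estimate simply signals within-subject
  variance exceeding between-subject variance);
* per-subject Euclidean distances (mm) between the two sessions' peaks,
  summarized by mean and sample SD over the subjects with both sessions
  identified -- a run whose SMN was not identified contributes a missing
  entry, not a zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ICCResult",
    "DistanceTable",
    "icc_oneway",
    "truncated_average",
    "axis_averaged_icc",
    "peak_distances",
    "summarize_distances",
    "proportion_within",
]

AXES = ("x_mm", "y_mm", "z_mm")


@dataclass
class ICCResult:
    """Per-axis one-way ICCs for one (condition, side, visit-pair, setting)
    cell: raw estimates (may be negative), truncated values, and their
    average."""

    condition: str
    side: str
    visit_pair: tuple[str, str]
    n_components: int
    icc_x: float
    icc_y: float
    icc_z: float
    icc_x_trunc: float
    icc_y_trunc: float
    icc_z_trunc: float
    icc_avg: float
    n_subjects_used: int
    k_sessions: int = 2

    def __post_init__(self) -> None:
        expect = np.mean([self.icc_x_trunc, self.icc_y_trunc, self.icc_z_trunc])
        if abs(self.icc_avg - expect) > 1e-12:
            raise ValueError("icc_avg is not the mean of the truncated axes")
        if self.n_subjects_used < 2:
            raise ValueError("ICC needs at least 2 subjects")


@dataclass
class DistanceTable:
    """Per-subject between-session peak distances (mm) for one cell; a None
    distance marks a subject missing in either session."""

    condition: str
    side: str
    visit_pair: tuple[str, str]
    n_components: int
    distances: dict
    mean_mm: float
    std_mm: float
    n_used: int


def icc_oneway(values) -> tuple[float, float, float]:
    """One-way ICC from an (n subjects x K sessions) array.

    Returns (raw ICC, MSb, MSw) where MSb = K * sum_i (m_i - m)^2 / (n - 1)
    and MSw = sum_ik (m_ik - m_i)^2 / (n (K - 1)). The raw estimate may be
    negative; truncation is the caller's choice.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError("values must be a 2-D (subjects x sessions) array; "
                         "subjects with missing sessions must be dropped first")
    n, k = arr.shape
    if n < 2:
        raise ValueError(f"need >= 2 subjects, got {n}")
    if k < 2:
        raise ValueError(f"need >= 2 sessions per subject, got {k}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("values contain non-finite entries; drop incomplete "
                         "subjects upstream")
    subj_means = arr.mean(axis=1)
    grand = arr.mean()
    msb = k * np.sum((subj_means - grand) ** 2) / (n - 1)
    msw = np.sum((arr - subj_means[:, np.newaxis]) ** 2) / (n * (k - 1))
    denom = msb + (k - 1) * msw
    if denom == 0:
        raise ValueError("all values identical; ICC undefined (MSb + (K-1)MSw = 0)")
    return (msb - msw) / denom, msb, msw


def truncated_average(raw_iccs) -> tuple[np.ndarray, float]:
    """Truncate negative per-axis ICCs to 0, then average the axes.

    Truncation happens before averaging: raw (-0.3, 0.57, -0.1) averages to
    0.19, not 0.057.
    """
    raw = np.asarray(raw_iccs, dtype=float)
    truncated = np.maximum(raw, 0.0)
    return truncated, float(truncated.mean())


def _complete_subjects(peaks_a: pd.DataFrame, peaks_b: pd.DataFrame
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise exclusion: keep subjects non-missing in both sessions."""
    def usable(df):
        df = df.copy()
        if "missing" in df.columns:
            df = df[~df["missing"].astype(bool)]
        return df.set_index("subject")

    a, b = usable(peaks_a), usable(peaks_b)
    common = a.index.intersection(b.index)
    return a.loc[common], b.loc[common]


def axis_averaged_icc(peaks_a: pd.DataFrame, peaks_b: pd.DataFrame,
                      condition: str = "", side: str = "",
                      visit_pair: tuple[str, str] = ("A", "B"),
                      n_components: int = 0) -> ICCResult:
    """Per-axis one-way ICC (K = 2) of peak mm coordinates for one cell.

    ``peaks_a`` / ``peaks_b`` are peak-table frames for the two sessions of
    one (condition, side, setting) cell, one row per subject. Subjects
    missing in either session are excluded pairwise.
    """
    a, b = _complete_subjects(peaks_a, peaks_b)
    n = len(a)
    if n < 2:
        raise ValueError(
            f"cell ({condition}, {side}, {visit_pair}, {n_components}): only "
            f"{n} complete subject(s); ICC needs >= 2")
    raw = []
    for axis in AXES:
        pairs = np.column_stack([a[axis].to_numpy(float), b[axis].to_numpy(float)])
        icc, _, _ = icc_oneway(pairs)
        raw.append(icc)
    truncated, avg = truncated_average(raw)
    return ICCResult(condition=condition, side=side, visit_pair=visit_pair,
                     n_components=n_components,
                     icc_x=raw[0], icc_y=raw[1], icc_z=raw[2],
                     icc_x_trunc=truncated[0], icc_y_trunc=truncated[1],
                     icc_z_trunc=truncated[2], icc_avg=avg,
                     n_subjects_used=n, k_sessions=2)


def summarize_distances(distances) -> tuple[float, float, int]:
    """Mean and sample SD (n-1 denominator) over non-missing distances.

    ``distances`` maps subject -> distance in mm, with None/NaN for missing.
    """
    vals = np.array([v for v in dict(distances).values()
                     if v is not None and np.isfinite(v)], dtype=float)
    if vals.size == 0:
        raise ValueError("no non-missing distances to summarize")
    mean = float(vals.mean())
    std = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
    return mean, std, int(vals.size)


def peak_distances(peaks_a: pd.DataFrame, peaks_b: pd.DataFrame,
                   condition: str = "", side: str = "",
                   visit_pair: tuple[str, str] = ("A", "B"),
                   n_components: int = 0) -> DistanceTable:
    """Per-subject Euclidean distance (mm) between two sessions' peaks.

    A subject missing in either session gets a missing (None) distance and
    is excluded from the mean/SD.
    """
    def indexed(df):
        return df.set_index("subject")

    a, b = indexed(peaks_a), indexed(peaks_b)
    subjects = a.index.union(b.index)
    distances: dict = {}
    for subject in subjects:
        ok = (subject in a.index and subject in b.index
              and not bool(a.loc[subject].get("missing", False))
              and not bool(b.loc[subject].get("missing", False)))
        if not ok:
            distances[subject] = None
            continue
        pa = a.loc[subject, list(AXES)].to_numpy(float)
        pb = b.loc[subject, list(AXES)].to_numpy(float)
        distances[subject] = float(np.linalg.norm(pa - pb))
    mean, std, n_used = summarize_distances(distances)
    return DistanceTable(condition=condition, side=side, visit_pair=visit_pair,
                         n_components=n_components, distances=distances,
                         mean_mm=mean, std_mm=std, n_used=n_used)


def proportion_within(tables, lo_mm: float, hi_mm: float) -> float:
    """Fraction of all pooled non-missing distances d with lo <= d <= hi."""
    pooled = [v for table in tables for v in table.distances.values()
              if v is not None and np.isfinite(v)]
    if not pooled:
        raise ValueError("no non-missing distances pooled")
    pooled = np.asarray(pooled, dtype=float)
    return float(np.mean((pooled >= lo_mm) & (pooled <= hi_mm)))
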