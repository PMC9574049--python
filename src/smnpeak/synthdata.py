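"""Synthetic resting-state cohorts with a known sensorimotor-network peak.

The generator emulates the acquisition design the pipeline is meant for:
N subjects scanned at several visits (possibly on different scanners) under
eyes-open / eyes-closed conditions, each run an 8-minute BOLD series on an
MNI-like grid. Each run is a sum of spatial network sources (Gaussian blobs)
times AR(1)-smoothed random time courses, plus scanner-scaled Gaussian noise.
The bilateral SMN source is displaced rigidly per subject (between-subject
variance) and per session (within-subject variance), independently for the
left and right blobs, and the displaced peak coordinates are recorded as
ground truth. That makes the true between/within variance of the peak -- and
hence the population intraclass correlation -- a known quantity.

``simulate_peak_coordinates`` is a coordinate-only shortcut with the same
variance structure, used to validate the ICC estimator at large n.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .volume import Volume4D, save_mask, save_volume4d

__all__ = [
    "GridSpec",
    "SourceSpec",
    "CohortConfig",
    "DEFAULT_GRID",
    "REDUCED_GRID",
    "default_smn_source",
    "derive_seed",
    "make_grid_mask",
    "default_smn_mask",
    "brain_mask",
    "simulate_run",
    "simulate_cohort",
    "simulate_peak_coordinates",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class GridSpec:
    """A regular axis-aligned sampling grid in an MNI-like mm space."""

    shape: tuple[int, int, int] = (61, 73, 61)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    origin_mm: tuple[float, float, float] = (-90.0, -126.0, -72.0)

    def __post_init__(self) -> None:
        if any(n < 8 for n in self.shape):
            raise ValueError(f"grid shape entries must be >= 8, got {self.shape}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size_mm)
        aff[:3, 3] = self.origin_mm
        return aff

    def mm_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Meshgrid (x, y, z) of voxel-center mm coordinates."""
        axes = [
            o + v * np.arange(n)
            for n, v, o in zip(self.shape, self.voxel_size_mm, self.origin_mm)
        ]
        return np.meshgrid(*axes, indexing="ij")

    def contains_mm(self, point) -> bool:
        p = np.asarray(point, dtype=float)
        lo = np.asarray(self.origin_mm)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.voxel_size_mm)
        return bool(np.all(p >= lo - 1e-9) and np.all(p <= hi + 1e-9))


#: Standard-resolution MNI-like grid (3 mm, 61 x 73 x 61).
DEFAULT_GRID = GridSpec()

#: Same bounding box at 6 mm -- used for fast reduced-scale cohorts.
REDUCED_GRID = GridSpec(shape=(31, 37, 31), voxel_size_mm=(6.0, 6.0, 6.0))


@dataclass(frozen=True)
class SourceSpec:
    """One spatial network source: a set of Gaussian blobs plus an AR(1)
    temporal smoothness coefficient in [0, 1)."""

    name: str
    blobs: tuple  # of (center_mm triple, fwhm_mm, amplitude)
    temporal_smoothness: float = 0.3

    def __post_init__(self) -> None:
        if len(self.blobs) == 0:
            raise ValueError(f"source {self.name!r} needs at least one blob")
        for center, fwhm, amp in self.blobs:
            if fwhm <= 0:
                raise ValueError("blob fwhm must be positive")
            if not np.all(np.isfinite([*center, fwhm, amp])):
                raise ValueError("blob parameters must be finite")
        if not (0.0 <= self.temporal_smoothness < 1.0):
            raise ValueError("temporal_smoothness must be in [0, 1)")


def default_smn_source(fwhm_mm: float = 20.0) -> SourceSpec:
    """Bilateral sensorimotor source: one blob per precentral hand area."""
    return SourceSpec(
        name="SMN",
        blobs=(((-38.0, -22.0, 52.0), fwhm_mm, 1.0), ((38.0, -22.0, 52.0), fwhm_mm, 1.0)),
    )


def _default_sources() -> tuple[SourceSpec, ...]:
    return (
        default_smn_source(),
        SourceSpec("visual", blobs=(((0.0, -82.0, 2.0), 22.0, 1.0),)),
        SourceSpec("medial-frontal", blobs=(((0.0, 44.0, 10.0), 22.0, 1.0),)),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Design and variance structure of a synthetic cohort.

    The defaults mirror the acquisition design the pipeline targets:
    21 subjects, visits V1/V2 on one scanner and V3 on another, EO and EC
    conditions, 240 volumes at TR = 2 s. ``sigma_between_mm`` and
    ``sigma_within_mm`` are the per-axis SDs of the rigid SMN displacement
    and are the simulator's ground truth for reliability.
    """

    n_subjects: int = 21
    visits: tuple = (("V1", "scannerA"), ("V2", "scannerA"), ("V3", "scannerB"))
    conditions: tuple = ("EO", "EC")
    n_volumes: int = 240
    tr_s: float = 2.0
    grid: GridSpec = DEFAULT_GRID
    sources: tuple = field(default_factory=_default_sources)
    sigma_between_mm: float = 6.0
    sigma_within_mm: float = 3.0
    scanner_noise_scale: tuple = (("scannerA", 1.0), ("scannerB", 1.2))
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_volumes < 1:
            raise ValueError("n_volumes must be >= 1")
        if self.sigma_between_mm < 0 or self.sigma_within_mm < 0:
            raise ValueError("sigmas must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        names = [s.name for s in self.sources]
        if names.count("SMN") != 1:
            raise ValueError("config must contain exactly one source named 'SMN'")
        scanners_used = {sc for _, sc in self.visits}
        known = {sc for sc, _ in self.scanner_noise_scale}
        if not scanners_used <= known:
            raise ValueError(f"no noise scale for scanners {scanners_used - known}")

    @property
    def visit_ids(self) -> list[str]:
        return [v for v, _ in self.visits]

    def scanner_of(self, visit_id: str) -> str:
        for v, sc in self.visits:
            if v == visit_id:
                return sc
        raise KeyError(f"unknown visit {visit_id!r}")

    def noise_scale_of(self, scanner_id: str) -> float:
        return dict(self.scanner_noise_scale)[scanner_id]

    @property
    def smn_source(self) -> SourceSpec:
        return next(s for s in self.sources if s.name == "SMN")


def derive_seed(base_seed: int, *keys) -> int:
    """Stable per-run seed < 2**31 from a base seed and hashable keys.

    Uses SHA-256 of the repr of the key tuple, so the mapping is identical
    across platforms and Python processes (unlike the built-in ``hash``).
    """
    digest = hashlib.sha256(repr((int(base_seed), *keys)).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _gaussian_profile(grid: GridSpec, blobs) -> np.ndarray:
    """Max over blobs of amplitude * exp(-d^2 / 2 sigma^2) on the grid."""
    xx, yy, zz = grid.mm_coordinates()
    profile = np.zeros(grid.shape)
    for center, fwhm, amplitude in blobs:
        sigma = fwhm * FWHM_TO_SIGMA
        d2 = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 + (zz - center[2]) ** 2
        np.maximum(profile, amplitude * np.exp(-d2 / (2.0 * sigma**2)), out=profile)
    return profile


def make_grid_mask(grid: GridSpec, blobs, threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """Binary mask of voxels where the max Gaussian blob profile exceeds
    ``threshold``; returns (mask, affine).

    Used to build a parametric SMN mask (one blob per pre/postcentral hand
    area, optionally one for the SMA) when no atlas-derived mask is supplied.
    """
    if len(blobs) == 0:
        raise ValueError("need at least one blob")
    for center, _, _ in blobs:
        if not grid.contains_mm(center):
            raise ValueError(f"blob center {tuple(center)} lies outside the grid")
    profile = _gaussian_profile(grid, blobs)
    mask = profile > threshold
    if not mask.any():
        raise ValueError(
            f"threshold {threshold} exceeds every blob profile value "
            f"(max {profile.max():.4g}); mask would be empty"
        )
    return mask, grid.affine


def default_smn_mask(grid: GridSpec, source: SourceSpec | None = None,
                     widen: float = 2.0, threshold: float = 0.1) -> np.ndarray:
    """Generous SMN search mask around the source blobs.

    The anatomical SMN (bilateral pre/postcentral gyri plus SMA) is far
    larger than the core of the network's activation blob, so the default
    mask widens each blob's FWHM by ``widen`` before thresholding -- peaks
    displaced between subjects or sessions still fall inside it.
    """
    source = source or default_smn_source()
    blobs = tuple((c, fwhm * widen, amp) for c, fwhm, amp in source.blobs)
    mask, _ = make_grid_mask(grid, blobs, threshold)
    return mask


def brain_mask(grid: GridSpec) -> np.ndarray:
    """Synthetic 'brain' support: a superellipsoid filling most of the grid."""
    xx, yy, zz = grid.mm_coordinates()
    lo = np.asarray(grid.origin_mm)
    hi = lo + (np.asarray(grid.shape) - 1) * np.asarray(grid.voxel_size_mm)
    center = (lo + hi) / 2.0
    semi = 0.95 * (hi - lo) / 2.0
    r = (
        ((xx - center[0]) / semi[0]) ** 4
        + ((yy - center[1]) / semi[1]) ** 4
        + ((zz - center[2]) / semi[2]) ** 4
    )
    return r <= 1.0


def _ar1_timecourse(rng: np.random.Generator, n: int, phi: float) -> np.ndarray:
    """AR(1) series with unit marginal variance."""
    eps = rng.standard_normal(n)
    if phi == 0.0:
        return eps
    tc = np.empty(n)
    tc[0] = eps[0]
    scale = np.sqrt(1.0 - phi**2)
    for t in range(1, n):
        tc[t] = phi * tc[t - 1] + scale * eps[t]
    return tc


def _constrain_center(center: np.ndarray, base: np.ndarray, grid: GridSpec,
                      mask: np.ndarray) -> np.ndarray:
    """Pull a displaced blob center back toward its undisplaced position until
    it falls inside the brain mask (keeps every true peak inside the brain)."""
    inv_vox = 1.0 / np.asarray(grid.voxel_size_mm)
    origin = np.asarray(grid.origin_mm)
    for _ in range(64):
        idx = np.rint((center - origin) * inv_vox).astype(int)
        if np.all(idx >= 0) and np.all(idx < mask.shape) and mask[tuple(idx)]:
            return center
        center = base + 0.9 * (center - base)
    return base.copy()


def _smn_truth_and_blobs(config: CohortConfig, base_seed: int, subject: int,
                         visit_id: str, condition: str, grid: GridSpec,
                         bmask: np.ndarray):
    """Displaced SMN blob set and the true left/right peak mm coordinates.

    The whole blob is moved rigidly: a per-subject offset (drawn once per
    subject and side from N(0, sigma_between^2) per axis, identical across
    visits and conditions) plus a per-session offset from
    N(0, sigma_within^2). Left (center x < 0) and right blobs move
    independently, so the two sides can have distinct reliability.
    """
    smn = config.smn_source
    new_blobs = []
    truth: dict[str, list[float]] = {}
    for center, fwhm, amp in smn.blobs:
        side = "left" if center[0] < 0 else "right"
        sub_rng = np.random.default_rng(
            derive_seed(base_seed, "subject-offset", subject, side))
        ses_rng = np.random.default_rng(
            derive_seed(base_seed, "session-offset", subject, visit_id, condition, side))
        offset = (config.sigma_between_mm * sub_rng.standard_normal(3)
                  + config.sigma_within_mm * ses_rng.standard_normal(3))
        base = np.asarray(center, dtype=float)
        new_center = _constrain_center(base + offset, base, grid, bmask)
        new_blobs.append((tuple(new_center), fwhm, amp))
        # one blob per side in the default SMN; with several, the
        # highest-amplitude blob defines the side's true peak
        if side not in truth or amp > truth[side][1]:
            truth[side] = [new_center.tolist(), amp]
    return tuple(new_blobs), {k: v[0] for k, v in truth.items()}


def simulate_run(config: CohortConfig, subject: int, visit_id: str,
                 condition: str, seed: int | None = None
                 ) -> tuple[Volume4D, dict]:
    """Simulate one BOLD run; returns (Volume4D, ground-truth record).

    The run is a sum over sources of (spatial map x AR(1) time course) plus
    scanner-scaled i.i.d. Gaussian noise. ``seed`` overrides the config's
    base seed; identical (config, subject, visit, condition, seed) gives
    bit-identical output.
    """
    if not (0 <= subject < config.n_subjects):
        raise ValueError(f"subject {subject} outside 0..{config.n_subjects - 1}")
    if visit_id not in config.visit_ids:
        raise ValueError(f"unknown visit {visit_id!r}; have {config.visit_ids}")
    if condition not in config.conditions:
        raise ValueError(f"unknown condition {condition!r}; have {list(config.conditions)}")

    grid = config.grid
    bmask = brain_mask(grid)
    base_seed = config.seed if seed is None else seed
    run_seed = derive_seed(base_seed, "run", subject, visit_id, condition)
    rng = np.random.default_rng(run_seed)

    data = np.zeros((*grid.shape, config.n_volumes))
    truth_peaks: dict[str, list[float]] = {}
    for source in config.sources:
        if source.name == "SMN":
            blobs, truth_peaks = _smn_truth_and_blobs(
                config, base_seed, subject, visit_id, condition, grid, bmask)
        else:
            blobs = source.blobs
        smap = _gaussian_profile(grid, blobs)
        tc = _ar1_timecourse(rng, config.n_volumes, source.temporal_smoothness)
        data += smap[..., np.newaxis] * tc

    scanner = config.scanner_of(visit_id)
    sd = config.noise_sd * config.noise_scale_of(scanner)
    if sd > 0:
        data += sd * rng.standard_normal(data.shape)

    vol = Volume4D(data=data, affine=grid.affine, tr_s=config.tr_s)
    truth = {
        "subject": subject,
        "visit": visit_id,
        "scanner": scanner,
        "condition": condition,
        "seed": run_seed,
        "smn_peak_mm": truth_peaks,
    }
    return vol, truth


def simulate_cohort(config: CohortConfig, out_dir) -> pd.DataFrame:
    """Write one 4-D NIfTI per (subject, visit, condition) plus the brain
    mask, the SMN mask, a manifest CSV and a ground-truth JSON sidecar.

    Returns the manifest (columns: subject, visit, scanner, condition, path).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    grid = config.grid
    save_mask(brain_mask(grid), grid.affine, out_dir / "brain_mask.nii.gz")
    save_mask(default_smn_mask(grid, config.smn_source), grid.affine,
              out_dir / "smn_mask.nii.gz")

    rows = []
    truths = []
    for subject in range(config.n_subjects):
        for visit_id, scanner in config.visits:
            for condition in config.conditions:
                vol, truth = simulate_run(config, subject, visit_id, condition)
                name = f"sub{subject:03d}_{visit_id}_{condition}.nii.gz"
                try:
                    save_volume4d(vol, out_dir / name)
                except OSError as exc:
                    raise OSError(f"failed writing {out_dir / name}: {exc}") from exc
                rows.append({"subject": subject, "visit": visit_id,
                             "scanner": scanner, "condition": condition,
                             "path": name})
                truths.append(truth)

    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    (out_dir / "ground_truth.json").write_text(json.dumps(truths, indent=1))
    return manifest


def simulate_peak_coordinates(mu, sigma_between: float, sigma_within: float,
                              n_subjects: int, k_sessions: int, seed: int
                              ) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate per-session peak coordinates with a known variance split.

    coordinate = mu + subject effect (SD sigma_between per axis)
                    + session noise (SD sigma_within per axis).

    Returns a long table (subject, session, x_mm, y_mm, z_mm) and the
    analytic true ICC per axis, sigma_b^2 / (sigma_b^2 + sigma_w^2) -- the
    population quantity the one-way ICC estimates.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if k_sessions < 2:
        raise ValueError("need at least 2 sessions")
    if sigma_between < 0 or sigma_within < 0:
        raise ValueError("sigmas must be non-negative")
    if sigma_between == 0 and sigma_within == 0:
        raise ValueError("both variance components are zero; ICC is undefined")

    rng = np.random.default_rng(seed)
    mu = np.asarray(mu, dtype=float)
    subj = sigma_between * rng.standard_normal((n_subjects, 1, 3))
    ses = sigma_within * rng.standard_normal((n_subjects, k_sessions, 3))
    coords = mu[np.newaxis, np.newaxis, :] + subj + ses

    records = [
        {"subject": i, "session": k,
         "x_mm": coords[i, k, 0], "y_mm": coords[i, k, 1], "z_mm": coords[i, k, 2]}
        for i in range(n_subjects) for k in range(k_sessions)
    ]
    denom = sigma_between**2 + sigma_within**2
    true_icc = np.full(3, sigma_between**2 / denom)
    return pd.DataFrame(records), true_icc
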