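# Methods

This note documents the models, numerical choices and limitations behind
`smnpeak`, in the package's own words.

## Synthetic cohort model

Each simulated run is

    Y(v, t) = Σ_s M_s(v) · a_s(t) + σ_scanner · ε(v, t)

with `M_s` the spatial map of source *s* (max over Gaussian blobs of
`amplitude · exp(−d²/2σ²)`, σ = FWHM/2.35482), `a_s` an AR(1) series with
unit marginal variance and coefficient `temporal_smoothness` (default 0.3),
and ε i.i.d. standard normal scaled by `noise_sd` times a per-scanner
factor. Spatial maps are super-Gaussian (sparse), which is what makes the
spatial-ICA model identifiable; the temporal model is deliberately simple
because the analysis treats time courses as nuisance mixing.

The SMN source has one blob per hemisphere (default centers (±38, −22, 52)
mm, FWHM 20 mm — the precentral hand-knob region on an MNI-like grid).
For each (subject, side) a rigid offset is drawn from
N(0, `sigma_between_mm`² I₃) once, and for each (subject, session, side)
an additional offset from N(0, `sigma_within_mm`² I₃); left and right move
independently so the two sides can have distinct reliability. The
displaced blob center is the run's true peak, recorded as ground truth.
With this construction the population intraclass correlation of the peak
coordinate per axis is exactly σ²ᵦ/(σ²ᵦ+σ²𝓌), which is what
`simulate_peak_coordinates` returns analytically and what the estimator
tests check against.

Defaults mirror the target acquisition design: 21 subjects; visits V1/V2
on one scanner and V3 on a second with a 1.2× noise scale; EO and EC
conditions; 240 volumes at TR = 2 s; a 61×73×61 grid at 3 mm with origin
(−90, −126, −72). The normalized grid is a declared assumption — published
integer distance tables do not pin down a unique grid. A 31×37×31 / 6 mm
grid (`REDUCED_GRID`, same bounding box) is provided for fast cohorts; the
test suite and examples use it with 80 volumes and 3–8 subjects so a full
synthetic experiment runs in minutes on one CPU.

Two containment rules keep the geometry sane: the synthetic "brain" is a
superellipsoid (exponent 4, semi-axes 0.95× the half-extents), and a
displaced blob center that would leave it is damped back toward its
undisplaced position in 0.9× steps until inside. This truncates extreme
displacement draws, so at very large sigmas the realized variance is
slightly below nominal; the variance-bookkeeping test uses sigmas small
enough that truncation never triggers.

The default SMN *search mask* (`default_smn_mask`) widens the source blobs'
FWHM by 2× before thresholding at 0.1 of the peak profile. Rationale: the
anatomical SMN (bilateral pre/postcentral gyri plus SMA) is much larger
than the activation core, and the mask must contain the peak wherever
between-subject/session displacement puts it. Any user-supplied mask on
the same grid can be substituted.

What the generator does **not** emulate: head motion, slice timing,
physiological noise, EPI distortion, Rician noise, spatial
autocorrelation of the noise, or any real inter-scanner difference beyond
a noise/intensity scale. Passing synthetic tests therefore demonstrates
the correctness and statistical calibration of the measurement chain, not
its robustness to real-scanner artifacts.

## Preprocessing

Only two steps are in scope: dropping the first `n_discard` volumes
(default 10) and separable Gaussian smoothing (default FWHM 6 mm).
Smoothing converts FWHM to a per-axis sigma in voxel units from the
affine's column norms, so anisotropic voxels are handled; only
axis-aligned affines are accepted. Boundary handling is nearest-edge
replication, chosen so results are bit-stable and mass is approximately
preserved in the interior. Slice timing, realignment and normalization
are out of scope — real data must arrive already in a common space.

## ICA engine

Whitening removes each voxel's temporal mean and then each frame's
spatial mean before the SVD. The second centering is a numerical choice:
it puts the retained principal-component rows at exactly zero spatial
mean, so "unit variance, zero correlation" holds in the Pearson sense to
machine precision rather than only approximately.

Infomax uses the logistic nonlinearity with the natural-gradient update
`ΔW = lr (I + (1−2g(u))uᵀ/b) W` over shuffled voxel blocks
(block ≈ max(256, √(v/3))), initial rate 0.01, annealing ×0.9 when
successive weight updates turn by more than 60°, halving with rollback on
a non-finite update, tolerance 1e-6 on the relative weight change, at most
512 passes. The published procedure names only "the Infomax algorithm"
and a convergence threshold without values; these defaults follow common
practice for runica-style implementations. A non-convergent run is kept
with a warning (stability selection is the guard), matching how repeated-
run stability toolboxes treat such runs.

Stability selection pools the maps of `n_runs` (default 20) randomly
initialized runs, clusters them into `n_components` clusters by
average-linkage agglomeration on 1 − |Pearson r|, and returns each
cluster's centrotype (member with maximal summed intra-cluster
similarity). The stability index is mean intra-cluster |r| minus mean
extra-cluster |r|, clipped to [0, 1]; a singleton cluster's intra term
is 1. Components are ordered by decreasing stability.

Each map is z-scored over in-brain voxels and its sign (map and time
course together) flipped so the in-mask skewness is non-negative. The
sign convention makes the conventional threshold z > 1 select the
activated side; binarization is applied to signed z, not |z|.

## SMN identification and peaks

Components are ranked by Dice with the full SMN mask (ties → lower
index). The laterality index of a component is (D_L − D_R)/(D_L + D_R)
using the mask halves at mm x = 0 (voxels exactly at x = 0 belong to
neither half). Defaults: `dice_floor` 0.10, `laterality_cut` 0.5, both
config-exposed — the published procedure relied on visual inspection here,
so these thresholds are this package's operationalization, not an
inference of the original criteria. If the top component is lateralized
but no opposite-side partner passes both cuts, the run falls back to
bilateral mode with the top component (the unstated corner case). A run
whose best Dice is below the floor is recorded as unidentified and
propagates as missing data.

The peak is the arg-max of the (unthresholded) selected z-map within each
mask half; ties break to the lexicographically smallest (x, y, z) index.
Whether the original analysis searched thresholded or unthresholded maps
is unknown; unthresholded is used because the arg-max is invariant to any
threshold below the maximum.

## Reliability statistics

`icc_oneway` implements the one-way random-effects ICC(1,1):
MSᵦ = K·Σᵢ(m̄ᵢ−m̄)²/(n−1), MS𝓌 = ΣᵢΣₖ(mᵢₖ−m̄ᵢ)²/(n(K−1)),
ICC = (MSᵦ−MS𝓌)/(MSᵦ+(K−1)MS𝓌). Estimates below 0 (within-variance
dominating) are kept in the result but truncated to 0 per axis **before**
the three axes are averaged — the order matters: raw (−0.3, 0.57, −0.1)
averages to 0.19, not 0.06, and only the truncate-first rule reproduces
published table arithmetic. ICCs are computed on mm coordinates (the unit
of the published distance tables); subjects missing in either session of
a pair are excluded pairwise, and a cell with fewer than two complete
subjects is an error naming the cell.

Distances are per-subject Euclidean norms in mm; summaries use the sample
SD (n−1) over non-missing entries only. `proportion_within` pools
distances across tables with an inclusive band. Reports round to two
decimals for display while keeping full precision in numeric columns.
Confidence intervals, two-way ICC variants and Bland–Altman analysis are
intentionally out of scope.

## Determinism

Every stochastic step takes a seed. Per-run seeds derive from the base
seed via SHA-256 of the (seed, role, subject, visit, condition, …) tuple,
truncated below 2³¹ — stable across platforms and processes. Identical
configs reproduce bit-identical cohorts and byte-identical reports.

## Problem sizes

The synthetic experiments in the test suite run on the reduced grid with
80-volume runs, 2–8 subjects, 5–8 requested components and 1–5 stability
runs; the estimator-calibration checks use 2000 simulated subjects. These
sizes were chosen as the smallest at which each effect being tested is
comfortably measurable, and keep the whole suite within a few minutes on
a single CPU.
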