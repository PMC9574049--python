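"""Single-subject spatial ICA with stability selection.

The decomposition model is the one standard for resting-state fMRI: the
voxel-by-time data matrix is expressed as a temporal mixing matrix times a
set of spatially independent source maps. The steps are

1. PCA whitening of the (time x voxel) matrix to ``n_components`` rows
   (:func:`pca_whiten`),
2. natural-gradient Infomax with a logistic nonlinearity on the whitened
   spatial data (:func:`infomax`) -- maximum-likelihood separation for
   super-Gaussian spatial sources,
3. stability selection over repeated randomly initialized runs: all runs'
   maps are pooled, clustered by average-linkage on 1 - |spatial r|, and
   each cluster's centrotype is returned together with a stability index
   (:func:`icasso_decompose`),
4. conversion of each map to z-scores over in-brain voxels with the sign
   aligned so the in-mask skewness is non-negative (:func:`zscore_align`),
   which makes a positive z threshold select the activated side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .volume import Volume4D

__all__ = [
    "WhitenedData",
    "ComponentMap",
    "ICADecomposition",
    "pca_whiten",
    "infomax",
    "icasso_decompose",
    "zscore_align",
]


@dataclass
class WhitenedData:
    """PCA-reduced spatial data: ``reduced`` is (n_components x n_in-mask
    voxels) with zero-mean, unit-variance, mutually uncorrelated rows."""

    reduced: np.ndarray
    whitening: np.ndarray      # (n_components x t): reduced = whitening @ centered
    dewhitening: np.ndarray    # (t x n_components): centered ~= dewhitening @ reduced
    mask_indices: np.ndarray   # flat indices of in-mask voxels (C order)
    explained_variance: np.ndarray
    voxel_mean: np.ndarray     # per-voxel temporal mean removed
    frame_mean: np.ndarray     # per-frame spatial mean removed (after the above)
    shape3d: tuple[int, int, int]


@dataclass
class ComponentMap:
    """One ICA component: spatial map, time course, and stability index."""

    zmap: np.ndarray           # 3-D; off-mask voxels are 0
    timecourse: np.ndarray
    stability_iq: float
    sign_aligned: bool = False
    zscored: bool = False


@dataclass
class ICADecomposition:
    components: list
    n_components: int
    mask: np.ndarray
    affine: np.ndarray
    converged: bool
    seed: int

    def __post_init__(self) -> None:
        if len(self.components) != self.n_components:
            raise ValueError("component count does not match request")


def center_voxel_time(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Remove each voxel's temporal mean, then each frame's spatial mean.

    The second centering puts every row of the retained PCA subspace at
    exactly zero spatial mean, so whitened rows are uncorrelated in the
    Pearson sense, not just orthogonal.
    """
    voxel_mean = matrix.mean(axis=0)
    centered = matrix - voxel_mean
    frame_mean = centered.mean(axis=1)
    centered -= frame_mean[:, np.newaxis]
    return centered, voxel_mean, frame_mean


def pca_whiten(vol: Volume4D, brain_mask: np.ndarray, n_components: int) -> WhitenedData:
    """Whiten the in-mask (time x voxel) matrix to ``n_components`` rows."""
    mask = np.asarray(brain_mask, dtype=bool)
    if mask.shape != vol.shape3d:
        raise ValueError("mask shape does not match volume")
    n_voxels = int(mask.sum())
    if n_voxels == 0:
        raise ValueError("brain mask is empty")
    t = vol.n_volumes
    limit = min(t, n_voxels)
    if not (1 <= n_components <= limit):
        raise ValueError(
            f"n_components={n_components} must be in [1, {limit}] "
            f"(t={t}, in-mask voxels={n_voxels})")

    flat = vol.data.reshape(-1, t)
    mask_idx = np.flatnonzero(mask.ravel())
    matrix = flat[mask_idx].T                      # (t x v)
    centered, voxel_mean, frame_mean = center_voxel_time(matrix)

    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[n_components - 1] < 1e-12 * max(s[0], 1e-300):
        raise ValueError(
            f"data rank < n_components={n_components}; reduce the request")
    scale = np.sqrt(n_voxels)
    reduced = scale * vt[:n_components]
    whitening = scale * (u[:, :n_components] / s[:n_components]).T
    dewhitening = u[:, :n_components] * s[:n_components] / scale
    explained = (s**2 / np.sum(s**2))[:n_components]
    return WhitenedData(reduced=reduced, whitening=whitening,
                        dewhitening=dewhitening, mask_indices=mask_idx,
                        explained_variance=explained, voxel_mean=voxel_mean,
                        frame_mean=frame_mean, shape3d=vol.shape3d)


def _sigmoid(u: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(u, -60.0, 60.0)))


def infomax(whitened: WhitenedData, seed: int, lr0: float = 0.01,
            tol: float = 1e-6, max_iter: int = 512
            ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Natural-gradient Infomax with a logistic nonlinearity.

    Returns (square unmixing matrix W, source maps W @ reduced, converged).
    The weight update per block B of whitened columns is
    ``dW = lr * (I + (1 - 2 g(u)) u^T / b) W`` with ``u = W B`` and logistic
    ``g``; the learning rate anneals when successive updates turn by more
    than 60 degrees, and halves (restoring the previous weights) on a
    non-finite update.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    z = whitened.reduced
    n, v = z.shape
    rng = np.random.default_rng(seed)
    w, _ = np.linalg.qr(rng.standard_normal((n, n)))

    lr = lr0
    block = int(min(v, max(256, np.floor(np.sqrt(v / 3.0)))))
    eye = np.eye(n)
    prev_step = None
    converged = False
    for _ in range(max_iter):
        w_old = w.copy()
        order = rng.permutation(v)
        blew_up = False
        for start in range(0, v, block):
            cols = order[start:start + block]
            u = w @ z[:, cols]
            y = _sigmoid(u)
            w = w + lr * ((eye + (1.0 - 2.0 * y) @ u.T / len(cols)) @ w)
            if not np.all(np.isfinite(w)):
                blew_up = True
                break
        if blew_up:
            lr *= 0.5
            w = w_old
            if lr < 1e-12:
                raise FloatingPointError(
                    "Infomax diverged: weights non-finite even at the "
                    "smallest learning rate")
            continue
        step = w - w_old
        change = np.linalg.norm(step) / max(np.linalg.norm(w_old), 1e-300)
        if prev_step is not None:
            denom = np.linalg.norm(step) * np.linalg.norm(prev_step)
            if denom > 0:
                cosang = np.clip(np.sum(step * prev_step) / denom, -1.0, 1.0)
                if np.degrees(np.arccos(cosang)) > 60.0:
                    lr *= 0.9
        prev_step = step
        if change < tol:
            converged = True
            break
    return w, w @ z, converged


def _abs_correlation(maps: np.ndarray) -> np.ndarray:
    """|Pearson r| between rows (spatial maps)."""
    centered = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    norms[norms == 0] = 1.0
    unit = centered / norms[:, np.newaxis]
    sim = np.abs(unit @ unit.T)
    np.clip(sim, 0.0, 1.0, out=sim)
    return sim


def icasso_decompose(vol: Volume4D, brain_mask: np.ndarray, n_components: int,
                     n_runs: int = 20, seed: int = 0, lr0: float = 0.01,
                     tol: float = 1e-6, max_iter: int = 512) -> ICADecomposition:
    """Repeated-run ICA with stability clustering.

    Infomax is run ``n_runs`` times with seeds ``seed .. seed+n_runs-1``; the
    pooled maps are clustered (average linkage on 1 - |r|) into
    ``n_components`` clusters; each returned component is its cluster's
    centrotype (the member with maximal summed intra-cluster similarity) and
    carries ``stability_iq`` = mean intra-cluster |r| minus mean
    extra-cluster |r| (1 for a perfectly reproducible component).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    white = pca_whiten(vol, brain_mask, n_components)

    all_maps, all_tcs = [], []
    n_converged = 0
    failures: list[str] = []
    for run in range(n_runs):
        try:
            w, sources, conv = infomax(white, seed=seed + run, lr0=lr0,
                                       tol=tol, max_iter=max_iter)
        except FloatingPointError as exc:   # run failed outright
            failures.append(f"run {run}: {exc}")
            continue
        if not conv:
            warnings.warn(f"Infomax run {run} did not reach tol={tol}; "
                          "run retained", RuntimeWarning, stacklevel=2)
        n_converged += int(conv)
        mixing = white.dewhitening @ np.linalg.inv(w)   # (t x n)
        all_maps.append(sources)
        all_tcs.append(mixing.T)
    if not all_maps:
        raise RuntimeError("all ICA runs failed: " + "; ".join(failures))

    maps = np.vstack(all_maps)                     # (n_runs*n x v)
    tcs = np.vstack(all_tcs)
    sim = _abs_correlation(maps)
    m = maps.shape[0]
    if m == n_components:
        labels = np.arange(m)
    else:
        dist = squareform(1.0 - sim, checks=False)
        tree = linkage(dist, method="average")
        labels = fcluster(tree, t=n_components, criterion="maxclust") - 1
    if len(np.unique(labels)) != n_components:
        raise RuntimeError(
            f"clustering produced {len(np.unique(labels))} clusters for "
            f"{n_components} components (degenerate pooled maps)")

    components = []
    for cluster in np.unique(labels):
        inside = np.flatnonzero(labels == cluster)
        outside = np.flatnonzero(labels != cluster)
        sub = sim[np.ix_(inside, inside)]
        centrotype = inside[np.argmax(sub.sum(axis=1))]
        if len(inside) > 1:
            intra = (sub.sum() - len(inside)) / (len(inside) * (len(inside) - 1))
        else:
            intra = 1.0
        extra = sim[np.ix_(inside, outside)].mean() if len(outside) else 0.0
        iq = float(np.clip(intra - extra, 0.0, 1.0))

        zmap = np.zeros(np.prod(white.shape3d))
        zmap[white.mask_indices] = maps[centrotype]
        components.append(ComponentMap(zmap=zmap.reshape(white.shape3d),
                                       timecourse=tcs[centrotype].copy(),
                                       stability_iq=iq))
    components.sort(key=lambda c: -c.stability_iq)

    return ICADecomposition(components=components, n_components=n_components,
                            mask=np.asarray(brain_mask, dtype=bool),
                            affine=vol.affine,
                            converged=(n_converged == len(all_maps)), seed=seed)


def zscore_align(decomposition: ICADecomposition) -> ICADecomposition:
    """Standardize each map over in-mask voxels and align its sign.

    After this step each map has in-mask mean 0 and SD 1, off-mask voxels 0,
    and non-negative in-mask skewness (map and time course flipped together
    when needed), so thresholding at a positive z keeps the activated side.
    """
    mask = decomposition.mask
    out = []
    for i, comp in enumerate(decomposition.components):
        vals = comp.zmap[mask]
        sd = vals.std()
        if sd == 0:
            raise ValueError(f"component {i} is constant within the mask; "
                             "cannot z-score")
        zvals = (vals - vals.mean()) / sd
        tc = comp.timecourse
        if np.mean(zvals**3) < 0:
            zvals = -zvals
            tc = -tc
        zmap = np.zeros_like(comp.zmap)
        zmap[mask] = zvals
        out.append(replace(comp, zmap=zmap, timecourse=tc,
                           sign_aligned=True, zscored=True))
    return replace(decomposition, components=out)
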