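"""PCA whitening, Infomax separation, stability clustering, z-scoring."""

import warnings

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from smnpeak import (Volume4D, dice_coefficient, icasso_decompose, infomax,
                     pca_whiten, zscore_align)
from smnpeak.ica import center_voxel_time


def matrix_as_volume(matrix: np.ndarray) -> Volume4D:
    """(t x v) matrix laid out as a (v1, v2, 1, t) volume."""
    t, v = matrix.shape
    a = v // 50 if v % 50 == 0 else v
    b = v // a
    data = np.ascontiguousarray(matrix.T.reshape(a, b, 1, t))
    return Volume4D(data, np.eye(4))


def full_mask(vol: Volume4D) -> np.ndarray:
    return np.ones(vol.shape3d, dtype=bool)


class TestWhitening:
    def test_rows_unit_variance_uncorrelated(self, rng):
        vol = Volume4D(rng.standard_normal((8, 8, 8, 24)), np.eye(4))
        white = pca_whiten(vol, full_mask(vol), 6)
        cov = np.cov(white.reduced, ddof=0)
        np.testing.assert_allclose(cov, np.eye(6), atol=1e-8)
        np.testing.assert_allclose(white.reduced.mean(axis=1), 0.0, atol=1e-10)

    def test_explained_variance_contract(self, rng):
        vol = Volume4D(rng.standard_normal((8, 8, 8, 24)), np.eye(4))
        white = pca_whiten(vol, full_mask(vol), 6)
        ev = white.explained_variance
        assert np.all(np.diff(ev) <= 1e-15)
        assert np.all(ev > 0) and np.all(ev <= 1) and ev.sum() <= 1 + 1e-12

    def test_rank2_reconstruction(self, rng):
        sources = rng.laplace(size=(2, 2500))
        mixing = rng.standard_normal((12, 2))
        vol = matrix_as_volume(mixing @ sources)
        white = pca_whiten(vol, full_mask(vol), 2)
        matrix = vol.data.reshape(-1, 12).T
        centered, _, _ = center_voxel_time(matrix)
        recon = white.dewhitening @ white.reduced
        assert (np.linalg.norm(recon - centered)
                <= 1e-6 * np.linalg.norm(centered))

    def test_too_many_components_error_names_both_limits(self, rng):
        vol = Volume4D(rng.standard_normal((8, 8, 8, 10)), np.eye(4))
        with pytest.raises(ValueError, match=r"t=10.*voxels=512"):
            pca_whiten(vol, full_mask(vol), 11)

    def test_empty_mask_rejected(self, rng):
        vol = Volume4D(rng.standard_normal((8, 8, 8, 10)), np.eye(4))
        with pytest.raises(ValueError, match="empty"):
            pca_whiten(vol, np.zeros(vol.shape3d, bool), 2)


class TestInfomax:
    def make_whitened(self, seed=0, n_sources=2, v=5000):
        rng = np.random.default_rng(seed)
        sources = rng.laplace(size=(n_sources, v))
        mixing = rng.standard_normal((2 * n_sources, n_sources))
        vol = matrix_as_volume(mixing @ sources)
        return pca_whiten(vol, full_mask(vol), n_sources), sources

    @pytest.mark.parametrize("n_sources", [2, 3])
    def test_recovers_laplacian_sources(self, n_sources):
        white, sources = self.make_whitened(seed=7, n_sources=n_sources)
        _, recovered, _ = infomax(white, seed=11)
        corr = np.abs(np.corrcoef(np.vstack([recovered, sources]))
                      [:n_sources, n_sources:])
        rows, cols = linear_sum_assignment(-corr)
        assert np.all(corr[rows, cols] > 0.99)

    def test_output_shapes(self):
        white, _ = self.make_whitened(seed=1)
        w, maps, _ = infomax(white, seed=0, max_iter=5)
        assert w.shape == (2, 2)
        assert maps.shape == white.reduced.shape

    def test_deterministic_given_seed(self):
        white, _ = self.make_whitened(seed=2)
        w1, _, _ = infomax(white, seed=5, max_iter=30)
        w2, _, _ = infomax(white, seed=5, max_iter=30)
        np.testing.assert_array_equal(w1, w2)


def toy_volume(rng, noise_sd=0.0, t=24):
    """Three well-separated blob sources on a 12^3 grid."""
    shape = (12, 12, 12)
    grids = np.indices(shape, dtype=float)
    centers = [(3, 3, 3), (8, 8, 4), (4, 9, 9)]
    maps = [np.exp(-sum((g - c) ** 2 for g, c in zip(grids, center)) / 6.0)
            for center in centers]
    tcs = rng.standard_normal((3, t))
    data = sum(m[..., None] * tc for m, tc in zip(maps, tcs))
    data = data + noise_sd * rng.standard_normal((*shape, t))
    return Volume4D(data, np.eye(4)), maps


class TestIcasso:
    def test_single_run_degenerate_clustering(self, rng):
        vol, _ = toy_volume(rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            decomp = icasso_decompose(vol, full_mask(vol), 3, n_runs=1, seed=0,
                                      max_iter=100)
        assert len(decomp.components) == 3
        for comp in decomp.components:
            assert 0.0 <= comp.stability_iq <= 1.0

    def test_noiseless_toy_components_are_stable(self, rng):
        vol, _ = toy_volume(rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            decomp = icasso_decompose(vol, full_mask(vol), 3, n_runs=5, seed=3,
                                      max_iter=200)
        assert all(c.stability_iq > 0.9 for c in decomp.components)

    def test_component_count_matches_request(self, rng):
        vol, _ = toy_volume(rng, noise_sd=0.3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for n in (2, 4):
                decomp = icasso_decompose(vol, full_mask(vol), n, n_runs=2,
                                          seed=1, max_iter=60)
                assert len(decomp.components) == n

    def test_stability_does_not_increase_with_noise(self, rng):
        means = []
        for noise in (0.05, 0.8, 3.0):
            vol, _ = toy_volume(np.random.default_rng(42), noise_sd=noise)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                decomp = icasso_decompose(vol, full_mask(vol), 3, n_runs=4,
                                          seed=5, max_iter=150)
            means.append(np.mean([c.stability_iq for c in decomp.components]))
        assert means[0] >= means[1] - 1e-9
        assert means[1] >= means[2] - 1e-9


class TestZScoreAlign:
    def decompose(self, rng, **kw):
        vol, _ = toy_volume(rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return vol, icasso_decompose(vol, full_mask(vol), 3, n_runs=1,
                                         seed=2, max_iter=100, **kw)

    def test_zero_mean_unit_sd_and_positive_skew(self, rng):
        vol, decomp = self.decompose(rng)
        aligned = zscore_align(decomp)
        for comp in aligned.components:
            vals = comp.zmap[aligned.mask]
            assert vals.mean() == pytest.approx(0.0, abs=1e-6)
            assert vals.std() == pytest.approx(1.0, abs=1e-6)
            assert np.mean(vals**3) >= 0
            assert comp.sign_aligned and comp.zscored

    def test_sign_flip_absorbed(self, rng):
        vol, decomp = self.decompose(rng)
        flipped = decomp.__class__(
            components=[c.__class__(zmap=-c.zmap, timecourse=-c.timecourse,
                                    stability_iq=c.stability_iq)
                        for c in decomp.components],
            n_components=decomp.n_components, mask=decomp.mask,
            affine=decomp.affine, converged=decomp.converged, seed=decomp.seed)
        a = zscore_align(decomp)
        b = zscore_align(flipped)
        for ca, cb in zip(a.components, b.components):
            np.testing.assert_allclose(ca.zmap, cb.zmap, atol=1e-10)

    def test_threshold_count_matches_oracle(self, rng):
        vol, decomp = self.decompose(rng)
        aligned = zscore_align(decomp)
        for raw, comp in zip(decomp.components, aligned.components):
            vals = raw.zmap[decomp.mask]
            z = (vals - vals.mean()) / vals.std()
            if np.mean(z**3) < 0:
                z = -z
            assert (comp.zmap > 1).sum() == (z > 1).sum()

    def test_constant_map_rejected(self, rng):
        vol, decomp = self.decompose(rng)
        decomp.components[1].zmap = np.ones_like(decomp.components[1].zmap)
        with pytest.raises(ValueError, match="component 1"):
            zscore_align(decomp)


def test_scale_invariance_of_zmaps(rng):
    vol, _ = toy_volume(rng, noise_sd=0.2)
    scaled = Volume4D(vol.data * 37.5, vol.affine)
    mask = full_mask(vol)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        a = zscore_align(icasso_decompose(vol, mask, 3, n_runs=2, seed=9,
                                          max_iter=80))
        b = zscore_align(icasso_decompose(scaled, mask, 3, n_runs=2, seed=9,
                                          max_iter=80))
    for ca, cb in zip(a.components, b.components):
        np.testing.assert_allclose(ca.zmap, cb.zmap, atol=1e-6)


def test_smn_component_unique_across_settings():
    """At low noise exactly one component overlaps the true SMN mask with
    Dice > 0.5 for each total-component setting."""
    from smnpeak import (CohortConfig, REDUCED_GRID, brain_mask,
                         default_smn_mask, discard_initial_volumes,
                         simulate_run, smooth_gaussian)

    cfg = CohortConfig(
        n_subjects=2, visits=(("V1", "sA"),), conditions=("EO",),
        n_volumes=80, grid=REDUCED_GRID, sigma_between_mm=2.0,
        sigma_within_mm=1.0, noise_sd=0.05,
        scanner_noise_scale=(("sA", 1.0),), seed=3)
    vol, _ = simulate_run(cfg, 0, "V1", "EO")
    vol = smooth_gaussian(discard_initial_volumes(vol, 10), 6.0)
    bmask = brain_mask(cfg.grid)
    smn_mask = default_smn_mask(cfg.grid, widen=1.0, threshold=0.1)
    for n in (20, 30, 40):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            decomp = zscore_align(icasso_decompose(vol, bmask, n, n_runs=1,
                                                   seed=4, max_iter=300))
        dices = [dice_coefficient(c.zmap > 1, smn_mask)
                 for c in decomp.components]
        assert sum(d > 0.5 for d in dices) == 1, (n, sorted(dices)[-3:])
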