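"""Reconstruction: FBP, split-Bregman iterative recon, regularizer filters."""

import numpy as np
import pytest

from pcct_cardiac.acquisition import (AcquisitionConfig, ParallelProjector,
                                      acquire, bin_effective_attenuation,
                                      log_normalize)
from pcct_cardiac.physics import WATER
from pcct_cardiac.recon import (RegularizerConfig, energy_rank_sparse_filter,
                                fbp, fbp_volume, iterative_recon,
                                joint_kernel_filter,
                                temporal_bilateral_filter, to_hu)


def _central_roi(n, frac=0.2):
    c = (n - 1) / 2
    yy, xx = np.mgrid[:n, :n]
    return (yy - c) ** 2 + (xx - c) ** 2 <= (frac * n) ** 2


class TestFBP:
    def test_zero_sinogram_gives_zero_image(self, water_disk_sino):
        sino = water_disk_sino
        zero = sino.__class__(data=np.zeros_like(sino.data),
                              timestamps=sino.timestamps, angles=sino.angles,
                              thresholds=sino.thresholds, mode="log",
                              air_counts=sino.air_counts, meta=sino.meta)
        assert np.allclose(fbp(zero, 0), 0.0, atol=1e-12)

    def test_noiseless_disk_roi_within_3pct_of_truth(self, water_disk_sino):
        n = water_disk_sino.meta["grid_n"]
        roi = _central_roi(n)
        mu_w = bin_effective_attenuation(WATER)
        for b in range(4):
            img = fbp(water_disk_sino, b)
            assert img[roi].mean() == pytest.approx(mu_w[b], rel=0.03)

    def test_view_subset_same_mean_higher_streak_variance(self, water_disk_phantom):
        sino = log_normalize(acquire(water_disk_phantom, AcquisitionConfig(
            views=300, seed=5)))
        n = sino.meta["grid_n"]
        roi = _central_roi(n)
        full = fbp(sino, 0)
        sub = fbp(sino, 0, np.arange(0, 300, 10))
        assert sub[roi].mean() == pytest.approx(full[roi].mean(), rel=0.05)
        assert sub[roi].std() > full[roi].std()

    def test_empty_subset_rejected(self, water_disk_sino):
        with pytest.raises(ValueError, match="empty"):
            fbp(water_disk_sino, 0, np.array([], dtype=int))


class TestToHU:
    @pytest.mark.parametrize("mu,expect", [(0.2, 0.0), (0.0, -1000.0),
                                           (0.5, 1500.0)])
    def test_closed_forms(self, mu, expect):
        assert to_hu(mu, 0.2) == pytest.approx(expect)

    def test_recon_volume_calibration(self, water_disk_sino):
        """Water ~0 HU and air ~-1000 HU in the calibrated reconstruction."""
        vol = fbp_volume(water_disk_sino).to_hu()
        n = water_disk_sino.meta["grid_n"]
        roi = _central_roi(n)
        assert abs(vol.data[0, 0][roi].mean()) < 50.0
        corner = vol.data[0, 0][:4, :4]
        assert corner.mean() == pytest.approx(-1000.0, abs=50.0)


class TestTemporalBilateralFilter:
    def test_constant_in_time_is_fixed_point(self, rng):
        x = np.repeat(rng.standard_normal((1, 12, 12)), 5, axis=0)
        assert np.allclose(temporal_bilateral_filter(x, 1.0), x)

    def test_impulse_attenuated_edges_preserved(self, rng):
        base = np.zeros((6, 8, 8))
        base[:, :, :4] = 10.0
        small = base.copy()
        small[3, 2, 6] += 1.0  # within range sigma: smoothed
        out = temporal_bilateral_filter(small, range_sigma=3.0)
        assert out[3, 2, 6] - base[3, 2, 6] <= 0.5
        big = base.copy()
        big[3, 2, 6] += 100.0  # exceeds range sigma: preserved
        out = temporal_bilateral_filter(big, range_sigma=3.0)
        assert abs(out[3, 2, 6] - big[3, 2, 6]) <= 5.0

    def test_infinite_range_sigma_is_plain_gaussian(self, rng):
        x = rng.standard_normal((6, 8, 8))
        out = temporal_bilateral_filter(x, np.inf, domain_sigma=1.0, window=2)
        w = np.exp(-0.5 * (np.arange(-2, 3) / 1.0) ** 2)
        ref = sum(wi * np.roll(x, -d, axis=0)
                  for wi, d in zip(w, range(-2, 3))) / w.sum()
        assert np.allclose(out, ref)


class TestEnergyRankSparseFilter:
    def test_rank_one_stack_is_fixed_point(self, rng):
        base = rng.standard_normal((12, 12))
        stack = np.stack([c * base for c in (1.0, 0.7, 0.5, 0.3)])
        out = energy_rank_sparse_filter(stack)
        assert np.abs(out - stack).max() <= 0.01 * np.abs(stack).max()

    def test_zero_threshold_is_identity(self, rng):
        stack = rng.standard_normal((4, 10, 10))
        assert np.allclose(energy_rank_sparse_filter(stack, threshold=0.0),
                           stack)

    def test_denoises_rank_one_signal(self, rng):
        base = rng.standard_normal((16, 16))
        clean = np.stack([c * base for c in (1.0, 0.7, 0.5, 0.3)])
        noisy = clean + 0.2 * rng.standard_normal(clean.shape)
        den = energy_rank_sparse_filter(noisy)
        assert np.sqrt(((den - clean) ** 2).mean()) < \
            np.sqrt(((noisy - clean) ** 2).mean())

    def test_joint_kernel_filter_preserves_spectral_direction(self, rng):
        base = np.ones((16, 16))
        stack = np.stack([c * base for c in (1.0, 0.7, 0.5, 0.3)])
        noisy = stack + 0.05 * rng.standard_normal(stack.shape)
        out = joint_kernel_filter(noisy)
        # uniform image: smoothing reduces noise without changing the means
        for b, c in enumerate((1.0, 0.7, 0.5, 0.3)):
            assert out[b].mean() == pytest.approx(c, abs=0.02)
            assert out[b].std() < noisy[b].std()


class TestIterativeRecon:
    def test_unregularized_matches_least_squares_and_fbp(self, water_disk_sino):
        """lambda = 0, noiseless, full sampling: CGLS solution ~ FBP ROI."""
        sino = water_disk_sino
        n = sino.meta["grid_n"]
        vol = iterative_recon(sino, reg=RegularizerConfig(
            lambda_scale=0.0, bregman_iters=2, cg_iters=30))

        # independent CGLS oracle on the same operator
        proj = ParallelProjector(n, sino.meta["voxel_mm"],
                                 n_det=sino.data.shape[1])
        b = 0
        y = sino.data[..., b]
        x = np.zeros((n, n))
        r = proj.backproject_stack(y, sino.angles)
        p = r.copy()
        rs = np.sum(r * r)
        for _ in range(60):
            Ap = proj.backproject_stack(proj.project_stack(p, sino.angles),
                                        sino.angles)
            alpha = rs / np.sum(p * Ap)
            x += alpha * p
            r -= alpha * Ap
            rs_new = np.sum(r * r)
            p = r + (rs_new / rs) * p
            rs = rs_new
        roi = _central_roi(n)
        assert vol.data[0, b][roi].mean() == pytest.approx(x[roi].mean(),
                                                           rel=0.01)
        fbp_img = fbp(sino, b)
        assert vol.data[0, b][roi].mean() == pytest.approx(
            fbp_img[roi].mean(), rel=0.01)

    def test_objective_recorded_and_non_increasing(self, water_disk_phantom):
        sino = log_normalize(acquire(water_disk_phantom, AcquisitionConfig(
            views=120, photons_per_ray=5e3, seed=3)))
        vol = iterative_recon(sino, reg=RegularizerConfig(bregman_iters=4))
        obj = vol.provenance["objective"]
        assert len(obj) >= 2
        for a, b in zip(obj, obj[1:]):
            assert b <= a * 1.001

    def test_single_channel_case_runs(self, water_disk_sino):
        """One phase, one bin degenerates to plain TV-type split Bregman."""
        sino = water_disk_sino
        one_bin = sino.__class__(data=sino.data[..., :1],
                                 timestamps=sino.timestamps,
                                 angles=sino.angles,
                                 thresholds=sino.thresholds[:1], mode="log",
                                 air_counts=sino.air_counts[:1],
                                 meta=sino.meta)
        vol = iterative_recon(one_bin, reg=RegularizerConfig(
            bregman_iters=2, cg_iters=8))
        assert vol.data.shape[:2] == (1, 1)
        assert np.all(np.isfinite(vol.data))
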