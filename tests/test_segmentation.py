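"""LV segmentation: loss, augmentation, training rules, metrics."""

import numpy as np
import pytest

from pcct_cardiac.segmentation import (SegmentationSample, UNet2D, UNetConfig,
                                       augment, binary_cross_entropy,
                                       composite_loss, evaluate,
                                       make_lv_dataset, normalize_image,
                                       select_threshold, soft_dice,
                                       split_dataset, train)


class TestCompositeLoss:
    def test_equals_bce_plus_one_minus_soft_dice(self, rng):
        p = rng.uniform(0.01, 0.99, (3, 1, 8, 8))
        t = (rng.random((3, 1, 8, 8)) > 0.6).astype(float)
        total = composite_loss(p, t)
        assert total == pytest.approx(
            binary_cross_entropy(p, t) + (1 - soft_dice(p, t)), abs=1e-9)

    def test_half_probability_on_half_ones_mask(self):
        """p = 0.5 everywhere, mask half ones: BCE = ln 2, soft Dice = 0.5
        (up to the +1 smoothing), total = ln 2 + 0.5."""
        n = 1000  # large enough that the smoothing constant is negligible
        p = np.full((1, n), 0.5)
        t = np.zeros((1, n)); t[0, :n // 2] = 1.0
        loss = composite_loss(p, t)
        assert loss == pytest.approx(np.log(2) + 0.5, abs=2e-3)

    def test_perfect_prediction_loss_near_zero(self):
        eps = 1e-6
        t = np.zeros((1, 100)); t[0, :30] = 1.0
        p = np.where(t > 0, 1 - eps, eps)
        assert composite_loss(p, t) < 1e-2

    def test_empty_mask_is_finite(self):
        p = np.full((1, 50), 1e-7)
        t = np.zeros((1, 50))
        assert np.isfinite(composite_loss(p, t))

    def test_out_of_range_probabilities_clamped_with_warning(self):
        t = np.ones((1, 4))
        with pytest.warns(UserWarning, match="clamped"):
            loss = composite_loss(np.array([[0.0, 1.0, 0.5, 0.5]]), t)
        assert np.isfinite(loss)

    def test_gradient_matches_finite_differences(self, rng):
        p = rng.uniform(0.2, 0.8, (2, 6, 6))
        t = (rng.random((2, 6, 6)) > 0.5).astype(float)
        loss, grad = composite_loss(p, t, return_grad=True)
        for _ in range(5):
            idx = tuple(rng.integers(0, s) for s in p.shape)
            eps = 1e-6
            pp = p.copy(); pp[idx] += eps
            pm = p.copy(); pm[idx] -= eps
            fd = (composite_loss(pp, t) - composite_loss(pm, t)) / (2 * eps)
            assert grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-9)


class TestAugment:
    def _sample(self):
        img = np.zeros((32, 32)); img[8:24, 8:24] = 1.0
        mask = np.zeros((32, 32), bool); mask[12:20, 12:20] = True
        return SegmentationSample(normalize_image(img), mask)

    def test_zero_magnitude_is_identity(self):
        s = self._sample()
        out = augment(s, seed=3, max_shift=0, max_zoom=0, max_rotate_deg=0)
        assert np.array_equal(out.image, s.image)
        assert np.array_equal(out.mask, s.mask)

    def test_output_is_renormalized(self):
        out = augment(self._sample(), seed=5)
        assert abs(out.image.mean()) < 1e-9
        assert out.image.std() == pytest.approx(1.0, abs=1e-9)

    def test_mask_voxels_conserved_under_pure_rotation(self):
        from scipy import ndimage
        s = self._sample()
        rot_img = ndimage.rotate(s.image, 90, reshape=False, order=1)
        rot_mask = ndimage.rotate(s.mask.astype(float), 90, reshape=False,
                                  order=0) >= 0.5
        assert rot_mask.sum() == s.mask.sum()  # lossless 90-degree rotation

    @pytest.mark.parametrize("zoom", [1.1, 1.2, 1.3])
    def test_zoom_scales_mask_area(self, zoom):
        from pcct_cardiac.physics import disk_fraction
        from pcct_cardiac.segmentation.train import _zoom_same
        mask = disk_fraction((96, 96), (47.5, 47.5), 20.0) >= 0.5
        zoomed = _zoom_same(mask.astype(float), zoom, order=0) >= 0.5
        assert zoomed.sum() == pytest.approx(zoom**2 * mask.sum(), rel=0.05)

    def test_seeded_augmentation_is_reproducible(self):
        a = augment(self._sample(), seed=11)
        b = augment(self._sample(), seed=11)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.mask, b.mask)


class TestNormalizationInvariant:
    def test_dataset_samples_are_zero_mean_unit_std(self):
        for s in make_lv_dataset(5, 32, seed=0):
            assert abs(s.image.mean()) < 1e-6
            assert abs(s.image.std() - 1.0) < 1e-6
            assert set(np.unique(s.mask)) <= {0, 1}


class TestSplit:
    def test_default_split_reproduces_cohort_partition(self):
        """246 labeled segmentations split 186/38/22 under the default
        proportions (123 subjects x 2 cardiac phases)."""
        samples = make_lv_dataset(246, 16, seed=1)
        tr, va, te = split_dataset(samples, seed=0)
        assert (len(tr), len(va), len(te)) == (186, 38, 22)
        assert len(tr) + len(va) + len(te) == 246

    def test_split_is_a_shuffled_partition(self):
        samples = make_lv_dataset(50, 16, seed=1)
        tr, va, te = split_dataset(samples, seed=4)
        ids = sorted(s.subject_id for s in tr + va + te)
        assert ids == sorted(s.subject_id for s in samples)


class TestSelectThreshold:
    def test_perfect_predictor_returns_lowest_grid_point(self):
        t = np.zeros(100, bool); t[:40] = True
        p = np.where(t, 1 - 1e-9, 1e-9)
        assert select_threshold(p, t) == 0.01

    def test_scaled_mask_threshold_boundary(self):
        t = np.zeros(200, bool); t[:80] = True
        p = t * 0.8 + 0.1
        thr = select_threshold(p, t)
        # P = R = 1 anywhere in (0.1, 0.9]; grid + tie rule give 0.11
        assert thr == 0.11

    def test_matches_exhaustive_grid_search(self, rng):
        t = rng.random(500) > 0.8
        p = np.clip(rng.random(500) + 0.3 * t, 0, 1)
        thr = select_threshold(p, t)
        gaps = {}
        for g in np.round(np.arange(0.01, 1.0, 0.01), 2):
            pred = p >= g
            if pred.sum() == 0:
                continue
            prec = (pred & t).sum() / pred.sum()
            rec = (pred & t).sum() / t.sum()
            gaps[g] = abs(prec - rec)
        best = min(gaps.values())
        assert gaps[thr] == pytest.approx(best, abs=1e-12)
        assert thr == min(g for g, v in gaps.items()
                          if v == pytest.approx(best, abs=1e-12))


class TestEvaluate:
    def test_perfect_and_complement_predictions(self):
        t = np.zeros((8, 8), bool); t[:4] = True
        perfect = evaluate(t.astype(float), t, 0.5)
        assert (perfect["dice"], perfect["precision"], perfect["recall"],
                perfect["auc"]) == (1.0, 1.0, 1.0, 1.0)
        comp = evaluate((~t).astype(float), t, 0.5)
        assert comp["dice"] == comp["precision"] == comp["recall"] == 0.0

    def test_hand_enumerated_four_voxel_case(self):
        truth = np.array([1, 1, 0, 0], dtype=bool)
        probs = np.array([0.9, 0.4, 0.6, 0.1])
        m = evaluate(probs, truth, 0.5)
        assert m["dice"] == pytest.approx(0.5)
        assert m["precision"] == pytest.approx(0.5)
        assert m["recall"] == pytest.approx(0.5)
        assert m["auc"] == pytest.approx(0.75)


class TestTraining:
    def _tiny_sets(self):
        data = make_lv_dataset(12, 16, seed=2)
        return data[:8], data[8:]

    def test_one_epoch_report_has_one_entry_per_loss(self):
        tr, va = self._tiny_sets()
        cfg = UNetConfig(base_channels=2, levels=2, image_size=16)
        _, rep = train(cfg, tr, va, seed=0, epochs=1, use_augment=False)
        assert len(rep.train_losses) == 1
        assert len(rep.val_losses) == 1
        assert rep.epochs == 1

    def test_plateau_rule_exactly_one_decay_after_six_flat_epochs(self,
                                                                  monkeypatch):
        """Constant validation loss for 6 epochs triggers exactly one 10x
        learning-rate decay, after epoch 6."""
        import importlib
        trmod = importlib.import_module("pcct_cardiac.segmentation.train")
        monkeypatch.setattr(trmod, "_mean_loss",
                            lambda model, samples, batch=16: 1.0)
        tr, va = self._tiny_sets()
        cfg = UNetConfig(base_channels=2, levels=2, image_size=16)
        _, rep = train(cfg, tr, va, seed=0, epochs=6, use_augment=False)
        assert rep.lr_events == [6]

    def test_epochs_capped_at_max(self):
        tr, va = self._tiny_sets()
        cfg = UNetConfig(base_channels=2, levels=2, image_size=16)
        _, rep = train(cfg, tr, va, seed=0, epochs=90, max_epochs=2,
                       use_augment=False)
        assert rep.epochs == 2

    def test_training_reduces_validation_loss(self):
        tr, va = self._tiny_sets()
        cfg = UNetConfig(base_channels=4, levels=2, image_size=16)
        _, rep = train(cfg, tr, va, seed=0, epochs=6, use_augment=False)
        assert rep.val_losses[-1] < rep.val_losses[0]

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            train(None, [], [], seed=0)


class TestUNetBackprop:
    def test_gradients_match_finite_differences(self, rng):
        cfg = UNetConfig(in_channels=1, base_channels=2, levels=2,
                         image_size=8)
        net = UNet2D(cfg, seed=0)
        x = rng.standard_normal((2, 1, 8, 8))
        t = (rng.random((2, 1, 8, 8)) > 0.7).astype(float)
        p = net.forward(x)
        _, g = composite_loss(p, t, return_grad=True)
        grads = net.backward(g)
        for name in ("e0_w1", "e1_w2", "u0_w", "d0_w1", "out_w", "e0_b1"):
            W = net.params[name]
            idx = tuple(rng.integers(0, s) for s in W.shape)
            eps = 1e-6
            W[idx] += eps
            lp = composite_loss(net.forward(x), t)
            W[idx] -= 2 * eps
            lm = composite_loss(net.forward(x), t)
            W[idx] += eps
            fd = (lp - lm) / (2 * eps)
            assert grads[name][idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)

    def test_save_load_roundtrip(self, tmp_path):
        cfg = UNetConfig(base_channels=2, levels=2, image_size=16)
        net = UNet2D(cfg, seed=3)
        path = tmp_path / "model.npz"
        net.save(path)
        loaded = UNet2D.load(path)
        x = np.random.default_rng(0).standard_normal((1, 1, 16, 16))
        assert np.allclose(net.forward(x, train=False),
                           loaded.forward(x, train=False))
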