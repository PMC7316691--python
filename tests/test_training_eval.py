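"""Normalisation, patching, metrics, loss, optimisation and IQA tests."""

import numpy as np
import pytest
from skimage.metrics import peak_signal_noise_ratio, structural_similarity

from nwsr.autodiff import Tensor
from nwsr.networks import NetworkConfig, NWLayer, build_cnnnet_sr
from nwsr.training_eval import (Adam, IQARecord, TrainConfig, denormalize,
                                evaluate, extract_patches, iqa_csv,
                                normalize_pair, psnr, ssim, ssim_l1_loss,
                                train, validation_loss)


class TestNormalizePair:
    def test_standard_lr_spanning_unit_interval_is_fixed_point(self):
        rng = np.random.default_rng(0)
        lr = rng.random((32, 32))
        lr = (lr - lr.mean()) / lr.std()           # mean 0, std 1
        lr = np.clip(lr, lr.min(), lr.max())
        lr[0, 0], lr[0, 1] = 0.0, 1.0              # informative span [0, 1]
        lr = np.clip(lr, 0.0, 1.0)
        lr = (lr - lr.mean()) / lr.std()
        # re-anchor span exactly
        lr = (lr - lr.min()) / (lr.max() - lr.min())
        mean, std = lr.mean(), lr.std()
        z = (lr - mean) / std
        lr_n, _, stats = normalize_pair(lr, lr, np.ones_like(lr))
        expected = (z - z.min()) / (z.max() - z.min())
        assert np.allclose(lr_n, expected)

    def test_round_trip_inverts_exactly(self):
        rng = np.random.default_rng(1)
        lr = rng.random((16, 16))
        hr = rng.random((16, 16))
        mask = (rng.random((16, 16)) < 0.3).astype(float)
        lr = lr * mask
        lr_n, hr_n, stats = normalize_pair(lr, hr, mask)
        assert np.abs(denormalize(hr_n, stats) - hr).max() <= 1e-9
        assert np.abs(denormalize(lr_n, stats)[mask > 0] - lr[mask > 0]).max() <= 1e-9

    def test_hr_uses_lr_statistics(self):
        rng = np.random.default_rng(2)
        lr = rng.random((16, 16))
        lr_n, hr_n, _ = normalize_pair(lr, lr.copy(), np.ones_like(lr))
        assert np.array_equal(lr_n, hr_n)

    def test_sparse_zeros_reimposed(self):
        rng = np.random.default_rng(3)
        mask = (rng.random((16, 16)) < 0.2).astype(float)
        lr = rng.random((16, 16)) * mask
        lr_n, _, _ = normalize_pair(lr, rng.random((16, 16)), mask)
        assert not lr_n[mask == 0].any()

    def test_constant_lr_raises(self):
        with pytest.raises(ValueError):
            normalize_pair(np.full((8, 8), 2.0), np.zeros((8, 8)),
                           np.ones((8, 8)))


class TestExtractPatches:
    def test_exact_tiling(self):
        frame = np.arange(128 * 128, dtype=float).reshape(128, 128)
        patches, _ = extract_patches(frame, np.ones_like(frame), 64)
        assert patches.shape == (4, 64, 64)
        assert np.array_equal(patches[0], frame[:64, :64])
        assert np.array_equal(patches[1], frame[:64, 64:])

    def test_remainder_dropped(self):
        patches, _ = extract_patches(np.zeros((100, 100)), np.zeros((100, 100)), 64)
        assert patches.shape == (1, 64, 64)

    def test_tiling_round_trip(self):
        rng = np.random.default_rng(4)
        frame = rng.random((128, 128))
        patches, _ = extract_patches(frame, frame, 64)
        rebuilt = np.block([[patches[0], patches[1]], [patches[2], patches[3]]])
        assert np.array_equal(rebuilt, frame)

    def test_too_small_frame_raises(self):
        with pytest.raises(ValueError):
            extract_patches(np.zeros((32, 32)), np.zeros((32, 32)), 64)


class TestMetrics:
    def test_psnr_closed_form_uniform_error(self):
        a = np.zeros((32, 32))
        assert np.isclose(psnr(a, a + 0.1, data_range=1.0), 20.0)

    def test_psnr_identical_frames_is_infinite(self):
        a = np.random.default_rng(0).random((16, 16))
        assert np.isinf(psnr(a, a))

    @pytest.mark.parametrize("seed", range(5))
    def test_metrics_match_reference_implementations(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((48, 48))
        b = np.clip(a + 0.1 * rng.standard_normal((48, 48)), 0, 1)
        assert abs(psnr(a, b, 1.0)
                   - peak_signal_noise_ratio(a, b, data_range=1.0)) <= 1e-9
        ref = structural_similarity(a, b, data_range=1.0, gaussian_weights=True,
                                    sigma=1.5, use_sample_covariance=False)
        assert abs(ssim(a, b, 1.0) - ref) <= 1e-6

    def test_ssim_identical_is_one(self):
        a = np.random.default_rng(1).random((32, 32))
        assert np.isclose(ssim(a, a), 1.0)

    def test_ssim_anticorrelated_pattern_is_strongly_negative(self):
        a = np.indices((64, 64)).sum(0) % 2 * 1.0  # checkerboard
        assert ssim(a, 1.0 - a) < -0.5

    def test_masked_ssim_averages_selected_windows_only(self):
        rng = np.random.default_rng(2)
        a, b = rng.random((64, 64)), rng.random((64, 64))
        full = ssim(a, b)
        half_mask = np.zeros((64, 64))
        half_mask[:, :32] = 1
        left = ssim(a, b, mask=half_mask)
        assert left != pytest.approx(full)  # genuinely restricted


class TestSSIML1Loss:
    def test_zero_at_equality(self):
        x = np.random.default_rng(0).random((64, 64))
        assert ssim_l1_loss(x, x) <= 1e-12

    def test_alpha_zero_is_mean_absolute_error(self):
        a = np.full((32, 32), 0.4)
        assert np.isclose(ssim_l1_loss(a, a + 0.25, alpha=0.0), 0.25)

    def test_matches_reference_composition(self):
        rng = np.random.default_rng(5)
        a = rng.random((64, 64))
        b = np.clip(a + 0.05 * rng.standard_normal((64, 64)), 0, 1)
        alpha = 0.84
        expected = alpha * (1.0 - ssim(a, b)) + (1 - alpha) * np.abs(a - b).mean()
        assert np.isclose(ssim_l1_loss(a, b, alpha=alpha), expected, atol=1e-12)

    def test_positive_unless_equal(self):
        rng = np.random.default_rng(6)
        a = rng.random((32, 32))
        assert ssim_l1_loss(a, a + 1e-3) > 0

    def test_differentiable_path_returns_tensor(self):
        x = Tensor(np.random.default_rng(7).random((1, 1, 32, 32)),
                   requires_grad=True)
        loss = ssim_l1_loss(x, x.data * 0.9)
        assert isinstance(loss, Tensor)
        loss.backward()
        assert x.grad is not None and np.isfinite(x.grad).all()

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            ssim_l1_loss(np.zeros((8, 8)), np.zeros((9, 9)))


class TestTrain:
    @pytest.fixture()
    def tiny_problem(self):
        rng = np.random.default_rng(8)
        x = rng.random((4, 32, 32))
        y = np.stack([0.5 * xi + 0.1 for xi in x])
        return x, y

    def test_overfit_single_batch(self, tiny_problem):
        x, y = tiny_problem
        net = build_cnnnet_sr(NetworkConfig(n_res_blocks=1, n_features=4), seed=0)
        hist = train(net, x, y, TrainConfig(lr=3e-3, steps=200, batch_size=4,
                                            seed=0))
        assert hist[-1] < 0.1 * hist[0]

    def test_same_seed_identical_histories(self, tiny_problem):
        x, y = tiny_problem
        cfg = TrainConfig(lr=1e-3, steps=10, batch_size=2, seed=5)
        h1 = train(build_cnnnet_sr(NetworkConfig(n_res_blocks=1, n_features=4),
                                   seed=1), x, y, cfg)
        h2 = train(build_cnnnet_sr(NetworkConfig(n_res_blocks=1, n_features=4),
                                   seed=1), x, y, cfg)
        assert h1 == h2

    def test_zero_learning_rate_freezes_loss(self, tiny_problem):
        x, y = tiny_problem
        net = build_cnnnet_sr(NetworkConfig(n_res_blocks=1, n_features=4), seed=2)
        hist = train(net, x, y, TrainConfig(lr=0.0, steps=8, batch_size=4, seed=0))
        assert np.allclose(hist, hist[0])

    def test_empty_dataset_raises(self):
        net = build_cnnnet_sr(NetworkConfig(n_res_blocks=1, n_features=4), seed=0)
        with pytest.raises(ValueError):
            train(net, np.zeros((0, 32, 32)), np.zeros((0, 32, 32)),
                  TrainConfig(steps=1))

    def test_nw_kernel_recovery_from_gaussian_regression(self):
        """One NW kernel trained on Gaussian-NW outputs recovers the kernel."""
        from nwsr.baselines import gaussian_tap_kernel
        from nwsr.nw_layer import nw_core

        rng = np.random.default_rng(10)
        k, sigma = 3, 1.5
        gen = gaussian_tap_kernel(sigma, k)
        gen /= np.abs(gen).sum()
        n = 60
        masks = (rng.random((n, 1, 24, 24)) < 0.12).astype(float)
        feats = rng.random((n, 1, 24, 24)) * masks
        # targets via the classical operation with the generating kernel
        gt_bank = Tensor(gen[None, None])
        targets, _ = nw_core(Tensor(feats), Tensor(masks), gt_bank,
                             Tensor(np.zeros(1)))
        layer = NWLayer(1, 1, k, rng)
        layer.bias.requires_grad = False  # bias frozen at 0
        opt = Adam([layer.weight], lr=3e-3)
        for step in range(150):
            idx = rng.integers(0, n, size=8)
            pred, _ = layer(Tensor(feats[idx]), Tensor(masks[idx]))
            diff = pred - Tensor(targets.data[idx])
            loss = (diff * diff).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
        learned = layer.projected_weight().data[0, 0]
        corr = (learned * gen).sum() / np.sqrt((learned ** 2).sum()
                                               * (gen ** 2).sum())
        assert corr > 0.9


class TestValidationAndGrid:
    def test_validation_loss_matches_manual_average(self):
        rng = np.random.default_rng(11)
        x = rng.random((5, 32, 32))
        y = rng.random((5, 32, 32))
        net = build_cnnnet_sr(NetworkConfig(n_res_blocks=1, n_features=4), seed=0)
        cfg = TrainConfig()
        manual = np.mean([ssim_l1_loss(net.predict(xi), yi)
                          for xi, yi in zip(x, y)])
        assert np.isclose(validation_loss(net, x, y, cfg, batch_size=1), manual)


class TestEvaluate:
    class _Item:
        def __init__(self, lr, hr):
            self.lr, self.hr = lr, hr

    def test_identity_model_on_identical_frames(self):
        frame = np.random.default_rng(0).random((32, 32))
        rec = evaluate(lambda it: it.lr, [self._Item(frame, frame)])
        assert rec.mean_ssim == pytest.approx(1.0)
        assert rec.has_infinite_psnr

    def test_single_frame_std_is_zero(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((32, 32)), rng.random((32, 32))
        rec = evaluate(lambda it: it.lr, [self._Item(a, b)])
        assert rec.std_psnr == 0.0 and rec.std_ssim == 0.0

    def test_aggregation_arithmetic(self):
        rec = IQARecord(per_frame=[(20.0, 0.8), (30.0, 0.9)])
        assert rec.mean_psnr == pytest.approx(25.0)
        assert rec.mean_ssim == pytest.approx(0.85)

    def test_empty_testset_raises(self):
        with pytest.raises(ValueError):
            evaluate(lambda it: it.lr, [])

    def test_csv_report_layout(self, tmp_path):
        rec = IQARecord(per_frame=[(20.0, 0.8), (30.0, 0.9)])
        path = tmp_path / "report.csv"
        iqa_csv({"LINEAR BASELINE": rec}, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "model,frame_id,psnr_db,ssim"
        assert len(lines) == 4  # header + 2 frames + summary
        assert "mean±std" in lines[-1]
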