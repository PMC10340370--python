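"""Slice samples, augmentation, the combined loss, and generator contracts."""



import numpy as np
import pytest

from spectac import Role, Volume3, build_unet, normalize_volume
from spectac.acnet import (
    AugmentPolicy,
    NetConfig,
    SliceSample,
    augment,
    loss,
    loss_and_grad,
    make_slice_samples,
    predict_acm,
    train,
)
from spectac.metrics import ACM_SSIM, mre, mssim


@pytest.fixture()
def nac_volume(rng):
    return Volume3(rng.random((6, 64, 64)) * 380.0, role=Role.COUNTS_PROP)


@pytest.fixture()
def acm_volume(rng):
    return Volume3(rng.random((6, 64, 64)) * 0.18, role=Role.MU_CM1)


class TestNormalize:
    def test_max_becomes_exactly_one(self, nac_volume):
        out = normalize_volume(nac_volume)
        assert out.values.max() == 1.0
        assert out.values.min() >= 0.0

    def test_idempotent(self, nac_volume):
        once = normalize_volume(nac_volume)
        twice = normalize_volume(once)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_scale_invariant(self, nac_volume):
        a = normalize_volume(nac_volume)
        b = normalize_volume(nac_volume.with_values(nac_volume.values * 17.0))
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)

    def test_attenuation_maps_refused(self, acm_volume):
        with pytest.raises(ValueError, match="not normalised"):
            normalize_volume(acm_volume)

    def test_all_zero_volume_refused(self):
        vol = Volume3(np.zeros((2, 4, 4)), role=Role.COUNTS_PROP)
        with pytest.raises(ValueError, match="positive"):
            normalize_volume(vol)


class TestSliceSamples:
    def test_one_sample_per_slice(self, nac_volume, acm_volume):
        samples = make_slice_samples(normalize_volume(nac_volume), acm_volume)
        assert len(samples) == 6

    def test_boundary_slices_replicate_edge_neighbour(self, nac_volume, acm_volume):
        nac = normalize_volume(nac_volume)
        samples = make_slice_samples(nac, acm_volume)
        np.testing.assert_array_equal(samples[0].input[..., 0], samples[0].input[..., 1])
        np.testing.assert_array_equal(samples[-1].input[..., 2], samples[-1].input[..., 1])

    def test_interior_channels_are_the_volume_slices(self, nac_volume, acm_volume):
        nac = normalize_volume(nac_volume)
        samples = make_slice_samples(nac, acm_volume)
        z = 3
        np.testing.assert_array_equal(samples[z].input[..., 0], nac.values[z - 1])
        np.testing.assert_array_equal(samples[z].input[..., 1], nac.values[z])
        np.testing.assert_array_equal(samples[z].input[..., 2], nac.values[z + 1])
        np.testing.assert_array_equal(samples[z].target, acm_volume.values[z])

    def test_misaligned_volumes_rejected(self, nac_volume):
        other = Volume3(np.zeros((5, 64, 64)), role=Role.MU_CM1)
        with pytest.raises(ValueError, match="aligned"):
            make_slice_samples(normalize_volume(nac_volume), other)


class TestAugment:
    @pytest.fixture()
    def sample(self, rng):
        inp = np.zeros((64, 64, 3))
        inp[20:30, 25:40, :] = rng.random((10, 15, 3))
        tgt = np.zeros((64, 64))
        tgt[20:30, 25:40] = 0.15
        return SliceSample(inp, tgt)

    def test_all_off_policy_is_identity(self, sample):
        policy = AugmentPolicy(
            p_rotate=0.0, p_flip=0.0, p_shift=0.0
        )
        out = augment(sample, policy, seed=3)
        np.testing.assert_array_equal(out.input, sample.input)
        np.testing.assert_array_equal(out.target, sample.target)

    def test_flip_twice_restores_original(self, sample):
        policy = AugmentPolicy(p_rotate=0.0, p_shift=0.0, p_flip=1.0,
                               flip_coronal=True, flip_sagittal=False, flip_axial=False)
        once = augment(sample, policy, seed=1)
        twice = augment(once, policy, seed=2)
        np.testing.assert_array_equal(twice.input, sample.input)
        np.testing.assert_array_equal(twice.target, sample.target)

    def test_integer_shift_moves_support_exactly(self, sample):
        policy = AugmentPolicy(p_rotate=0.0, p_flip=0.0, p_shift=1.0, shift_max_voxels=7)
        rng = np.random.default_rng(9)
        out = augment(sample, policy, rng)
        # recover the drawn offset from the support centroids
        iy, ix = np.nonzero(sample.target)
        oy, ox = np.nonzero(out.target)
        dy = int(round(oy.mean() - iy.mean()))
        dx = int(round(ox.mean() - ix.mean()))
        assert abs(dy) <= 7 and abs(dx) <= 7
        np.testing.assert_array_equal(
            out.target, np.roll(np.roll(sample.target, dy, 0), dx, 1)
        )

    def test_input_and_target_get_identical_transform(self, sample):
        policy = AugmentPolicy()
        out = augment(sample, policy, seed=17)
        # the target support must coincide with the input support (channel 1)
        np.testing.assert_array_equal(out.input[..., 1] > 0, out.target > 0)

    def test_deterministic_per_seed(self, sample):
        policy = AugmentPolicy()
        a = augment(sample, policy, seed=5)
        b = augment(sample, policy, seed=5)
        np.testing.assert_array_equal(a.input, b.input)
        np.testing.assert_array_equal(a.target, b.target)

    def test_shift_beyond_seven_voxels_rejected(self):
        with pytest.raises(ValueError):
            AugmentPolicy(shift_max_voxels=9)


class TestLoss:
    def test_zero_for_identical_images(self, rng):
        y = rng.random((32, 32)) * 0.2
        assert loss(y, y) == pytest.approx(0.0, abs=1e-12)

    def test_alpha_one_reduces_to_one_minus_mssim(self, rng):
        y = rng.random((32, 32)) * 0.2
        x = np.abs(y + rng.normal(0, 0.02, y.shape))
        assert loss(y, x, alpha=1.0) == pytest.approx(1.0 - mssim(y, x, ACM_SSIM), rel=1e-9)

    def test_weighted_combination_of_components(self, rng):
        y = rng.random((32, 32)) * 0.2 + 0.02
        x = np.abs(y + rng.normal(0, 0.02, y.shape))
        eps = 1e-3 * y.max()
        expected = 0.8 * (1.0 - mssim(y, x, ACM_SSIM)) + 0.2 * (mre(y, x, eps) / 100.0)
        assert loss(y, x, alpha=0.8) == pytest.approx(expected, rel=1e-9)

    def test_analytic_gradient_matches_finite_differences(self, rng):
        y = rng.random((20, 20)) * 0.2
        x = np.abs(y + rng.normal(0, 0.02, y.shape))
        _, g = loss_and_grad(y, x, alpha=0.8)
        h = 1e-7
        for idx in [(3, 4), (10, 10), (15, 2), (0, 0)]:
            xp = x.copy(); xp[idx] += h
            xm = x.copy(); xm[idx] -= h
            num = (loss(y, xp, 0.8) - loss(y, xm, 0.8)) / (2 * h)
            assert g[idx] == pytest.approx(num, rel=5e-4, abs=1e-9)

    def test_augmented_pair_keeps_zero_loss(self, rng):
        tgt = np.zeros((64, 64))
        tgt[20:40, 25:45] = 0.15
        sample = SliceSample(np.repeat(tgt[..., None], 3, axis=2) / 0.15, tgt)
        out = augment(sample, AugmentPolicy(), seed=21)
        assert loss(out.target, out.target) == pytest.approx(0.0, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            loss(np.zeros((16, 16)), np.zeros((16, 17)))

    def test_batched_loss_equals_per_sample_mean(self, rng):
        from spectac.acnet import batch_loss_and_grad

        y = rng.random((5, 32, 32)) * 0.2
        x = np.abs(y + rng.normal(0, 0.03, y.shape))
        vb, gb = batch_loss_and_grad(y, x)
        per = [loss_and_grad(y[i], x[i]) for i in range(5)]
        assert vb == pytest.approx(np.mean([v for v, _ in per]), rel=1e-12)
        np.testing.assert_allclose(gb, np.stack([g for _, g in per]) / 5, atol=1e-15)


class TestUNet:
    @pytest.fixture(scope="class")
    def tiny_cfg(self):
        return NetConfig(
            levels=3, base_channels=2, dropout_rate=0.1, max_epochs=3,
            patience=2, batch_size=4, seed=11,
        )

    def test_output_shape_matches_input(self, tiny_cfg, rng):
        net = build_unet(tiny_cfg)
        out = net.forward(rng.random((2, 3, 64, 64)), training=False)
        assert out.shape == (2, 1, 64, 64)

    def test_output_nonnegative(self, tiny_cfg, rng):
        net = build_unet(tiny_cfg)
        out = net.forward(rng.random((2, 3, 64, 64)) - 0.5, training=False)
        assert np.all(out >= 0)

    def test_indivisible_spatial_size_rejected(self, tiny_cfg, rng):
        net = build_unet(tiny_cfg)
        with pytest.raises(ValueError, match="divisible"):
            net.forward(rng.random((1, 3, 62, 62)))

    def test_eval_forward_deterministic(self, tiny_cfg, rng):
        net = build_unet(tiny_cfg)
        x = rng.random((1, 3, 64, 64))
        np.testing.assert_array_equal(net.predict(x), net.predict(x))

    def test_same_seed_same_initial_parameters(self, tiny_cfg):
        from spectac import nn

        a, b = build_unet(tiny_cfg), build_unet(tiny_cfg)
        for sa, sb in zip(nn.get_state(a), nn.get_state(b)):
            np.testing.assert_array_equal(sa, sb)


class TestTraining:
    def make_samples(self, rng, n=6):
        samples = []
        for _ in range(n):
            tgt = np.zeros((64, 64))
            cy, cx = rng.integers(20, 44, 2)
            tgt[cy - 8 : cy + 8, cx - 8 : cx + 8] = 0.15
            inp = np.repeat((tgt / 0.15)[..., None], 3, axis=2)
            samples.append(SliceSample(inp, tgt))
        return samples

    def test_history_lengths_match_epochs_run(self, rng):
        cfg = NetConfig(levels=3, base_channels=2, max_epochs=4, patience=4,
                        batch_size=4, seed=1)
        samples = self.make_samples(rng)
        model, hist = train(build_unet(cfg), samples, samples[:2], cfg)
        assert len(hist["train_loss"]) == len(hist["val_loss"])
        assert 1 <= len(hist["train_loss"]) <= 4

    def test_identical_seeds_identical_history(self, rng):
        cfg = NetConfig(levels=3, base_channels=2, max_epochs=3, patience=3,
                        batch_size=4, seed=7)
        samples = self.make_samples(rng)
        _, h1 = train(build_unet(cfg), samples, samples[:2], cfg,
                      augment_policy=AugmentPolicy())
        _, h2 = train(build_unet(cfg), samples, samples[:2], cfg,
                      augment_policy=AugmentPolicy())
        assert h1 == h2

    def test_empty_sets_rejected(self, rng):
        cfg = NetConfig(levels=3, base_channels=2, seed=1)
        with pytest.raises(ValueError):
            train(build_unet(cfg), [], self.make_samples(rng), cfg)


class TestCalibration:
    def test_recovers_a_known_monotone_distortion(self, rng):
        from spectac.acnet import fit_mu_calibration

        truth = rng.random(80000) * 0.18
        pred = 0.88 * truth  # systematic 12% under-prediction
        cal = fit_mu_calibration(pred, truth)
        probe = np.array([0.05, 0.10, 0.14])
        np.testing.assert_allclose(cal(0.88 * probe), probe, rtol=0.03)

    def test_curve_is_monotone_and_zero_preserving(self, rng):
        from spectac.acnet import fit_mu_calibration

        truth = rng.random(60000) * 0.18
        pred = np.clip(truth + rng.normal(0, 0.01, truth.shape), 0, None)
        cal = fit_mu_calibration(pred, truth)
        assert cal(0.0) == 0.0
        grid = np.linspace(0, 0.25, 100)
        assert np.all(np.diff(cal(grid)) >= -1e-12)

    def test_too_few_voxels_rejected(self):
        from spectac.acnet import fit_mu_calibration

        with pytest.raises(ValueError, match="too few"):
            fit_mu_calibration(np.zeros(1000), np.zeros(1000))


def test_hyperparameter_search_returns_best_by_validation_loss(rng):
    from spectac.acnet import hyperparameter_search

    tgt = np.zeros((64, 64))
    tgt[24:40, 24:40] = 0.15
    samples = [SliceSample(np.repeat((tgt / 0.15)[..., None], 3, axis=2), tgt)] * 4
    base = NetConfig(levels=3, base_channels=2, max_epochs=2, patience=2, batch_size=4)
    best, results = hyperparameter_search(
        samples, samples[:2], base,
        space={"learning_rate": [1e-3, 1e-2], "dropout_rate": [0.0, 0.1]},
        n_trials=2, seed=0,
    )
    assert len(results) == 2
    best_loss = min(v for _, v in results)
    assert any(c == best and v == best_loss for c, v in results)


class TestPredict:
    def test_volume_prediction_contract(self, rng):
        cfg = NetConfig(levels=3, base_channels=2, seed=2)
        net = build_unet(cfg)
        nac = Volume3(rng.random((5, 64, 64)), role=Role.COUNTS_PROP)
        out = predict_acm(net, normalize_volume(nac))
        assert out.shape == nac.shape
        assert out.role == Role.MU_CM1
        assert np.all(out.values >= 0)

    def test_all_zero_slices_give_finite_output(self):
        cfg = NetConfig(levels=3, base_channels=2, seed=2)
        net = build_unet(cfg)
        nac = Volume3(np.zeros((3, 64, 64)), role=Role.COUNTS_PROP)
        nac.values[0, 0, 0] = 1.0
        out = predict_acm(net, nac)
        assert np.all(np.isfinite(out.values))

    def test_unnormalised_volume_rejected(self, rng):
        cfg = NetConfig(levels=3, base_channels=2, seed=2)
        net = build_unet(cfg)
        nac = Volume3(rng.random((3, 64, 64)) * 10, role=Role.COUNTS_PROP)
        with pytest.raises(ValueError, match="normalised"):
            predict_acm(net, nac)
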