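"""Reconstruction contracts: SSIM, data consistency, network degeneracies."""

import numpy as np
import pytest

from needletrack.kspace import (centered_fft2, centered_ifft2,
                                make_central_mask, rss_combine)
from needletrack.phantom import PhantomConfig, generate_sample
from needletrack.recon import (CRNNConfig, CRNNModel, SSIMConfig,
                               data_consistency, reconstruct_sequence, ssim,
                               train_model)

TINY = CRNNConfig.desk(n_filters=8, n_iterations=1, epochs=1, batch_size=2,
                       rng_seed=0)


@pytest.fixture(scope="module")
def short_sample():
    cfg = PhantomConfig.desk(n_frames=8, move_window=(3, 5), rng_seed=5)
    return generate_sample(cfg)


def tiny_sequences(n=3, grid=32, seed=0):
    cfg = PhantomConfig.desk(grid_size=grid, guide_length_mm=12.0,
                             guide_radius_mm=1.2, tip_start=(22.0, 18.0),
                             tip_end=(16.0, 18.0), n_frames=5,
                             move_window=(1, 3))
    from needletrack.experiment import training_corpus
    return training_corpus(cfg, n, seed=seed, motion_mm=(3.0, 6.0))


class TestSSIM:
    def test_self_similarity_is_one(self, rng):
        x = rng.random((32, 32))
        assert ssim(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_constant_images_closed_form(self):
        cfg = SSIMConfig()
        mu_a, mu_b = 0.3, 0.7
        a = np.full((24, 24), mu_a)
        b = np.full((24, 24), mu_b)
        c1 = (cfg.k1 * cfg.dynamic_range) ** 2
        expected = (2 * mu_a * mu_b + c1) / (mu_a ** 2 + mu_b ** 2 + c1)
        assert ssim(a, b, cfg) == pytest.approx(expected, rel=1e-10)

    def test_symmetry(self, rng):
        for _ in range(5):
            a, b = rng.random((20, 20)), rng.random((20, 20))
            assert ssim(a, b) == pytest.approx(ssim(b, a), abs=1e-12)

    def test_matches_skimage_oracle(self, rng):
        from skimage.metrics import structural_similarity
        a = rng.random((48, 48))
        b = np.clip(a + 0.1 * rng.standard_normal((48, 48)), 0, 1)
        ref = structural_similarity(a, b, gaussian_weights=True, sigma=1.5,
                                    use_sample_covariance=False,
                                    data_range=1.0)
        assert ssim(a, b) == pytest.approx(ref, abs=1e-10)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            ssim(np.zeros((16, 16)), np.zeros((16, 17)))


class TestDataConsistency:
    def test_full_mask_returns_measurement(self, rng):
        pred = rng.standard_normal((32, 32)) + 1j * rng.standard_normal((32, 32))
        meas = rng.standard_normal((32, 32)) + 1j * rng.standard_normal((32, 32))
        out = data_consistency(pred, meas, make_central_mask(32, 1))
        assert np.array_equal(out, meas)

    def test_retained_lines_bit_exact_others_untouched(self, rng):
        pred = rng.standard_normal((64, 64)) + 1j * rng.standard_normal((64, 64))
        meas = rng.standard_normal((64, 64)) + 1j * rng.standard_normal((64, 64))
        m = make_central_mask(64, 8)
        out = data_consistency(pred, meas, m)
        assert np.array_equal(out[m.retained], meas[m.retained])
        assert np.array_equal(out[~m.retained], pred[~m.retained])

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            data_consistency(np.zeros((32, 32), complex),
                             np.zeros((16, 16), complex),
                             make_central_mask(32, 2))


class TestReconstructSequence:
    def test_zero_weight_network_equals_zero_filled(self, short_sample):
        from needletrack.kspace import zero_fill_reconstruct
        model = CRNNModel(TINY)
        model.zero_weights()
        mask = make_central_mask(short_sample.grid_size, 8)
        rec = reconstruct_sequence(short_sample.dyn_kspace, mask, model,
                                   clamp=False)
        zf = np.stack([zero_fill_reconstruct(k, mask)
                       for k in short_sample.dyn_kspace])
        assert np.allclose(rec, zf, atol=1e-5)

    def test_fresh_network_starts_as_zero_filled(self, short_sample):
        # zero-initialized output conv: identity residual before training
        from needletrack.kspace import zero_fill_reconstruct
        model = CRNNModel(TINY)
        mask = make_central_mask(short_sample.grid_size, 8)
        rec = reconstruct_sequence(short_sample.dyn_kspace, mask, model,
                                   clamp=False)
        zf = np.stack([zero_fill_reconstruct(k, mask)
                       for k in short_sample.dyn_kspace])
        assert np.allclose(rec, zf, atol=1e-5)

    def test_full_sampling_equals_rss_regardless_of_weights(self, short_sample):
        model = CRNNModel(CRNNConfig.desk(n_filters=8, n_iterations=2,
                                          rng_seed=3))
        mask = make_central_mask(short_sample.grid_size, 1)
        rec = reconstruct_sequence(short_sample.dyn_kspace, mask, model,
                                   clamp=False)
        rss = np.stack([rss_combine(centered_ifft2(k))
                        for k in short_sample.dyn_kspace])
        assert np.max(np.abs(rec - rss)) / np.max(rss) < 1e-6

    def test_static_input_gives_static_output(self):
        cfg = PhantomConfig.desk(n_frames=6, move_window=(0, 0), rng_seed=9)
        sample = generate_sample(cfg)  # guide static from frame 0
        model = CRNNModel(TINY)
        mask = make_central_mask(sample.grid_size, 8)
        rec = reconstruct_sequence(sample.dyn_kspace[1:], mask, model)
        assert np.allclose(rec, rec[0][None], atol=1e-6)

    def test_final_kspace_matches_sampled_lines(self, short_sample):
        model = CRNNModel(CRNNConfig.desk(n_filters=8, rng_seed=2))
        mask = make_central_mask(short_sample.grid_size, 8)
        rec = reconstruct_sequence(short_sample.dyn_kspace, mask, model,
                                   return_complex=True)
        for f in (0, 4):
            k = centered_fft2(rec[f])
            meas = short_sample.dyn_kspace[f, 0]
            diff = np.abs(k[mask.retained] - meas[mask.retained])
            assert diff.max() < 1e-4  # single-precision round trip

    def test_output_range_clamped(self, short_sample):
        model = CRNNModel(CRNNConfig.desk(n_filters=8, rng_seed=2))
        mask = make_central_mask(short_sample.grid_size, 8)
        rec = reconstruct_sequence(short_sample.dyn_kspace, mask, model)
        assert rec.min() >= 0.0 and rec.max() <= 1.0 + 1e-6

    def test_multi_coil_full_sampling_recovers_rss(self):
        cfg = PhantomConfig.desk(n_coils=3, n_frames=5, move_window=(1, 3),
                                 rng_seed=4)
        sample = generate_sample(cfg)
        model = CRNNModel(CRNNConfig.desk(n_filters=8, rng_seed=1))
        mask = make_central_mask(sample.grid_size, 1)
        rec = reconstruct_sequence(sample.dyn_kspace, mask, model,
                                   sens=sample.coil_sens, clamp=False)
        rss = np.stack([rss_combine(centered_ifft2(k))
                        for k in sample.dyn_kspace])
        assert np.max(np.abs(rec - rss)) / np.max(rss) < 1e-5

    def test_multi_coil_requires_sensitivities(self, rng):
        model = CRNNModel(TINY)
        k = rng.standard_normal((3, 2, 64, 64)) + 0j
        with pytest.raises(ValueError, match="sensitivit"):
            reconstruct_sequence(k, make_central_mask(64, 8), model)


class TestTraining:
    def test_fixed_seed_identical_loss_trace(self):
        seqs = tiny_sequences()
        _, t1 = train_model(seqs, TINY)
        _, t2 = train_model(seqs, TINY)
        assert t1.losses == t2.losses

    def test_augmentation_changes_trace(self):
        seqs = tiny_sequences()
        _, with_aug = train_model(seqs, TINY)
        from dataclasses import replace
        _, without = train_model(seqs, replace(TINY, augment=False))
        assert with_aug.losses != without.losses

    def test_short_training_improves_validation_ssim(self):
        # tiny smoke test at 32 px: a few epochs must beat zero-filled
        train = tiny_sequences(n=6, seed=0)
        val = tiny_sequences(n=2, seed=99)
        cfg = CRNNConfig.desk(epochs=8, batch_size=3, rng_seed=0)
        model, trace = train_model(train, cfg)
        assert trace.losses[-1] < trace.losses[0]
        mask = make_central_mask(32, 8)
        gains = []
        for seq in val:
            k = centered_fft2(seq.astype(complex))[:, None]
            rec = reconstruct_sequence(k, mask, model)
            from needletrack.kspace import zero_fill_reconstruct
            for f in range(len(seq)):
                zf = np.clip(zero_fill_reconstruct(k[f], mask), 0, 1)
                gains.append(ssim(rec[f], seq[f]) - ssim(zf, seq[f]))
        assert np.mean(gains) > 0

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_model([], TINY)

    def test_checkpoint_round_trip(self, tmp_path, rng):
        model = CRNNModel(TINY)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = CRNNModel.load(path)
        assert loaded.cfg == model.cfg
        for a, b in zip(model.params, loaded.params):
            assert np.array_equal(a.data, b.data)


class TestConfigValidation:
    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            CRNNConfig(window_length=4)

    def test_presets(self):
        desk = CRNNConfig.desk()
        assert desk.n_iterations == 2 and desk.n_filters == 16
        full = CRNNConfig.paper_scale()
        assert full.n_iterations == 10 and full.n_filters == 128
        assert full.kernel_size == 3 and full.window_length == 5
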