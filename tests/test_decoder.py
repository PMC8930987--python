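"""Decoder: preprocessing, metrics, linear oracle, training, classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from fiberimg import decoder as dec
from fiberimg import encoder as enc
from fiberimg.decoder import DecoderConfig, fidelity, preprocess_waveform, ssim_metric
from fiberimg.fiber import group_delays
from fiberimg.patterns import ImagePattern, make_glyphs


class TestPreprocess:
    def test_long_waveform_cropped_to_target(self):
        rng = np.random.default_rng(0)
        x = preprocess_waveform(rng.uniform(0, 1, 4500), target_len=4096)
        assert x.shape == (4096,)

    def test_short_waveform_zero_padded(self):
        x = preprocess_waveform(np.ones(100), target_len=4096)
        assert x.shape == (4096,)

    def test_reshape_then_flatten_is_identity(self):
        rng = np.random.default_rng(1)
        w = rng.uniform(0, 1, 4096)
        img = preprocess_waveform(w, as_image=True)
        flat = preprocess_waveform(w)
        np.testing.assert_array_equal(img.reshape(-1), flat)
        assert img.shape == (64, 64)

    def test_identical_inputs_identical_outputs(self):
        rng = np.random.default_rng(2)
        w = rng.uniform(0, 1, 5000)
        np.testing.assert_array_equal(preprocess_waveform(w), preprocess_waveform(w.copy()))

    def test_all_zero_waveform_passes_through(self):
        x = preprocess_waveform(np.zeros(5000))
        assert np.all(x == 0)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            preprocess_waveform(np.array([]))


class TestFidelity:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, (8, 8))
        assert fidelity(x, x) == pytest.approx(1.0)

    def test_inverted_binary_is_minus_one(self):
        x = (np.random.default_rng(4).uniform(0, 1, (8, 8)) > 0.5).astype(float)
        assert fidelity(x, 1 - x) == pytest.approx(-1.0)

    def test_hand_computed_two_by_two(self):
        a = np.array([[1.0, 0.0], [0.0, 0.0]])
        b = np.array([[1.0, 0.0], [0.0, 1.0]])
        # direct 4-term Pearson formula gives 1/sqrt(3)
        assert fidelity(a, b) == pytest.approx(1 / np.sqrt(3), abs=1e-12)

    def test_constant_image_convention(self):
        x = np.random.default_rng(5).uniform(0, 1, (4, 4))
        assert fidelity(np.ones((4, 4)), x) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fidelity(np.ones((2, 2)), np.ones((3, 3)))

    @settings(max_examples=25, deadline=None)
    @given(
        arrays(float, (6, 6), elements=st.floats(0, 1, width=32)),
        arrays(float, (6, 6), elements=st.floats(0, 1, width=32)),
    )
    def test_symmetric_and_bounded(self, a, b):
        r = fidelity(a, b)
        assert -1.0 - 1e-12 <= r <= 1.0 + 1e-12
        assert r == pytest.approx(fidelity(b, a), abs=1e-12)


class TestSSIM:
    def test_identical_images(self):
        x = np.random.default_rng(6).uniform(0, 1, (32, 32))
        assert ssim_metric(x, x) == pytest.approx(1.0)

    def test_constant_image_scores_lower(self):
        x = np.random.default_rng(7).uniform(0, 1, (32, 32))
        assert ssim_metric(x, np.full_like(x, x.mean())) < ssim_metric(x, x)

    def test_symmetry(self):
        rng = np.random.default_rng(8)
        a, b = rng.uniform(0, 1, (2, 32, 32))
        assert ssim_metric(a, b) == pytest.approx(ssim_metric(b, a), abs=1e-12)

    def test_small_image_fallback(self):
        x = np.random.default_rng(9).uniform(0, 1, (6, 6))
        assert ssim_metric(x, x) == pytest.approx(1.0)

    def test_shuffling_degrades_both_metrics(self):
        rng = np.random.default_rng(10)
        x = make_glyphs(1, shape=(32, 32), seed=0)[0].intensities
        perm = rng.permutation(x.size)
        shuffled = x.ravel()[perm].reshape(x.shape)
        assert fidelity(x, shuffled) < fidelity(x, x)
        assert ssim_metric(x, shuffled) < ssim_metric(x, x)


def _simulate_linear_pairs(basis, geometry, pulse, detector, images, noise_seed=None):
    powers = enc.couple_images(images, basis, geometry, model="incoherent")
    traces, _, _ = enc.synthesize_waveforms(
        powers, group_delays(basis), pulse, detector, noise_seed=noise_seed
    )
    return [(t, img) for t, img in zip(traces, images)]


@pytest.fixture(scope="module")
def oracle_family(oracle_basis):
    """Noiseless incoherent-model data from a low-dimensional 8x8 family.

    The incoherent forward map is linear, so a family whose span is smaller
    than the map's rank is exactly recoverable by the pseudoinverse.
    """
    rng = np.random.default_rng(11)
    dim = 10
    basis_imgs = rng.uniform(0, 1, (dim, 8, 8))
    coeffs = rng.dirichlet(np.ones(dim), size=240)
    images = np.einsum("nd,dij->nij", coeffs, basis_imgs)
    a = oracle_basis.fiber.core_radius_um
    geometry = enc.SceneGeometry(
        pixel_pitch_um=2 * a / 8, image_shape=(8, 8), magnification=1.0,
        offset_um=(0.9, 1.3),
    )
    pairs = _simulate_linear_pairs(
        oracle_basis, geometry, enc.OpticalPulse(), enc.DetectorSpec(), images
    )
    return pairs


class TestLinearOracle:
    def test_pseudoinverse_recovers_low_dim_family(self, oracle_family):
        cfg = DecoderConfig(arch="linear", ridge_lambda=1e-10)
        model = dec.train_decoder(oracle_family, cfg)
        metrics = dec.evaluate_decoder(model, oracle_family)
        assert metrics.fidelity_mean > 0.99

    def test_training_pair_reconstruction(self, oracle_family):
        cfg = DecoderConfig(arch="linear", ridge_lambda=1e-10)
        model = dec.train_decoder(oracle_family, cfg)
        trace, img = oracle_family[0]
        rec = dec.reconstruct(model, trace)
        assert rec.intensities.shape == (64, 64)
        assert fidelity(rec, dec._target_image(img)) > 0.99

    def test_zero_waveform_gives_intercept_image(self, oracle_family):
        cfg = DecoderConfig(arch="linear", ridge_lambda=1e-10)
        model = dec.train_decoder(oracle_family, cfg)
        rec = dec.reconstruct(model, np.zeros(4096))
        mean_stat = model.normalization["mean"] / model.normalization["scale"]
        expected = np.clip(
            (model.model["b"] - mean_stat * model.model["W"].sum(axis=0)).reshape(64, 64),
            0, 1,
        )
        np.testing.assert_allclose(rec.intensities, expected, atol=1e-9)

    def test_output_always_clipped(self, oracle_family):
        cfg = DecoderConfig(arch="linear", ridge_lambda=1e-10)
        model = dec.train_decoder(oracle_family, cfg)
        rng = np.random.default_rng(12)
        rec = dec.reconstruct(model, rng.normal(0, 10, 4096))
        assert rec.intensities.min() >= 0 and rec.intensities.max() <= 1


class TestTraining:
    def test_fixed_seed_reproducible(self, small_system):
        train_pairs = _make_small_pairs(small_system, n=120, seed=13)
        cfg = DecoderConfig(arch="fc5", epochs=2, batch_size=32, seed=5)
        m1 = dec.train_decoder(train_pairs, cfg)
        m2 = dec.train_decoder(train_pairs, cfg)
        w1 = m1.model.get_weights()
        w2 = m2.model.get_weights()
        for a, b in zip(w1, w2):
            np.testing.assert_array_equal(a, b)

    def test_too_few_pairs_rejected(self, small_system):
        pairs = _make_small_pairs(small_system, n=10, seed=14)
        with pytest.raises(ValueError):
            dec.train_decoder(pairs, DecoderConfig(arch="linear"))

    def test_unet_trains_and_loss_decreases(self, small_system):
        train_pairs = _make_small_pairs(small_system, n=100, seed=15)
        cfg = DecoderConfig(arch="unet", epochs=2, batch_size=16, seed=0,
                            unet_base_channels=4)
        X, Y, stats = dec.prepare_training_arrays(train_pairs, cfg)
        from fiberimg.nn import UNet
        net = UNet(base_channels=4, seed=0)
        hist = net.fit(X.reshape(-1, 1, 64, 64), Y.reshape(-1, 1, 64, 64),
                       epochs=3, batch_size=16, lr=1e-3, seed=0)
        assert hist[-1] < hist[0]

    def test_unet_decoder_interface(self, small_system):
        train_pairs = _make_small_pairs(small_system, n=100, seed=16)
        cfg = DecoderConfig(arch="unet", epochs=1, batch_size=16, seed=0,
                            unet_base_channels=2)
        model = dec.train_decoder(train_pairs, cfg)
        rec = dec.reconstruct(model, train_pairs[0][0])
        assert rec.intensities.shape == (64, 64)
        assert rec.intensities.min() >= 0 and rec.intensities.max() <= 1

    def test_noise_monotonically_degrades_linear_decoder(self, small_system):
        imgs = make_glyphs(1300, shape=(16, 16), seed=17)
        stack = np.stack([im.intensities for im in imgs])
        powers = enc.couple_images(
            stack, small_system.basis, small_system.geometry, model="incoherent"
        )
        delays = group_delays(small_system.basis)
        fids = []
        for snr in (40.0, 30.0, 20.0, 10.0):
            det = enc.DetectorSpec(noise_snr_db=snr)
            traces, _, _ = enc.synthesize_waveforms(
                powers, delays, small_system.pulse, det, noise_seed=18
            )
            pairs = list(zip(traces, imgs))
            model = dec.train_decoder(pairs[:1000], DecoderConfig(arch="linear"))
            fids.append(dec.evaluate_decoder(model, pairs[1000:]).fidelity_mean)
        diffs = np.diff(fids)
        assert np.sum(diffs > 0.01) <= 1 and fids[0] > fids[-1]


class TestClassification:
    def test_orthogonal_single_mode_classes_perfectly_separable(self, small_basis):
        pulse, det = enc.OpticalPulse(), enc.DetectorSpec()
        delays = group_delays(small_basis)
        n_modes = len(delays)
        rng = np.random.default_rng(19)
        pairs = []
        for _ in range(150):
            lab = int(rng.integers(0, 2))
            p = np.zeros(n_modes)
            p[0 if lab == 0 else n_modes - 1] = 1.0
            t, _, _ = enc.synthesize_waveforms(p, delays, pulse, det)
            pairs.append((t[0], lab))
        acc = dec.classify_waveforms(pairs[:100], pairs[100:], seed=0, epochs=10)
        assert acc == 1.0

    def test_shuffled_labels_give_chance_accuracy(self, small_system):
        rng = np.random.default_rng(20)
        imgs = make_glyphs(600, shape=(16, 16), n_classes=4, seed=21)
        stack = np.stack([im.intensities for im in imgs])
        traces = small_system.waveforms(stack, noise_seed=22)
        labels = rng.permutation([im.label for im in imgs])
        pairs = [(t, int(l)) for t, l in zip(traces, labels)]
        acc = dec.classify_waveforms(pairs[:400], pairs[400:], seed=0, epochs=5)
        assert abs(acc - 0.25) < 0.15

    def test_single_class_rejected(self):
        pairs = [(np.ones(100), 0)] * 10
        with pytest.raises(ValueError):
            dec.classify_waveforms(pairs, pairs)

    def test_fixed_seed_deterministic_accuracy(self, small_system):
        imgs = make_glyphs(300, shape=(16, 16), n_classes=3, seed=23)
        stack = np.stack([im.intensities for im in imgs])
        traces = small_system.waveforms(stack, noise_seed=24)
        pairs = [(t, im.label) for t, im in zip(traces, imgs)]
        a1 = dec.classify_waveforms(pairs[:200], pairs[200:], seed=1, epochs=3)
        a2 = dec.classify_waveforms(pairs[:200], pairs[200:], seed=1, epochs=3)
        assert a1 == a2


class TestCheckpoint:
    @pytest.mark.parametrize("arch,kwargs", [
        ("linear", {}),
        ("fc5", {"epochs": 1, "batch_size": 32}),
        ("unet", {"epochs": 1, "batch_size": 16, "unet_base_channels": 2}),
    ])
    def test_roundtrip_preserves_predictions(self, tmp_path, small_system, arch, kwargs):
        pairs = _make_small_pairs(small_system, n=100, seed=25)
        cfg = DecoderConfig(arch=arch, seed=0, **kwargs)
        model = dec.train_decoder(pairs, cfg)
        path = tmp_path / "model.bin"
        dec.save_decoder(model, path)
        loaded = dec.load_decoder(path)
        rec1 = dec.reconstruct(model, pairs[0][0]).intensities
        rec2 = dec.reconstruct(loaded, pairs[0][0]).intensities
        np.testing.assert_allclose(rec1, rec2, atol=1e-6)
        assert loaded.provenance == model.provenance

    def test_bad_magic_rejected(self, tmp_path):
        p = tmp_path / "bad.bin"
        p.write_bytes(b"not a checkpoint")
        with pytest.raises(ValueError):
            dec.load_decoder(p)


def _make_small_pairs(system, n, seed):
    imgs = make_glyphs(n, shape=(16, 16), seed=seed)
    stack = np.stack([im.intensities for im in imgs])
    traces = system.waveforms(stack, noise_seed=seed + 1)
    return list(zip(traces, imgs))
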