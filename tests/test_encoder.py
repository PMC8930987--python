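"""Forward encoder: coupling, perturbation, waveform synthesis, frame timing."""

import numpy as np
import pytest

from fiberimg import encoder as enc
from fiberimg.fiber import group_delays, delay_spread_ns
from fiberimg.patterns import ImagePattern


@pytest.fixture()
def facet_geometry(small_basis):
    """Geometry whose pixel grid coincides with the facet grid (identity map)."""
    coords = small_basis.grid_coords_um
    pitch = float(coords[1] - coords[0])
    g = len(coords)
    return enc.SceneGeometry(
        pixel_pitch_um=pitch, image_shape=(g, g), magnification=1.0, offset_um=(0.0, 0.0)
    )


class TestCoupling:
    def test_zero_image_couples_nothing(self, small_basis, small_geometry):
        res = enc.couple_image(np.zeros((16, 16)), small_basis, small_geometry)
        assert np.all(res.mode_powers == 0)

    def test_injecting_one_mode_field_excites_only_it(self, small_basis, facet_geometry):
        # LP(0,1) is nonnegative, so its intensity uniquely determines the field
        idx = next(
            i for i, m in enumerate(small_basis.modes) if (m.l, m.m) == (0, 1)
        )
        psi = small_basis.field_grid[idx]
        res = enc.couple_image(psi**2, small_basis, facet_geometry, model="coherent")
        assert res.mode_powers[idx] == pytest.approx(1.0, abs=1e-6)
        others = np.delete(res.mode_powers, idx)
        assert np.all(others < 1e-6)

    def test_uniform_disc_excites_only_azimuthally_symmetric_modes(
        self, small_basis, facet_geometry
    ):
        res = enc.couple_image(np.ones(facet_geometry.image_shape), small_basis, facet_geometry)
        powers = res.mode_powers
        l_values = np.array([m.l for m in small_basis.modes])
        assert powers[l_values != 0].max() < 1e-4 * powers.max()

    def test_bessel_inequality(self, small_basis, small_geometry):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 1, (16, 16))
        for model in ("coherent", "incoherent"):
            res = enc.couple_image(img, small_basis, small_geometry, model=model)
            assert res.mode_powers.sum() <= res.total_input * (1 + 1e-6) + 1e-12

    def test_normalized_powers_are_fractions(self, small_basis, small_geometry):
        img = np.ones((16, 16))
        res = enc.couple_image(img, small_basis, small_geometry, normalize=True)
        assert 0 < res.mode_powers.sum() <= 1 + 1e-6

    def test_negative_image_rejected(self, small_basis, small_geometry):
        with pytest.raises(ValueError):
            enc.couple_image(-np.ones((16, 16)), small_basis, small_geometry)

    def test_batch_matches_single_image_path(self, small_basis, small_geometry):
        rng = np.random.default_rng(1)
        stack = rng.uniform(0, 1, (3, 16, 16))
        for model in ("coherent", "incoherent"):
            batch = enc.couple_images(stack, small_basis, small_geometry, model=model)
            for i in range(3):
                single = enc.couple_image(stack[i], small_basis, small_geometry, model=model)
                np.testing.assert_allclose(batch[i], single.mode_powers, rtol=1e-12, atol=1e-15)

    def test_speckle_phases_are_seeded(self, small_basis, small_geometry):
        img = np.ones((16, 16))
        a = enc.couple_image(img, small_basis, small_geometry, speckle_seed=5)
        b = enc.couple_image(img, small_basis, small_geometry, speckle_seed=5)
        c = enc.couple_image(img, small_basis, small_geometry, speckle_seed=6)
        np.testing.assert_array_equal(a.mode_powers, b.mode_powers)
        assert not np.allclose(a.mode_powers, c.mode_powers)


class TestPerturbation:
    def _coupling(self, small_basis, small_geometry):
        rng = np.random.default_rng(2)
        return enc.couple_image(rng.uniform(0, 1, (16, 16)), small_basis, small_geometry)

    def test_zero_strength_is_identity(self, small_basis, small_geometry):
        res = self._coupling(small_basis, small_geometry)
        pert, delays = enc.perturb_coupling(res, small_basis, 0.0, 50.0, seed=0)
        np.testing.assert_allclose(pert.mode_powers, res.mode_powers, atol=1e-12)
        np.testing.assert_array_equal(delays, group_delays(small_basis))

    @pytest.mark.parametrize("strength", [0.2, 0.7, 1.0])
    def test_total_power_conserved(self, small_basis, small_geometry, strength):
        res = self._coupling(small_basis, small_geometry)
        pert, _ = enc.perturb_coupling(res, small_basis, strength, 50.0, seed=3)
        assert pert.mode_powers.sum() == pytest.approx(res.mode_powers.sum(), rel=1e-9)

    def test_deterministic_given_seed(self, small_basis, small_geometry):
        res = self._coupling(small_basis, small_geometry)
        a = enc.perturb_coupling(res, small_basis, 1.0, 50.0, seed=9)
        b = enc.perturb_coupling(res, small_basis, 1.0, 50.0, seed=9)
        np.testing.assert_array_equal(a[0].mode_powers, b[0].mode_powers)
        np.testing.assert_array_equal(a[1], b[1])

    def test_batch_matches_single(self, small_basis, small_geometry):
        res = self._coupling(small_basis, small_geometry)
        res_inc = enc.CouplingResult(res.mode_powers, None, "incoherent")
        single, d_single = enc.perturb_coupling(res_inc, small_basis, 0.5, 20.0, seed=4)
        batch, d_batch = enc.perturb_powers(
            res.mode_powers[None], group_delays(small_basis), 0.5, 20.0, seed=4
        )
        np.testing.assert_allclose(batch[0], single.mode_powers, rtol=1e-10)
        np.testing.assert_allclose(d_batch, d_single)

    def test_invalid_strength_rejected(self, small_basis, small_geometry):
        res = self._coupling(small_basis, small_geometry)
        with pytest.raises(ValueError):
            enc.perturb_coupling(res, small_basis, 1.5, 0.0, seed=0)


class TestWaveformSynthesis:
    def test_single_mode_energy_conservation(self, pulse, detector):
        res = enc.CouplingResult(np.array([1.0]), None, "incoherent")
        w = enc.synthesize_waveform(res, np.array([0.0]), pulse, detector)
        assert w.samples.sum() * w.dt_ps == pytest.approx(1.0, abs=1e-3)

    def test_two_resolved_equal_subpulses(self, pulse, detector):
        res = enc.CouplingResult(np.array([0.5, 0.5]), None, "incoherent")
        w = enc.synthesize_waveform(res, np.array([0.0, 1000.0]), pulse, detector)
        t = w.t_ps
        half = len(w.samples) // 2
        p1 = t[np.argmax(w.samples[:half])]
        p2 = t[half + np.argmax(w.samples[half:])]
        assert p2 - p1 == pytest.approx(1000.0, abs=w.dt_ps)
        assert w.samples[:half].max() == pytest.approx(w.samples[half:].max(), rel=1e-6)

    def test_support_contained_in_delay_window(self, small_system):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 1, (16, 16))
        traces = small_system.waveforms(img[None])
        delays = small_system.delays_ps()
        spread_ps = delays.max() - delays.min()
        t = -5 * small_system.pulse.fwhm_ps + small_system.detector.dt_ps * np.arange(
            traces.shape[1]
        )
        nz = np.nonzero(traces[0] > 1e-9 * traces[0].max())[0]
        assert t[nz[0]] >= -500.0
        assert t[nz[-1]] <= spread_ps + 500.0

    def test_empty_mode_set_rejected(self, pulse, detector):
        res = enc.CouplingResult(np.array([]), None, "incoherent")
        with pytest.raises(ValueError):
            enc.synthesize_waveform(res, np.array([]), pulse, detector)

    def test_incoherent_model_linearity(self, small_basis, small_geometry, pulse, detector):
        rng = np.random.default_rng(4)
        i1, i2 = rng.uniform(0, 1, (2, 16, 16))
        alpha, beta = 0.3, 1.7
        delays = group_delays(small_basis)

        def wf(img):
            p = enc.couple_images(img[None], small_basis, small_geometry, model="incoherent")
            t, _, _ = enc.synthesize_waveforms(p, delays, pulse, detector)
            return t[0]

        combined = wf(alpha * i1 + beta * i2)
        np.testing.assert_allclose(combined, alpha * wf(i1) + beta * wf(i2), atol=1e-9)

    def test_pre_noise_integral_equals_coupled_power(self, small_system):
        rng = np.random.default_rng(5)
        img = rng.uniform(0, 1, (16, 16))
        powers = enc.couple_images(
            img[None], small_system.basis, small_system.geometry, model="coherent"
        )
        traces, dt, _ = enc.synthesize_waveforms(
            powers, small_system.delays_ps(), small_system.pulse, small_system.detector
        )
        assert traces[0].sum() * dt == pytest.approx(powers.sum(), rel=1e-3)

    def test_noise_deterministic_given_seed(self, pulse, detector):
        res = enc.CouplingResult(np.array([1.0, 0.5]), None, "incoherent")
        d = np.array([0.0, 500.0])
        a = enc.synthesize_waveform(res, d, pulse, detector, noise_seed=11)
        b = enc.synthesize_waveform(res, d, pulse, detector, noise_seed=11)
        np.testing.assert_array_equal(a.samples, b.samples)
        c = enc.synthesize_waveform(res, d, pulse, detector, noise_seed=12)
        assert not np.array_equal(a.samples, c.samples)

    def test_support_scales_linearly_with_length(self, small_basis):
        spreads = [delay_spread_ns(small_basis, length_m=L) for L in (150, 400, 1000)]
        assert spreads[1] == pytest.approx(spreads[0] * 400 / 150, rel=1e-12)
        assert spreads[2] == pytest.approx(spreads[0] * 1000 / 150, rel=1e-12)


class TestFrameTiming:
    def test_reference_period_no_overlap(self, reference_basis, small_geometry, pulse, detector):
        delays = group_delays(reference_basis)
        span = enc.frame_support_ns(delays, pulse, detector)
        assert span < 65.0  # one frame fits inside the repetition period

    def test_waveform_train_overlap_flag(self, small_system):
        rng = np.random.default_rng(6)
        imgs = [ImagePattern(rng.uniform(0, 1, (16, 16)), kind="grayscale") for _ in range(3)]
        span = enc.frame_support_ns(
            small_system.delays_ps(), small_system.pulse, small_system.detector
        )
        long_pulse = enc.OpticalPulse(period_ns=span * 2)
        _, overlap = enc.waveform_train(
            imgs, small_system.basis, small_system.geometry, long_pulse, small_system.detector
        )
        assert overlap is False
        short_pulse = enc.OpticalPulse(period_ns=span * 0.5)
        _, overlap = enc.waveform_train(
            imgs, small_system.basis, small_system.geometry, short_pulse, small_system.detector
        )
        assert overlap is True

    def test_exact_equality_does_not_overlap(self, small_system):
        span = enc.frame_support_ns(
            small_system.delays_ps(), small_system.pulse, small_system.detector
        )
        boundary_pulse = enc.OpticalPulse(period_ns=span)
        imgs = [ImagePattern(np.ones((16, 16)), kind="grayscale")]
        _, overlap = enc.waveform_train(
            imgs, small_system.basis, small_system.geometry, boundary_pulse,
            small_system.detector,
        )
        assert overlap is False

    @pytest.mark.parametrize(
        "span_ns,expected_mhz", [(18.7, 53.5), (65.0, 15.4), (1000.0, 1.0)]
    )
    def test_max_frame_rate(self, span_ns, expected_mhz):
        assert enc.max_frame_rate(span_ns) == expected_mhz

    def test_record_duration_and_frame_depth(self):
        # 62.5 Msamples at 100 GS/s hold 625 us, i.e. ~9600 frames at 65 ns
        dur = enc.record_duration_us(62.5e6, 100.0)
        assert dur == pytest.approx(625.0, rel=1e-12)
        assert enc.frame_depth(dur, 65.0) == 9615

    def test_undersampled_detector_warns(self, caplog):
        with caplog.at_level("WARNING"):
            enc.DetectorSpec(bandwidth_ghz=30.0, sample_rate_gsps=40.0)
        assert any("bandwidth" in r.message for r in caplog.records)


def test_frame_rate_inverse_in_mode_count():
    """At fixed core size, rate x mode count is roughly constant across NA.

    Mode count scales with V^2 while the delay spread (hence 1/rate) scales
    with the index contrast ~ NA^2, so their product is nearly invariant.
    """
    from fiberimg.fiber import FiberSpec, find_lp_modes

    products = []
    for na in (0.15, 0.22, 0.30):
        basis = find_lp_modes(FiberSpec(core_radius_um=25.0, na=na), grid_size=32)
        span_ns = delay_spread_ns(basis)
        products.append(len(basis) * (1000.0 / span_ns))
    products = np.asarray(products)
    assert products.max() / products.min() < 1.25
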