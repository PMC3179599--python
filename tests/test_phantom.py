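"""Phantom physics: AIF, Fermi response, convolution, signal model, render."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gamma as gamma_fn

import ktperf as kp
from ktperf.phantom import aif_gamma_variate, fermi_impulse_response, signal_model


class TestAIF:
    def test_zero_at_and_before_onset(self):
        p = kp.AIFParams(onset_s=1.0)
        t = np.array([0.0, 0.5, 1.0])
        assert np.all(aif_gamma_variate(t, p) == 0)

    def test_normalized_peak_at_alpha_beta(self):
        p = kp.AIFParams(onset_s=0.5, amplitude_mM=2.3, shape_alpha=3.5, shape_beta_s=0.4)
        t_peak = p.onset_s + p.shape_alpha * p.shape_beta_s
        assert aif_gamma_variate(np.array([t_peak]), p)[0] == pytest.approx(2.3, rel=1e-12)
        # peak is the global maximum on a dense grid
        t = np.linspace(0, 20, 20001)
        assert aif_gamma_variate(t, p).max() <= 2.3 * (1 + 1e-12)

    def test_area_matches_quadrature_oracle(self):
        # closed-form area of the normalized gamma-variate:
        # A * t_peak * e^alpha * Gamma(alpha+1) / alpha^(alpha+1)
        p = kp.AIFParams(onset_s=0.0, amplitude_mM=1.0, shape_alpha=3.0, shape_beta_s=1.0)
        a = p.shape_alpha
        analytic = p.shape_alpha * p.shape_beta_s * np.exp(a) * gamma_fn(a + 1) / a ** (a + 1)
        t = np.arange(0, 60.0, 1e-3)
        numeric = np.trapezoid(aif_gamma_variate(t, p), dx=1e-3)
        assert numeric == pytest.approx(analytic, rel=1e-6)

    def test_invalid_shape_raises(self):
        with pytest.raises(kp.ConfigurationError):
            kp.AIFParams(shape_alpha=-1.0)


class TestFermiResponse:
    def test_zero_amplitude_gives_zero_response(self):
        t = np.linspace(0, 10, 50)
        assert np.all(fermi_impulse_response(t, 0.0, 2.0, 1.0) == 0)

    def test_logistic_center_at_zero_shoulder(self):
        # k*tau0 = 0 puts t=0 at the logistic center: h(0) = F/2
        assert fermi_impulse_response(np.array([0.0]), 3.0, 5.0, 0.0)[0] == pytest.approx(1.5)

    @given(
        F=st.floats(0.001, 10), k=st.floats(0.01, 20), tau0=st.floats(0, 5),
        seed=st.integers(0, 1000),
    )
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_monotone_nonincreasing(self, F, k, tau0, seed):
        t = np.sort(np.random.default_rng(seed).uniform(0, 10, 30))
        h = fermi_impulse_response(t, F, k, tau0)
        assert np.all(np.diff(h) <= 1e-15 * F)

    def test_mbf_roundtrip_through_amplitude(self):
        for mbf in (0.5, 1.2, 7.3, 12.0):
            F = kp.mbf_to_fermi_amplitude(mbf, 2.0, 2.5)
            assert kp.fermi_mbf(F, 2.0, 2.5) == pytest.approx(mbf, rel=1e-12)


class TestTissueConcentration:
    def test_unit_impulse_is_identity(self, rng):
        dt = 0.1
        aif = rng.uniform(0, 2, 30)
        h = np.zeros(30)
        h[0] = 1.0 / dt
        np.testing.assert_allclose(kp.tissue_concentration(aif, h, dt), aif, rtol=1e-12)

    def test_zero_aif_gives_zero(self):
        assert np.all(kp.tissue_concentration(np.zeros(20), np.ones(20), 0.1) == 0)

    def test_matches_double_loop_oracle(self, rng):
        dt = 0.12
        aif = rng.uniform(0, 3, 40)
        h = rng.uniform(0, 1, 40)
        out = kp.tissue_concentration(aif, h, dt)
        oracle = np.zeros(40)
        for i in range(40):
            for j in range(i + 1):
                oracle[i] += dt * aif[j] * h[i - j]
        np.testing.assert_allclose(out, oracle, rtol=1e-12)

    def test_mismatched_lengths_raise(self):
        with pytest.raises(kp.InputError):
            kp.tissue_concentration(np.zeros(10), np.zeros(11), 0.1)


class TestSignalModel:
    def test_closed_form_value(self):
        # pre-contrast myocardium-like tissue at TD = 100 ms
        expected = 1000.0 * (1.0 - np.exp(-0.1 / 1.4))
        assert signal_model(0.0, 1.4, 3.7, 0.1, 1000.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(68.94, abs=0.01)

    def test_saturates_at_equilibrium(self):
        assert signal_model(1e9, 1.4, 3.7, 0.1, 1000.0) == pytest.approx(1000.0)

    def test_strictly_increasing_in_concentration(self):
        c = np.linspace(0, 10, 200)
        si = signal_model(c, 1.4, 3.7, 0.1, 1000.0)
        assert np.all(np.diff(si) > 0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(kp.InputError):
            signal_model(-0.1, 1.4, 3.7, 0.1, 1000.0)


class TestRenderPhantom:
    def test_seeded_reproducibility_bit_identical(self):
        cfg = kp.PhantomConfig(grid_size=32, n_frames=20, noise_sd=4.0, seed=3)
        a, _ = kp.render_phantom(cfg)
        b, _ = kp.render_phantom(cfg)
        assert np.array_equal(a.data, b.data)

    def test_frame_times_exact(self, control_phantom):
        series, _ = control_phantom
        expected = np.arange(60) * (60.0 / 495.1)
        assert np.array_equal(series.frame_times_s, expected)

    def test_uniform_mbf_sector_curves_identical(self, control_phantom):
        # zero noise + equal MBF: the three sector-mean curves coincide
        series, gt = control_phantom
        curves = [series.data[:, gt.sector_masks[l]].mean(axis=1) for l in kp.SECTOR_LABELS_3]
        np.testing.assert_allclose(curves[1], curves[0], rtol=1e-9)
        np.testing.assert_allclose(curves[2], curves[0], rtol=1e-9)

    def test_within_sector_pixel_curves_agree(self, control_phantom):
        series, gt = control_phantom
        m = gt.sector_masks["septal"]
        px = series.data[:, m]
        assert np.abs(px - px[:, :1]).max() < 1e-9 * px.max()

    def test_ground_truth_mbf_closed_form(self, infarct_phantom):
        _, gt = infarct_phantom
        for label, (F, k, tau0) in gt.sector_fermi.items():
            assert kp.fermi_mbf(F, k, tau0) == pytest.approx(gt.sector_mbf[label], rel=1e-12)
            mask_vals = gt.mbf_map[gt.sector_masks[label]]
            assert np.all(mask_vals == gt.sector_mbf[label])

    def test_lv_enhancement_ratio_in_reported_regime(self, control_phantom):
        # first-pass LV enhancement comparable to the in-vivo ratio 6.32 +/- 0.98
        series, gt = control_phantom
        lv = kp.extract_curve(series, gt.lv_roi_mask, "lv")
        assert 5.0 <= kp.enhancement_ratio(lv) <= 8.0

    def test_concentration_and_mbf_nonnegative(self, infarct_phantom):
        _, gt = infarct_phantom
        assert np.all(gt.mbf_map >= 0)
        assert np.all(gt.concentration_series >= 0)

    def test_oversized_geometry_raises(self):
        g = kp.HeartGeometry(endo_radius_mm=9.0, epi_radius_mm=13.0)
        with pytest.raises(kp.GeometryError):
            kp.render_phantom(kp.PhantomConfig(geometry=g))

    def test_config_invariants_enforced(self):
        with pytest.raises(kp.ConfigurationError):
            kp.PhantomConfig(n_frames=5)
        with pytest.raises(kp.ConfigurationError):
            kp.PhantomConfig(sector_mbf_ml_g_min=(7.3, -1.0, 7.3))
        with pytest.raises(kp.ConfigurationError):
            kp.HeartGeometry(endo_radius_mm=3.0, epi_radius_mm=2.0)
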