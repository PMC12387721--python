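"""ESF extraction, phase alignment, logistic fitting, LSF and TTF.

Closed-form oracles used throughout:
- logistic ESF of rate b → LSF ∝ sech²(bx/2) → TTF(f) = s/sinh(s), s=2π²f/b,
  hence f50 = 0.110292·b, f10 = 0.227953·b and FWHM = 2·ln(3+2√2)/b;
- Gaussian LSF of width σ → TTF(f) = exp(−2π²σ²f²), f50 = √(ln2)/(√2πσ).
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import erf

import cttf
from cttf.esf_ttf import (
    LOGISTIC_F10_COEF,
    LOGISTIC_F50_COEF,
    ESFSample,
    FitError,
    FittedESF,
    LSFCurve,
    SamplingError,
    TTFConfig,
    align_phase,
    esf_to_lsf,
    extract_esf,
    fit_logistic_esf,
    logistic_ttf,
    lsf_to_ttf,
    measure_ttf,
)


def _logistic_cloud(a, b, c, d, n=2000, span=6.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(-span, span, n)
    y = a / (1 + np.exp(-b * (x - c))) + d + noise * rng.standard_normal(n)
    return ESFSample(x, y, rng.uniform(-np.pi, np.pi, n), "test", pin_radius_mm=12.0)


class TestLogisticFit:
    def test_exact_recovery_without_noise(self):
        s = _logistic_cloud(1000.0, 3.0, 0.0, 0.0)
        fit = fit_logistic_esf(s)
        assert fit.a == pytest.approx(1000.0, rel=1e-6)
        assert fit.b == pytest.approx(3.0, rel=1e-6)
        assert fit.c == pytest.approx(0.0, abs=1e-6)
        assert fit.d == pytest.approx(0.0, abs=1e-3)

    def test_rate_recovered_within_2pct_under_noise(self):
        # Monte Carlo: 2000 samples, 5 HU noise
        errs = [
            abs(fit_logistic_esf(_logistic_cloud(1000, 3.0, 0, 0, noise=5.0, seed=s)).b - 3.0) / 3.0
            for s in range(40)
        ]
        assert np.mean(errs) < 0.02
        assert np.max(errs) < 0.05

    def test_negative_amplitude_dark_pin(self):
        s = _logistic_cloud(-1000.0, 2.5, 0.0, 0.0, noise=5.0, seed=1)
        fit = fit_logistic_esf(s)
        assert fit.a < 0
        assert abs(fit.a) == pytest.approx(1000.0, rel=0.02)

    def test_zero_contrast_rejected(self):
        s = _logistic_cloud(0.0, 3.0, 0.0, 100.0)
        with pytest.raises(FitError):
            fit_logistic_esf(s)

    def test_low_contrast_flag(self):
        s = _logistic_cloud(20.0, 3.0, 0.0, 0.0, noise=2.0, seed=2)
        fit = fit_logistic_esf(s, noise_sd_hu=10.0)
        assert "low-contrast" in fit.flags


class TestLSF:
    @pytest.mark.parametrize("b", [1.0, 3.0, 5.0])
    def test_fwhm_matches_closed_form(self, b):
        lsf = esf_to_lsf(FittedESF(500.0, b, 0.0, 0.0, 0.0))
        half = lsf.values >= lsf.values.max() / 2
        fwhm = lsf.x_mm[half][-1] - lsf.x_mm[half][0]
        expected = 2 * math.log(3 + 2 * math.sqrt(2)) / b
        assert fwhm == pytest.approx(expected, abs=2 * lsf.spacing_mm)

    def test_unit_area_and_positive_peak_for_negative_amplitude(self):
        lsf = esf_to_lsf(FittedESF(-800.0, 2.0, 0.3, 100.0, 0.0))
        assert lsf.values.sum() == pytest.approx(1.0)
        assert lsf.values.max() > 0
        assert (lsf.values >= 0).all()

    def test_tails_are_zeroed(self):
        lsf = esf_to_lsf(FittedESF(1000.0, 3.0, 0.0, 0.0, 0.0))
        peak = lsf.values.max()
        assert lsf.values[0] < 1e-6 * peak and lsf.values[-1] < 1e-6 * peak


class TestTTF:
    def test_delta_lsf_gives_flat_ttf(self):
        vals = np.zeros(101)
        vals[50] = 1.0
        res = lsf_to_ttf(LSFCurve(np.arange(101) * 0.02, vals, 0.02))
        assert np.allclose(res.ttf, 1.0, atol=1e-12)

    def test_ttf_normalized_at_zero_frequency(self):
        res = lsf_to_ttf(esf_to_lsf(FittedESF(100.0, 2.0, 0.0, 0.0, 0.0)))
        assert res.ttf[0] == 1.0

    @pytest.mark.parametrize("b", [1.0, 2.0, 3.0, 5.0])
    def test_logistic_ttf_matches_s_over_sinh_s(self, b):
        res = lsf_to_ttf(esf_to_lsf(FittedESF(1000.0, b, 0.0, 0.0, 0.0)))
        m = res.frequencies_inv_mm <= 1.5
        expected = logistic_ttf(res.frequencies_inv_mm[m], b)
        assert np.abs(res.ttf[m] - expected).max() < 1e-3
        assert res.f50_inv_mm == pytest.approx(LOGISTIC_F50_COEF * b, rel=0.005)
        assert res.f10_inv_mm == pytest.approx(LOGISTIC_F10_COEF * b, rel=0.005)

    @pytest.mark.parametrize("sigma", [0.3, 0.5, 0.8])
    def test_gaussian_lsf_oracle(self, sigma):
        dx = 0.02
        x = np.arange(-8 * sigma, 8 * sigma + dx / 2, dx)
        g = np.exp(-0.5 * (x / sigma) ** 2)
        res = lsf_to_ttf(LSFCurve(x, g / g.sum(), dx))
        assert res.f50_inv_mm == pytest.approx(math.sqrt(math.log(2)) / (math.sqrt(2) * math.pi * sigma), rel=0.005)
        assert res.f10_inv_mm == pytest.approx(math.sqrt(math.log(10)) / (math.sqrt(2) * math.pi * sigma), rel=0.005)

    @given(b=st.floats(0.5, 8.0))
    @settings(max_examples=25, deadline=None)
    def test_f50_f10_ratio_universal_for_logistic(self, b):
        res = lsf_to_ttf(esf_to_lsf(FittedESF(500.0, b, 0.0, 0.0, 0.0)))
        assert res.f50_inv_mm / res.f10_inv_mm == pytest.approx(0.48384, abs=0.002)


class TestExtraction:
    def test_step_edge_samples_split_by_sign(self, sharp_noiseless_acr):
        img, truth = sharp_noiseless_acr
        body = cttf.segment_body(img)
        masked = cttf.apply_body_mask(img, body)
        pins = cttf.segment_pins(masked, body, cttf.get_template("computational_acr"))
        rois = cttf.place_rois(masked, body, pins)
        bone = next(r for r in rois if r.material_name == "Bone")
        s = extract_esf(masked, bone)
        px = img.spacing_mm[0]
        inside = s.distances_mm < -0.8 * px
        outside = s.distances_mm > 0.8 * px
        assert np.all(s.values_hu[inside] == 955.0)
        assert np.all(s.values_hu[outside] == 0.0)
        assert s.distances_mm.min() < 0 < s.distances_mm.max()

    def test_blurred_edge_matches_erf_profile(self):
        # single bright pin, Gaussian blur, no noise: the radial ESF must track
        # A·(1−Φ(x/σ)) to within the circular-edge curvature correction
        sigma = 0.5
        spec = cttf.PhantomSpec(
            pins=[cttf.PinSpec("Bone", (100.0, 100.0), 12.5, 955.0)],
            blur=cttf.GaussianBlur(sigma), noise_sd_hu=0.0,
        )
        img, _ = cttf.render(spec)
        body = cttf.segment_body(img)
        masked = cttf.apply_body_mask(img, body)
        bone = cttf.PinDetection("Bone", (100.0, 100.0), 12.5)
        rois = cttf.place_rois(masked, body, [bone])
        s = extract_esf(masked, rois[0])
        model = 955.0 * 0.5 * (1 - erf(s.distances_mm / (math.sqrt(2) * sigma)))
        resid = s.values_hu - model
        assert np.abs(resid).max() < 0.03 * 955.0

    def test_too_small_roi_raises_sampling_error(self):
        img = cttf.HUImage(pixels=np.zeros((40, 40)), spacing_mm=(0.5, 0.5))
        roi = cttf.PinROI("x", (10.0, 10.0), 2.0, 1.0, 0, 0, 1, 0,
                          inner_mask=np.zeros((40, 40), bool),
                          outer_mask=np.zeros((40, 40), bool))
        with pytest.raises(SamplingError):
            extract_esf(img, roi, added_size_mm=0.5)


class TestAlignment:
    def _cloud_with_sector_shifts(self, shift_fn, seed=0):
        rng = np.random.default_rng(seed)
        n = 6000
        ang = rng.uniform(-np.pi, np.pi, n)
        x = rng.uniform(-6, 6, n)
        x_true = x - shift_fn(ang)  # each sector's edge sits at shift_fn(ang)
        y = 1000.0 / (1 + np.exp(-3.0 * x_true)) + 4.0 * rng.standard_normal(n)
        return ESFSample(x, y, ang, "test", pin_radius_mm=12.0)

    def test_identity_when_already_aligned(self):
        s = self._cloud_with_sector_shifts(lambda a: 0.0 * a)
        aligned = align_phase(s)
        fit0 = fit_logistic_esf(s)
        fit1 = fit_logistic_esf(aligned)
        assert abs(fit1.c - fit0.c) < 0.05

    def test_alignment_reduces_fit_residual_for_warped_edge(self):
        s = self._cloud_with_sector_shifts(lambda a: 0.4 * np.sin(2 * a))
        aligned = align_phase(s)
        assert fit_logistic_esf(aligned).rmse_hu < fit_logistic_esf(s).rmse_hu

    def test_offcentre_extraction_recovers_edge_position(self, acr_rendered):
        # deliberately bias the centroid by ~0.7 px; after phase alignment the
        # fitted edge centre should stay put
        img, truth = acr_rendered
        body = cttf.segment_body(img)
        masked = cttf.apply_body_mask(img, body)
        pins = cttf.segment_pins(masked, body, cttf.get_template("computational_acr"))
        bone = next(p for p in pins if p.material_name == "Bone")
        rois = cttf.place_rois(masked, body, [bone])
        c_ref = fit_logistic_esf(align_phase(extract_esf(masked, rois[0]))).c

        off = 0.7 * img.spacing_mm[0]
        bone_off = cttf.PinDetection(bone.material_name,
                                     (bone.centroid_mm[0] + off, bone.centroid_mm[1]),
                                     bone.radius_mm, bone.area_px)
        rois_off = cttf.place_rois(masked, body, [bone_off])
        c_off = fit_logistic_esf(align_phase(extract_esf(masked, rois_off[0]))).c
        assert abs(c_off - c_ref) < 0.05


class TestPipeline:
    def test_measure_ttf_runs_all_pins(self, acr_measurement):
        assert len(acr_measurement.results) == 4
        assert acr_measurement.failures == []
        for res in acr_measurement.results:
            assert res.ttf[0] == 1.0
            assert 0 < res.f50_inv_mm < res.f10_inv_mm

    def test_empirical_mode_close_to_fitted_at_high_cnr(self, acr_rendered):
        img, _ = acr_rendered
        fitted = cttf.measure_slice(img, "computational_acr", TTFConfig())
        raw = cttf.measure_slice(img, "computational_acr", TTFConfig(enable_curve_fit=False))
        f_fit = next(r.f50_inv_mm for r in fitted.results if r.material_name == "Bone")
        f_raw = next(r.f50_inv_mm for r in raw.results if r.material_name == "Bone")
        assert f_raw == pytest.approx(f_fit, rel=0.10)

    def test_contrast_dependent_blur_orders_f50(self):
        # sharper kernel on bone than acrylic → bone must resolve finer detail
        blur = {"body": cttf.GaussianBlur(0.5), "Bone": cttf.GaussianBlur(0.4),
                "Polyethylene": cttf.GaussianBlur(0.5), "Air": cttf.GaussianBlur(0.5),
                "Acrylic": cttf.GaussianBlur(0.6)}
        spec = cttf.preset("acr_like", seed=5, blur=blur)
        img, _ = cttf.render(spec)
        meas = cttf.measure_slice(img, "computational_acr")
        f = {r.material_name: r.f50_inv_mm for r in meas.results}
        assert f["Bone"] > f["Acrylic"]
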