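"""Unit and property tests for the preprocessing chain."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungraman import preprocess as pp
from lungraman import synthetic_cohort as sc

AXIS = pp.COMMON_AXIS


class TestAverageRepeats:
    def test_single_frame_identity(self):
        frame = np.array([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(pp.average_repeats([frame]), frame)

    def test_two_frames_mean(self):
        out = pp.average_repeats([np.zeros(4), np.full(4, 2.0)])
        np.testing.assert_array_equal(out, np.ones(4))

    def test_ragged_frames_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            pp.average_repeats([np.zeros(4), np.zeros(5)])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pp.average_repeats([])

    def test_variance_reduction_by_repeat_count(self):
        """Averaging 10 i.i.d. frames shrinks the per-pixel variance by
        ~10x (Monte-Carlo)."""
        rng = np.random.default_rng(0)
        frames = rng.normal(0.0, 1.0, (2000, 10, 64))
        means = frames.mean(axis=1)
        assert means.var() == pytest.approx(1.0 / 10.0, rel=0.05)


class TestSubtractDark:
    def test_equal_dark_and_times_gives_zero(self):
        frame = np.array([3.0, 4.0])
        out = pp.subtract_dark(frame, frame, 0.075, 0.075)
        np.testing.assert_array_equal(out, np.zeros(2))

    def test_integration_time_scaling(self):
        frame = np.full(5, 400.0)
        dark = np.full(5, 100.0)
        out = pp.subtract_dark(frame, dark, 0.075, 0.050)
        np.testing.assert_allclose(out, 250.0)

    def test_zero_dark_identity(self):
        frame = np.array([1.0, 2.0])
        np.testing.assert_array_equal(pp.subtract_dark(frame, np.zeros(2), 0.075, 0.05), frame)

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            pp.subtract_dark(np.ones(2), np.ones(2), 0.0, 0.05)

    def test_negative_results_not_clipped(self):
        out = pp.subtract_dark(np.full(3, 10.0), np.full(3, 10.0), 0.075, 0.05)
        assert np.all(out < 0)


class TestCalibration:
    def test_exact_quadratic_recovered(self):
        px = np.array([100.0, 300.0, 500.0, 700.0, 900.0])
        coeffs = (800.0, 0.85, 2e-5)
        ref = np.polynomial.polynomial.polyval(px, coeffs)
        fit = pp.fit_calibration(px, ref, order=2)
        np.testing.assert_allclose(fit.coefficients, coeffs, rtol=1e-9)
        assert fit.rms_residual < 1e-8

    def test_two_points_linear_exact(self):
        fit = pp.fit_calibration([0.0, 1000.0], [800.0, 1700.0], order=1)
        assert fit.rms_residual == pytest.approx(0.0, abs=1e-10)
        assert fit(np.array([500.0]))[0] == pytest.approx(1250.0)

    def test_jittered_peaks_fit_within_jitter_scale(self, instrument):
        """Half-pixel peak-position jitter leaves an rms residual below
        the jitter mapped to wavenumber units."""
        rng = np.random.default_rng(3)
        px = np.linspace(50, instrument.n_pixels - 50, 8)
        ref = np.polynomial.polynomial.polyval(px, instrument.true_pixel_to_wavenumber)
        jittered = px + rng.uniform(-0.5, 0.5, px.size)
        fit = pp.fit_calibration(jittered, ref, order=2)
        step = np.diff(instrument.pixel_wavenumbers()).max()
        assert fit.rms_residual < 0.5 * step

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError):
            pp.fit_calibration([1.0, 2.0], [800.0, 810.0], order=2)

    def test_non_monotone_fit_rejected(self):
        px = [0.0, 10.0, 20.0]
        ref = [800.0, 900.0, 820.0]  # not increasing
        with pytest.raises(ValueError):
            pp.fit_calibration(px, sorted(ref), order=2)


class TestResponse:
    def test_measured_equals_certified_gives_unit_factors(self):
        shape = np.linspace(1.0, 2.0, 256)
        resp = pp.estimate_response(shape, shape)
        np.testing.assert_allclose(resp.factors, 1.0, rtol=1e-9)

    def test_doubled_measurement_gives_factor_two(self):
        shape = np.linspace(1.0, 2.0, 256)
        resp = pp.estimate_response(2.0 * shape, shape)
        np.testing.assert_allclose(resp.factors, 2.0, rtol=1e-9)

    def test_recovers_true_instrument_response(self, instrument):
        """Noise-free reference measurement recovers the generator's
        response curve within 2% RMS."""
        refs = sc.synth_reference_frames(instrument)
        certified = sc.certified_reference_shape(instrument.pixel_wavenumbers())
        resp = pp.estimate_response(refs["broadband_reference_frame"], certified)
        rel = resp.factors / instrument.response_curve - 1.0
        assert np.sqrt(np.mean(rel**2)) < 0.02

    def test_correct_response_identity_and_halving(self):
        spec = np.array([2.0, 4.0, 6.0])
        np.testing.assert_array_equal(pp.correct_response(spec, pp.flat_response(3)), spec)
        resp2 = pp.ResponseCurve(factors=np.full(3, 2.0))
        np.testing.assert_allclose(pp.correct_response(spec, resp2), spec / 2.0)

    def test_roundtrip_recovers_pure_signal(self, instrument):
        refs = sc.synth_reference_frames(instrument)
        certified = sc.certified_reference_shape(instrument.pixel_wavenumbers())
        resp = pp.estimate_response(refs["broadband_reference_frame"], certified)
        signal = np.linspace(10.0, 20.0, instrument.n_pixels)
        measured = instrument.response_curve * signal
        recovered = pp.correct_response(measured, resp)
        rel = recovered / signal - 1.0
        assert np.sqrt(np.mean(rel**2)) < 0.02

    def test_nonpositive_certified_rejected(self):
        with pytest.raises(ValueError):
            pp.estimate_response(np.ones(10), np.zeros(10))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pp.correct_response(np.ones(5), pp.flat_response(4))


class TestBubbleFill:
    def test_constant_spectrum_is_its_own_baseline(self):
        spec = np.full(AXIS.size, 3.3)
        baseline, raman = pp.bubblefill(spec, AXIS, 100.0)
        np.testing.assert_array_equal(baseline, spec)
        np.testing.assert_array_equal(raman, np.zeros(AXIS.size))

    def test_broad_background_mostly_removed(self):
        """A 400 cm^-1-wide bump leaves a residual far below its
        amplitude (oracle-derived bound: ~11% worst-case arc sag)."""
        bg = sc.synth_background(AXIS, 100.0, decay_scale=None, bumps=[(1250.0, 400.0, 1.0)])
        _, raman = pp.bubblefill(bg, AXIS, 100.0)
        assert np.abs(raman).max() < 0.12 * bg.max()

    def test_peak_height_recovered_within_ten_percent(self):
        """A 15 cm^-1-fwhm peak on a dominant fluorescence background is
        recovered within 10% of its true amplitude."""
        amp = 50.0
        peak = amp * (7.5**2 / ((AXIS - 1200.0) ** 2 + 7.5**2))
        bg = sc.synth_background(AXIS, 100.0)
        _, raman = pp.bubblefill(bg + peak, AXIS, 100.0)
        recovered = raman[np.argmin(np.abs(AXIS - 1200.0))]
        assert recovered == pytest.approx(amp, rel=0.10)

    def test_baseline_below_spectrum_and_raman_nonnegative(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            spec = sc.synth_background(AXIS, 50.0) + rng.normal(0, 2.0, AXIS.size)
            baseline, raman = pp.bubblefill(spec, AXIS, 100.0)
            assert np.all(baseline <= spec + 1e-9)
            assert raman.min() >= -1e-9

    def test_scale_equivariance(self):
        spec = sc.synth_background(AXIS, 80.0) + 20.0 * (
            7.5**2 / ((AXIS - 1100.0) ** 2 + 7.5**2)
        )
        b1, r1 = pp.bubblefill(spec, AXIS, 100.0)
        b2, r2 = pp.bubblefill(3.7 * spec, AXIS, 100.0)
        np.testing.assert_allclose(b2, 3.7 * b1, atol=1e-9)
        np.testing.assert_allclose(r2, 3.7 * r1, atol=1e-9)

    def test_degenerate_width_returns_single_bubble(self):
        spec = sc.synth_background(AXIS, 10.0)
        baseline, raman = pp.bubblefill(spec, AXIS, 2000.0)
        assert np.all(baseline <= spec + 1e-9)
        assert np.all(np.isfinite(baseline))

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        spec = rng.normal(10.0, 1.0, AXIS.size)
        b1, r1 = pp.bubblefill(spec, AXIS, 100.0)
        b2, r2 = pp.bubblefill(spec, AXIS, 100.0)
        assert np.array_equal(b1, b2) and np.array_equal(r1, r2)

    def test_baseline_carries_no_band_scale_structure(self):
        """The baseline of pure noise is far smoother than the noise:
        its residual after a bubble-width smoother is tiny."""
        from scipy.signal import savgol_filter

        rng = np.random.default_rng(5)
        spec = rng.normal(0.0, 1.0, AXIS.size)
        baseline, _ = pp.bubblefill(spec, AXIS, 100.0)
        rough = baseline - savgol_filter(baseline, 101, 3)
        assert rough.std() < 0.2 * spec.std()

    def test_min_width_below_spacing_rejected(self):
        with pytest.raises(ValueError):
            pp.bubblefill(np.ones(901), AXIS, 0.5)


class TestSNV:
    def test_three_point_example(self):
        out = pp.snv(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out, [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_output_moments(self):
        rng = np.random.default_rng(1)
        out = pp.snv(rng.normal(5.0, 3.0, 901))
        assert abs(out.mean()) < 1e-12
        assert out.std() == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.0, 2.0, 100)
        np.testing.assert_allclose(pp.snv(pp.snv(x)), pp.snv(x), atol=1e-12)

    @given(
        scale=st.floats(0.1, 100.0),
        offset=st.floats(-100.0, 100.0),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=30, deadline=None)
    def test_affine_invariance(self, scale, offset, seed):
        x = np.random.default_rng(seed).normal(0.0, 1.0, 64)
        np.testing.assert_allclose(pp.snv(scale * x + offset), pp.snv(x), atol=1e-7)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pp.snv(np.full(10, 2.0))


@pytest.fixture(scope="module")
def noiseless_setup(instrument):
    inst = dataclasses.replace(
        instrument,
        background_scale=0.0,
        dark_rate=0.0,
        response_curve=np.ones(instrument.n_pixels),
    )
    bands = tuple(
        sc.BandSpec(c, f, a) for c, (f, a) in sc._BASE_BANDS.items()
    )  # narrow marker bands only
    prof = sc.TissueProfile("cancer_necrosis", "adenocarcinoma", bands, band_cv=0.0)
    cfg = sc.CohortConfig(seed=0, noise_enabled=False)
    meas = sc.simulate_measurement(prof, inst, cfg, "normal")
    calib = pp.CalibrationFit(
        coefficients=inst.true_pixel_to_wavenumber,
        order=2,
        residuals=np.zeros(3),
        rms_residual=0.0,
    )
    return inst, meas, calib


class TestPreprocessMeasurement:

    def test_noiseless_chain_recovers_pure_raman(self, noiseless_setup):
        """With flat response, exact calibration, and no background, the
        chain reproduces the SNV of the generator's pure Raman signal up
        to the wing mass the bubble baseline absorbs (oracle-derived:
        RMS < 0.15, correlation > 0.99)."""
        inst, meas, calib = noiseless_setup
        spec = pp.preprocess_measurement(meas, calib, pp.flat_response(inst.n_pixels))
        truth = np.interp(AXIS, inst.pixel_wavenumbers(), meas.truth["pure_raman"])
        expected = pp.snv(truth)
        rms = np.sqrt(np.mean((spec.snv_intensity - expected) ** 2))
        assert rms < 0.15
        assert np.corrcoef(spec.snv_intensity, expected)[0, 1] > 0.99

    def test_decomposition_reconstructs_resampled_spectrum(self, noiseless_setup):
        inst, meas, calib = noiseless_setup
        spec = pp.preprocess_measurement(meas, calib, pp.flat_response(inst.n_pixels))
        resampled = np.interp(AXIS, inst.pixel_wavenumbers(), meas.truth["pure_raman"])
        np.testing.assert_allclose(spec.baseline + spec.raman_before_snv, resampled, atol=1e-9)

    def test_snv_contract_on_output(self, processed_dataset):
        for spec in processed_dataset[:20]:
            assert abs(spec.snv_intensity.mean()) < 1e-9
            assert spec.snv_intensity.std() == pytest.approx(1.0, abs=1e-9)

    def test_resampling_preserves_band_centers(self, noiseless_setup):
        inst, meas, calib = noiseless_setup
        spec = pp.preprocess_measurement(meas, calib, pp.flat_response(inst.n_pixels))
        step = 1.0
        for center in (852.0, 1449.0, 1657.0):
            window = (AXIS > center - 30) & (AXIS < center + 30)
            peak = AXIS[window][np.argmax(spec.snv_intensity[window])]
            assert abs(peak - center) <= step

    def test_deterministic(self, noiseless_setup):
        inst, meas, calib = noiseless_setup
        s1 = pp.preprocess_measurement(meas, calib, pp.flat_response(inst.n_pixels))
        s2 = pp.preprocess_measurement(meas, calib, pp.flat_response(inst.n_pixels))
        assert np.array_equal(s1.snv_intensity, s2.snv_intensity)

    def test_degraded_measurement_processes_to_finite_output(
        self, instrument, calibration_and_response
    ):
        calib, resp = calibration_and_response
        prof = sc.default_profiles()["normal_lung"]
        cfg = sc.CohortConfig(seed=0)
        meas = sc.simulate_measurement(prof, instrument, cfg, "degraded", np.random.default_rng(4))
        spec = pp.preprocess_measurement(meas, calib, resp)
        assert np.all(np.isfinite(spec.snv_intensity))

    def test_snv_before_baseline_changes_result(self, instrument, calibration_and_response):
        """The chain order matters: swapping SNV ahead of baseline
        removal yields a different (no longer unit-variance) spectrum.
        Because bubblefill is exactly affine-equivariant the two orders
        agree only up to an affine map, which downstream stages (QF,
        feature scaling) do not forgive."""
        calib, resp = calibration_and_response
        prof = sc.default_profiles()["adenocarcinoma"]
        cfg = sc.CohortConfig(seed=0)
        meas = sc.simulate_measurement(prof, instrument, cfg, "normal", np.random.default_rng(8))
        standard = pp.preprocess_measurement(meas, calib, resp)
        swapped = pp.preprocess_measurement(
            meas, calib, resp, pp.PreprocessParams(snv_before_baseline=True)
        )
        assert not np.allclose(standard.snv_intensity, swapped.snv_intensity, atol=1e-3)
        assert abs(swapped.snv_intensity.std() - 1.0) > 0.01
        # ... but the affine equivalence itself holds exactly:
        np.testing.assert_allclose(
            pp.snv(swapped.snv_intensity), standard.snv_intensity, atol=1e-9
        )

    def test_stage_errors_carry_stage_name(self, noiseless_setup):
        inst, meas, calib = noiseless_setup
        bad = dataclasses.replace(meas, dark_frame=np.zeros(3))
        with pytest.raises(pp.PipelineStageError, match="subtract_dark"):
            pp.preprocess_measurement(bad, calib, pp.flat_response(inst.n_pixels))
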