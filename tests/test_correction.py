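"""Ratio computation, polynomial correction fitting and application."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epidqa import (
    MODE_CONSTANTS,
    PolyCorrection,
    ProfileCurve,
    RatioCurve,
    apply_profile_correction,
    compute_ratio,
    correction_factor,
    derive_correction_mode,
    fit_correction,
    load_correction,
    save_correction,
)
from epidqa.errors import CorrectionValidityError, FitError, RangeError
from epidqa.simulate import synthetic_ratio_curve


def _profile(r, v):
    return ProfileCurve(np.asarray(r, float), np.asarray(v, float))


R = np.linspace(0.0, 23.0, 231)


class TestComputeRatio:
    def test_identical_profiles_give_unity(self):
        p = _profile(R, 1.0 + 0.002 * R**2)
        ratio = compute_ratio(p, p)
        assert np.allclose(ratio.ratio, 1.0, atol=1e-15)

    def test_global_scale_absorbed_by_cax_normalization(self):
        pred = _profile(R, 1.0 + 0.001 * R**2)
        meas = _profile(R, 1.05 * pred.value)
        assert np.allclose(compute_ratio(meas, pred).ratio, 1.0, atol=1e-12)

    def test_quadratic_overresponse_recovered(self):
        pred = _profile(R, np.exp(-0.001 * R**2) + 0.5)
        meas = _profile(R, pred.value * (1.0 + 0.002 * R**2))
        ratio = compute_ratio(meas, pred)
        assert np.allclose(ratio.ratio, 1.0 + 0.002 * ratio.r_cm**2, rtol=1e-12)

    def test_orientation_flip_inverts(self):
        pred = _profile(R, 1.0 + 0.001 * R)
        meas = _profile(R, pred.value * (1.0 + 0.001 * R**2))
        fwd = compute_ratio(meas, pred)
        rev = compute_ratio(meas, pred, orientation="predicted_over_measured")
        assert np.allclose(fwd.ratio * rev.ratio, 1.0, atol=1e-12)

    def test_disjoint_ranges_rejected(self):
        a = _profile([0.0, 2.0, 4.0], [1.0, 1.0, 1.0])
        b = _profile([5.0, 7.0, 9.0], [1.0, 1.0, 1.0])
        with pytest.raises(RangeError):
            compute_ratio(a, b)


class TestFitCorrection:
    def test_unity_ratio_fits_to_zero_polynomial(self):
        ratio = RatioCurve(R, np.ones_like(R))
        corr = fit_correction(ratio, 4, 0.0, 22.0, 22.0)
        assert corr.coefficients == (0.0,) * 5
        assert corr.r_squared == 1.0
        assert correction_factor(corr, 10.0) == 0.0

    def test_exact_quartic_recovered(self):
        coeffs = np.array([0.0, -2e-3, 1e-4, -3e-6, 6e-7])
        ratio_vals = 1.0 + np.polynomial.polynomial.polyval(R, coeffs)
        corr = fit_correction(RatioCurve(R, ratio_vals / ratio_vals[0]), 4, 0.0, 23.0, 23.0)
        assert np.allclose(corr.coefficients, coeffs, atol=1e-9)
        assert corr.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_quartic_keeps_high_r_squared(self):
        # 0.1% multiplicative noise at pixel-pitch sampling over 0-22 cm
        ratio = synthetic_ratio_curve(seed=7)
        corr = fit_correction(ratio, 4, 0.0, 22.0, 22.0)
        assert corr.r_squared >= 0.999

    def test_too_few_samples(self):
        ratio = RatioCurve(np.array([0.0, 1.0, 2.0]), np.ones(3))
        with pytest.raises(FitError):
            fit_correction(ratio, 4, 0.0, 2.0, 5.0)


class TestCorrectionFactor:
    def test_zero_beyond_application_radius(self):
        corr = PolyCorrection((0.01, 0.002, 0.0, 0.0, 1e-6), 4, 0.0, 11.0, 14.0, 0.99)
        rng = np.random.default_rng(11)
        r = 14.0 + rng.uniform(1e-6, 26.0, 1000)
        assert np.all(correction_factor(corr, r) == 0.0)
        assert correction_factor(corr, 14.01) == 0.0

    @given(st.floats(min_value=14.0, max_value=100.0, exclude_min=True))
    @settings(max_examples=50, derandomize=True)
    def test_zero_beyond_cutoff_property(self, r):
        corr = PolyCorrection((0.05, -0.001, 2e-4, 0.0, 0.0), 4, 0.0, 11.0, 14.0, 1.0)
        assert correction_factor(corr, r) == 0.0

    def test_inside_window_is_polynomial(self):
        corr = PolyCorrection((0.01, 0.002), 1, 0.0, 10.0, 12.0, 1.0)
        assert correction_factor(corr, 5.0) == pytest.approx(0.02)

    def test_negative_r_rejected(self):
        corr = PolyCorrection((0.0, 0.0), 1, 0.0, 10.0, 12.0, 1.0)
        with pytest.raises(ValueError):
            correction_factor(corr, -1.0)

    def test_taper_ramps_to_zero_at_cutoff(self):
        corr = PolyCorrection((0.1,), 0, 0.0, 10.0, 14.0, 1.0, taper_band_cm=1.0)
        assert correction_factor(corr, 12.9) == pytest.approx(0.1)
        assert correction_factor(corr, 13.5) == pytest.approx(0.05)
        assert correction_factor(corr, 14.0) == pytest.approx(0.0, abs=1e-15)
        assert correction_factor(corr, 14.5) == 0.0


class TestApplyProfileCorrection:
    def test_zero_correction_is_identity(self):
        profile = _profile(R, 1.0 + 0.001 * R**2)
        corr = PolyCorrection((0.0,) * 5, 4, 0.0, 22.0, 22.0, 1.0)
        out = apply_profile_correction(profile, corr)
        assert np.allclose(out.value, profile.value, atol=1e-12)

    def test_constant_correction_hand_case(self):
        # three-point profile, constant +9.9% inside a 7 cm window
        profile = _profile([0.0, 5.0, 10.0], [1.0, 1.02, 1.05])
        corr = PolyCorrection((0.099,), 0, 0.0, 7.0, 7.0, 1.0)
        out = apply_profile_correction(profile, corr)
        # inside: divided by 1.099; outside untouched; then CAX renormalized
        expected = np.array([1.0 / 1.099, 1.02 / 1.099, 1.05])
        expected /= expected[0]
        assert np.allclose(out.value, expected, atol=1e-12)

    def test_invalid_correction_rejected(self):
        profile = _profile([0.0, 5.0], [1.0, 1.0])
        corr = PolyCorrection((-1.0,), 0, 0.0, 7.0, 7.0, 1.0)
        with pytest.raises(CorrectionValidityError):
            apply_profile_correction(profile, corr)


class TestDeriveCorrectionMode:
    def test_mode_constants_reach_the_field_limits(self):
        assert MODE_CONSTANTS["inhouse_20x20"]["r_apply_max_cm"] == 14.0
        assert MODE_CONSTANTS["inhouse_20x20"]["r_fit_max_cm"] == 11.0
        assert MODE_CONSTANTS["inhouse_large"]["r_fit_max_cm"] == 22.0
        assert MODE_CONSTANTS["bailey"]["order"] == 1
        assert (
            MODE_CONSTANTS["bailey"]["r_fit_min_cm"],
            MODE_CONSTANTS["bailey"]["r_fit_max_cm"],
        ) == (10.0, 25.0)

    @pytest.mark.parametrize("mode", sorted(MODE_CONSTANTS))
    def test_identical_profiles_give_zero_correction(self, mode):
        r = np.linspace(0.0, 25.0, 501)
        p = _profile(r, 1.0 + 0.002 * r**2 - 2e-5 * r**3)
        corr = derive_correction_mode(mode, p, p)
        probe = np.linspace(0.0, 30.0, 200)
        assert np.allclose(correction_factor(corr, probe), 0.0, atol=1e-9)
        out = apply_profile_correction(p, corr)
        assert np.allclose(out.value, p.value, atol=1e-9)

    def test_20x20_mode_applies_to_14cm(self):
        r = np.linspace(0.0, 15.0, 151)
        pred = _profile(r, 1.0 + 1e-3 * r)
        meas = _profile(r, pred.value * (1.0 + 1e-4 * r**2))
        corr = derive_correction_mode("inhouse_20x20", meas, pred)
        assert corr.r_apply_max_cm == 14.0
        assert correction_factor(corr, 14.5) == 0.0
        # inside the fit window the injected quadratic is recovered
        assert correction_factor(corr, 8.0) == pytest.approx(1e-4 * 64, abs=1e-6)


def test_correction_json_round_trip(tmp_path):
    ratio = synthetic_ratio_curve(seed=3)
    corr = fit_correction(ratio, 4, 0.0, 22.0, 22.0, mode="inhouse_large")
    path = tmp_path / "corr.json"
    save_correction(corr, path)
    loaded = load_correction(path)
    assert loaded == corr
    r = np.linspace(0, 25, 100)
    assert np.array_equal(correction_factor(loaded, r), correction_factor(corr, r))


def test_parameter_recovery_on_reduced_panel(controlled_config):
    """Injected radial over-response is recovered by the derivation chain."""
    from epidqa.experiment import build_scenario_calibration, LARGE_FIELD_DIAGONAL_DEG
    from epidqa import (
        extract_diagonal_profile,
        make_field_fluence,
        process_portal_image,
        simulate_predicted,
        simulate_raw,
    )

    cfg = controlled_config
    cal, corr = build_scenario_calibration(cfg, "inhouse_40x30")
    assert corr is not None
    r = np.linspace(0.0, 22.0, 221)
    injected = cfg.overresponse_values(r) - 1.0
    recovered = correction_factor(corr, r)
    assert np.max(np.abs(recovered - injected)) < 1e-3  # 0.1 percentage points

    # closed loop: with the corrected profile the open-field diagonal ratio
    # returns to unity inside the fit window (minus the one-pixel cutoff ring)
    fluence = make_field_fluence(cfg, 19.0, 19.0, 14.0, 14.0)
    measured = process_portal_image(simulate_raw(fluence, cfg, noise_stream=5), cal)
    predicted = simulate_predicted(fluence, cfg)
    n = int(round(23.0 / cfg.pitch_mm * 10)) + 1
    pm = extract_diagonal_profile(measured, n, 23.0, angle_deg=LARGE_FIELD_DIAGONAL_DEG)
    pp = extract_diagonal_profile(predicted, n, 23.0, angle_deg=LARGE_FIELD_DIAGONAL_DEG)
    ratio = compute_ratio(pm, pp)
    inside = ratio.r_cm <= 22.0 - cfg.pitch_mm / 10.0
    assert np.max(np.abs(ratio.ratio[inside] - 1.0)) < 0.005
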