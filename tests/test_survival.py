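"""Weibull curve evaluation, calibration and per-cycle probabilities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mhspc_cea import (
    CalibrationError,
    DigitizedSeries,
    InsufficientDataError,
    ValidationError,
    WeibullCurve,
    apply_hazard_ratio,
    calibrate_from_landmark,
    cycle_transition_probabilities,
    cycle_transition_probability,
    fit_to_points,
    survival_at,
)

shapes = st.floats(0.2, 5.0)
times = st.floats(0.5, 240.0)
fractions = st.floats(0.001, 0.999)


class TestSurvivalAt:
    def test_is_one_at_time_zero(self):
        assert survival_at(WeibullCurve(shape=2.3, scale=7.7), 0.0) == 1.0

    def test_exponential_closed_form(self):
        curve = WeibullCurve(shape=1.0, scale=109.58)
        assert survival_at(curve, 36.0) == pytest.approx(math.exp(-36 / 109.58))
        assert survival_at(curve, 36.0) == pytest.approx(0.720, abs=5e-4)

    def test_survival_at_scale_is_e_inverse(self):
        curve = WeibullCurve(shape=1.0, scale=109.58)
        assert survival_at(curve, 109.58) == pytest.approx(math.exp(-1), rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            survival_at(WeibullCurve(shape=1.0, scale=10.0), -1.0)

    def test_vectorized_and_strictly_decreasing(self):
        curve = WeibullCurve(shape=1.4, scale=50.0)
        t = np.linspace(0, 240, 241)
        s = curve.survival(t)
        assert s[0] == 1.0
        assert np.all(np.diff(s) < 0)
        assert np.all((s > 0) & (s <= 1))

    @pytest.mark.parametrize("shape,scale", [(0.0, 10.0), (-1.0, 10.0), (1.0, 0.0)])
    def test_invalid_parameters_rejected(self, shape, scale):
        with pytest.raises(ValidationError):
            WeibullCurve(shape=shape, scale=scale)


class TestCalibrateFromLandmark:
    def test_exponential_scale_closed_form(self):
        curve = calibrate_from_landmark(0.72, 36.0, 1.0)
        assert curve.scale == pytest.approx(36.0 / -math.log(0.72))
        assert curve.scale == pytest.approx(109.58, abs=0.01)

    def test_e_inverse_landmark_gives_scale_equal_to_time(self):
        curve = calibrate_from_landmark(math.exp(-1), 36.0, 1.0)
        assert curve.scale == pytest.approx(36.0, rel=1e-12)

    def test_round_trip_with_non_unit_shape(self):
        curve = calibrate_from_landmark(0.41, 36.0, 1.2)
        assert survival_at(curve, 36.0) == pytest.approx(0.41, abs=1e-12)

    @pytest.mark.parametrize("bad_s", [0.0, 1.0, -0.2, 1.3])
    def test_degenerate_landmark_rejected(self, bad_s):
        with pytest.raises(CalibrationError):
            calibrate_from_landmark(bad_s, 36.0, 1.0)

    def test_nonpositive_time_or_shape_rejected(self):
        with pytest.raises(ValidationError):
            calibrate_from_landmark(0.5, 0.0, 1.0)
        with pytest.raises(ValidationError):
            calibrate_from_landmark(0.5, 36.0, -1.0)

    @settings(deadline=None)
    @given(s=fractions, t=times, k=shapes)
    def test_round_trip_property(self, s, t, k):
        curve = calibrate_from_landmark(s, t, k)
        assert survival_at(curve, t) == pytest.approx(s, abs=1e-12)


class TestApplyHazardRatio:
    def test_reproduces_printed_treatment_landmark(self):
        soc = calibrate_from_landmark(0.72, 36.0, 1.0)
        enza = apply_hazard_ratio(soc, 0.67, arm_label="enzalutamide")
        assert survival_at(enza, 36.0) == pytest.approx(0.72**0.67, rel=1e-10)
        # arithmetic consistency with the published 80% landmark
        assert survival_at(enza, 36.0) == pytest.approx(0.80, abs=0.005)

    def test_unit_hazard_ratio_is_identity(self):
        soc = calibrate_from_landmark(0.41, 36.0, 1.3)
        same = apply_hazard_ratio(soc, 1.0)
        assert same.scale == pytest.approx(soc.scale, rel=1e-14)
        assert same.shape == soc.shape

    def test_nonpositive_hr_rejected(self):
        soc = calibrate_from_landmark(0.5, 36.0, 1.0)
        with pytest.raises(ValidationError):
            apply_hazard_ratio(soc, 0.0)

    @settings(deadline=None)
    @given(s=fractions, k=shapes, hr=st.floats(0.1, 3.0), t=times)
    def test_pointwise_power_relation(self, s, k, hr, t):
        ref = calibrate_from_landmark(s, 36.0, k)
        trt = apply_hazard_ratio(ref, hr)
        assert trt.shape == ref.shape
        assert survival_at(trt, t) == pytest.approx(
            survival_at(ref, t) ** hr, abs=1e-10
        )

    @settings(deadline=None)
    @given(a=st.floats(0.2, 3.0), b=st.floats(0.2, 3.0), t=times)
    def test_proportional_hazards_closure(self, a, b, t):
        ref = calibrate_from_landmark(0.6, 36.0, 1.4)
        two_step = apply_hazard_ratio(apply_hazard_ratio(ref, a), b)
        one_step = apply_hazard_ratio(ref, a * b)
        assert survival_at(two_step, t) == pytest.approx(
            survival_at(one_step, t), abs=1e-10
        )


class TestFitToPoints:
    def test_noiseless_points_recover_parameters(self):
        truth = WeibullCurve(shape=1.3, scale=60.0)
        t = np.arange(6.0, 61.0, 6.0)
        series = DigitizedSeries(times=t, survival=truth.survival(t))
        fitted = fit_to_points(series)
        assert fitted.shape == pytest.approx(1.3, abs=1e-6)
        assert fitted.scale == pytest.approx(60.0, abs=1e-6)
        assert fitted.fit_r_squared == pytest.approx(1.0, abs=1e-12)

    def test_too_few_usable_points_rejected(self):
        series = DigitizedSeries(times=[6.0, 12.0], survival=[0.9, 0.8])
        with pytest.raises(InsufficientDataError):
            fit_to_points(series)

    def test_saturated_points_are_excluded_from_fit(self):
        truth = WeibullCurve(shape=1.1, scale=40.0)
        t = np.array([0.0, 6.0, 12.0, 24.0, 36.0])
        s = np.concatenate([[1.0], truth.survival(t[1:])])
        fitted = fit_to_points(DigitizedSeries(times=t, survival=s))
        assert fitted.scale == pytest.approx(40.0, abs=1e-6)

    def test_non_monotone_series_rejected_on_construction(self):
        with pytest.raises(ValidationError):
            DigitizedSeries(times=[1.0, 2.0, 3.0], survival=[0.9, 0.95, 0.8])


class TestCycleTransitionProbability:
    def test_exponential_is_memoryless(self):
        curve = WeibullCurve(shape=1.0, scale=80.0)
        p = [cycle_transition_probability(curve, i, 1.0) for i in (0, 1, 50, 239)]
        assert all(pi == pytest.approx(p[0], rel=1e-12) for pi in p)

    def test_exponential_monthly_value(self):
        curve = WeibullCurve(shape=1.0, scale=109.58)
        p = cycle_transition_probability(curve, 0, 1.0)
        assert p == pytest.approx(1 - math.exp(-1 / 109.58), rel=1e-12)
        assert p == pytest.approx(0.00908, abs=5e-5)

    def test_increasing_hazard_gives_increasing_probability(self):
        curve = WeibullCurve(shape=1.6, scale=90.0)
        p = cycle_transition_probabilities(curve, 240, 1.0)
        assert np.all(np.diff(p) > 0)
        assert np.all((p >= 0) & (p < 1))

    @settings(deadline=None)
    @given(k=shapes, lam=st.floats(5.0, 300.0))
    def test_survival_product_identity(self, k, lam):
        curve = WeibullCurve(shape=k, scale=lam)
        p = cycle_transition_probabilities(curve, 120, 1.0)
        assert float(np.prod(1.0 - p)) == pytest.approx(
            survival_at(curve, 120.0), abs=1e-10
        )

    def test_preconditions(self):
        curve = WeibullCurve(shape=1.0, scale=10.0)
        with pytest.raises(ValidationError):
            cycle_transition_probability(curve, -1, 1.0)
        with pytest.raises(ValidationError):
            cycle_transition_probability(curve, 0, 0.0)


class TestSerialization:
    def test_curve_json_round_trip(self, tmp_path):
        curve = calibrate_from_landmark(
            0.72, 36.0, 1.0, endpoint_label="OS", arm_label="standard_care"
        )
        path = tmp_path / "curve.json"
        curve.to_json(path)
        assert WeibullCurve.from_json(path) == curve

    def test_series_csv_round_trip(self, tmp_path):
        series = DigitizedSeries(
            times=[6.0, 12.0, 18.0], survival=[0.9, 0.8, 0.7],
            endpoint_label="clinical_PFS", arm_label="enzalutamide",
        )
        path = tmp_path / "series.csv"
        series.to_csv(path)
        loaded = DigitizedSeries.from_csv(
            path, endpoint_label="clinical_PFS", arm_label="enzalutamide"
        )
        np.testing.assert_allclose(loaded.times, series.times)
        np.testing.assert_allclose(loaded.survival, series.survival)
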