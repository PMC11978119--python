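import numpy as np
import pytest
from scipy.special import expit

from lifexpect import (check_estimability, fit_rcs_one_step, life_expectancy,
                       logit_relative_survival, rolling_extrapolate)
from lifexpect.errors import InsufficientFollowupError, ValidationError
from lifexpect.extrapolate import ExtrapolationConfig, rcs_basis


def geometric_curve(p, horizon):
    s = p ** np.arange(horizon + 1)
    s[-1] = 0.0
    return s


class TestLogitRelativeSurvival:
    def test_ratio_half_maps_to_zero(self):
        s_r = np.ones(30)
        s_p = np.concatenate([[1.0], np.full(29, 0.5)])
        series = logit_relative_survival(s_p, s_r)
        assert np.allclose(series.w_valid, 0.0)

    def test_ratio_one_is_masked_not_infinite(self):
        s_r = geometric_curve(0.99, 40)
        s_p = s_r.copy()
        s_p[1:20] = s_r[1:20]              # ratio exactly 1 -> masked
        s_p[20:] = 0.5 * s_r[20:]
        series = logit_relative_survival(s_p, s_r)
        assert not series.valid[:19].any()
        assert np.isfinite(series.w_valid).all()

    def test_constant_offset_recovers_w0(self):
        w0 = -1.0
        s_r = geometric_curve(0.995, 60)
        s_p = np.concatenate([[1.0], expit(w0) * s_r[1:]])
        series = logit_relative_survival(s_p, s_r)
        assert np.allclose(series.w_valid, w0, atol=1e-10)

    def test_too_few_valid_months_rejected(self):
        s_r = np.ones(8)
        s_p = np.concatenate([[1.0], np.full(7, 0.5)])
        with pytest.raises(InsufficientFollowupError):
            logit_relative_survival(s_p, s_r)


class TestRcsOneStep:
    def test_affine_series_continues_exactly(self):
        t = np.arange(30.0)
        w = 2.0 - 0.05 * t
        pred = fit_rcs_one_step(t, w)
        assert pred == pytest.approx(2.0 - 0.05 * 30, abs=1e-8)

    def test_constant_series_predicts_constant(self):
        t = np.arange(24.0)
        assert fit_rcs_one_step(t, np.full(24, -0.7)) == pytest.approx(-0.7, abs=1e-8)

    def test_smooth_curve_one_step_error_below_noise(self):
        rng = np.random.default_rng(0)
        t = np.arange(48.0)
        sigma = 0.02
        truth = np.sin(t / 40) - 0.01 * t
        pred = fit_rcs_one_step(t, truth + rng.normal(0, sigma, t.size))
        truth_next = np.sin(48 / 40) - 0.01 * 48
        assert abs(pred - truth_next) < 3 * sigma

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValidationError):
            fit_rcs_one_step(np.full(20, 5.0), np.zeros(20))

    def test_basis_is_linear_beyond_boundary_knots(self):
        knots = np.array([2.0, 5.0, 8.0, 11.0])
        x = np.array([12.0, 13.0, 14.0])
        b = rcs_basis(x, knots)
        # beyond the last knot every column must be affine in x
        for col in b.T:
            assert np.diff(col, 2) == pytest.approx(0.0, abs=1e-9)


class TestEstimability:
    def test_identical_curves_refused(self):
        s = geometric_curve(0.99, 120)
        assert not check_estimability(s, s).estimable

    def test_uniformly_worse_curve_estimable(self):
        s_r = geometric_curve(0.99, 120)
        assert check_estimability(s_r ** 3, s_r).estimable

    def test_noise_margin_tightens_threshold(self):
        s_r = geometric_curve(0.99, 120)
        s_p = 0.97 * s_r  # 3% worse: inside the material margin
        s_p[0] = 1.0
        assert check_estimability(s_p, s_r).estimable
        assert not check_estimability(s_p, s_r, auc_ratio_se=0.05).estimable


class TestRollingExtrapolation:
    def test_constant_w_closed_form(self):
        """A constant logit offset must extrapolate as expit(w0) * S_r, and
        for exponential referent survival the LE follows the geometric sum."""
        w0, p = -1.0, 0.99
        horizon = 1400
        s_r = geometric_curve(p, horizon)
        t_obs = 120
        s_p_obs = np.concatenate([[1.0], expit(w0) * s_r[1: t_obs + 1]])
        res = rolling_extrapolate(s_p_obs, s_r, horizon_months=horizon, check=False)
        assert np.allclose(res.s_patient[t_obs + 1:], expit(w0) * s_r[t_obs + 1: len(res.s_patient)],
                           atol=1e-6)
        le_closed = expit(w0) * (0.5 + p / (1 - p)) / 12 + (1 - expit(w0)) * 0.5 / 12
        assert res.le == pytest.approx(le_closed, rel=0.005)

    def test_referent_exhaustion_forces_zero(self):
        s_r = geometric_curve(0.9, 120)   # reaches 0 by month 120
        s_p_obs = np.concatenate([[1.0], 0.6 * s_r[1:41]])
        res = rolling_extrapolate(s_p_obs, s_r, horizon_months=600, check=False)
        assert res.s_patient[-1] <= 1e-4

    def test_output_non_increasing_over_random_cohorts(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            p = rng.uniform(0.99, 0.999)
            w0 = rng.uniform(-2, -0.2)
            drift = rng.uniform(0, 0.01)
            s_r = geometric_curve(p, 800)
            t = np.arange(1, 101)
            w = w0 - drift * t + rng.normal(0, 0.03, 100)
            s_p_obs = np.concatenate([[1.0], expit(w) * s_r[1:101]])
            s_p_obs = np.minimum.accumulate(s_p_obs)
            res = rolling_extrapolate(s_p_obs, s_r, horizon_months=800, check=False)
            assert np.all(np.diff(res.s_patient) <= 1e-12)

    def test_loss_plus_le_is_referent_le(self):
        s_r = geometric_curve(0.995, 900)
        s_p_obs = np.concatenate([[1.0], expit(-0.5) * s_r[1:121]])
        res = rolling_extrapolate(s_p_obs, s_r, horizon_months=900, check=False)
        assert res.le + res.loss_le == pytest.approx(res.le_referent, abs=1e-12)

    def test_horizon_cap_flags_truncation(self):
        s_r = geometric_curve(0.9995, 400)
        s_p_obs = np.concatenate([[1.0], expit(-0.2) * s_r[1:121]])
        res = rolling_extrapolate(s_p_obs, s_r, horizon_months=150, check=False)
        assert res.truncated


class TestLifeExpectancy:
    def test_rectangle_curve(self):
        s = np.concatenate([np.ones(121), [0.0]])
        assert life_expectancy(s) == pytest.approx(10.0, abs=0.5 / 12)

    def test_exponential_closed_form(self):
        p = 0.99
        s = geometric_curve(p, 3000)
        closed = (0.5 + p / (1 - p)) / 12
        assert life_expectancy(s) == pytest.approx(closed, rel=0.005)

    def test_loss_is_area_between_curves(self):
        s_r = geometric_curve(0.995, 600)
        s_p = 0.7 * s_r
        s_p[0] = 1.0
        gap = life_expectancy(s_r) - life_expectancy(s_p)
        assert gap == pytest.approx(np.trapezoid(s_r - s_p) / 12, abs=1e-12)
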