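"""Centile models: pinball loss, exact-LP quantile regressions, LMS model."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit, logit
from scipy.stats import kstest, spearmanr

from immunoclock import (
    DEFAULT_TAUS,
    GeneratorParams,
    LMSCentileModel,
    fit_lms,
    fit_lqr,
    fit_nqr,
    generate_cohort,
    individual_centile,
    pinball_loss,
    true_quantile,
)
from immunoclock.centiles import ConvergenceError, UnsupportedOperationError


class TestPinballLoss:
    def test_zero_iff_exact(self):
        y = np.array([0.1, 0.5, 0.9])
        assert pinball_loss(y, y, 0.3) == 0.0
        assert pinball_loss(y, y + 0.01, 0.3) > 0.0

    def test_hand_computed_values(self):
        assert pinball_loss([0.0, 1.0], [0.5, 0.5], 0.5) == pytest.approx(0.25)
        assert pinball_loss([1.0], [0.0], 0.9) == pytest.approx(0.9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pinball_loss([1.0, 2.0], [1.0], 0.5)


def _lqr_oracle_loss(age, y, tau):
    """Minimum pinball loss over all lines through two data points with
    distinct ages (an optimal quantile-regression line is such a basic
    solution)."""
    best = np.inf
    for i, j in itertools.combinations(range(len(age)), 2):
        if age[i] == age[j]:
            continue
        slope = (y[j] - y[i]) / (age[j] - age[i])
        intercept = y[i] - slope * age[i]
        best = min(best, pinball_loss(y, intercept + slope * age, tau))
    return best


class TestLinearQuantileRegression:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(st.floats(18, 100, allow_nan=False),
                  st.floats(0, 1, allow_nan=False)),
        min_size=3, max_size=7,
    ), st.sampled_from([0.15, 0.5, 0.85]))
    def test_matches_basic_solution_oracle_on_tiny_data(self, points, tau):
        age = np.array([p[0] for p in points])
        y = np.array([p[1] for p in points])
        if np.ptp(age) < 1e-6:
            return
        model = fit_lqr(age, y, taus=(tau,))
        b0, b1 = model.coef_[tau]
        fitted_loss = pinball_loss(y, b0 + b1 * age, tau)
        assert fitted_loss <= _lqr_oracle_loss(age, y, tau) + 1e-9

    def test_intercept_only_median(self):
        y = np.array([0.1, 0.2, 0.3, 0.6, 0.9])
        model = fit_lqr(np.full(5, 50.0), y, taus=(0.5,), intercept_only=True)
        assert model.coef_[0.5][0] == pytest.approx(np.median(y), abs=1e-9)

    def test_constant_ages_rejected_without_intercept_only(self):
        with pytest.raises(ValueError, match="intercept_only"):
            fit_lqr(np.full(10, 40.0), np.linspace(0.1, 0.9, 10))

    def test_subgradient_coverage_condition(self, cohort1600):
        age = cohort1600["age_years"].to_numpy()
        y = cohort1600["immax"].to_numpy()
        model = fit_lqr(age, y)
        n = len(y)
        for tau, (b0, b1) in model.coef_.items():
            fitted = b0 + b1 * age
            strictly_below = np.mean(y < fitted)
            weakly_below = np.mean(y <= fitted)
            assert strictly_below <= tau + 2.0 / n
            assert weakly_below >= tau - 2.0 / n

    def test_median_request_returns_exact_line(self, fitted_models):
        model = fitted_models["LQR"]
        ages = np.array([25.0, 60.0, 95.0])
        q = model.predict_quantiles(ages, (0.5,))
        b0, b1 = model.coef_[0.5]
        np.testing.assert_allclose(q[:, 0], b0 + b1 * ages, atol=1e-12)


class TestSplineQuantileRegression:
    def test_large_penalty_collapses_to_straight_line(self, default_params):
        cohort = generate_cohort(300, default_params, seed=13)
        age = cohort["age_years"].to_numpy()
        y = cohort["immax"].to_numpy()
        nqr = fit_nqr(age, y, taus=(0.5,), penalty=1e7)
        lqr = fit_lqr(age, y, taus=(0.5,))
        grid = np.linspace(age.min(), age.max(), 50)
        np.testing.assert_allclose(nqr.predict_quantiles(grid, (0.5,)),
                                   lqr.predict_quantiles(grid, (0.5,)), atol=2e-3)

    def test_recovers_linear_median(self, ws_params):
        cohort = generate_cohort(1000, ws_params, seed=14)
        age = cohort["age_years"].to_numpy()
        model = fit_nqr(age, cohort["immax"].to_numpy(), taus=(0.5,))
        grid = np.linspace(age.min() + 1, age.max() - 1, 40)
        truth = true_quantile(np.full(40, 0.5), grid, ws_params)
        fitted = model.predict_quantiles(grid, (0.5,))[:, 0]
        assert np.max(np.abs(fitted - truth)) < 0.02

    def test_no_extrapolation(self, fitted_models):
        with pytest.raises(ValueError, match="extrapolate"):
            fitted_models["NQR"].predict_quantiles(np.array([101.0]))

    def test_roughness_never_increases_with_penalty(self, default_params):
        cohort = generate_cohort(400, default_params, seed=15)
        age = cohort["age_years"].to_numpy()
        y = cohort["immax"].to_numpy()
        grid = np.linspace(age.min(), age.max(), 100)
        roughness = []
        for penalty in (0.01, 1.0, 100.0, 1e4):
            m = fit_nqr(age, y, taus=(0.5,), penalty=penalty)
            curve = m.predict_quantiles(grid, (0.5,))[:, 0]
            roughness.append(np.sum(np.diff(curve, 2) ** 2))
        assert all(b <= a + 1e-12 for a, b in zip(roughness, roughness[1:]))


class TestLMSModel:
    def test_homogeneous_data_gives_flat_curves(self):
        # no age effect: Gaussian on the logit scale; the fitted percentile
        # curves must be flat and match the marginal sample quantiles
        rng = np.random.default_rng(16)
        age = rng.uniform(18, 100, 800)
        y = expit(rng.normal(-0.3, 0.4, 800))
        model = fit_lms(age, y)
        q = model.predict_quantiles(np.array([25.0, 55.0, 90.0]), (0.5,))
        assert np.ptp(q) < 0.02
        assert q[0, 0] == pytest.approx(np.median(y), abs=0.03)

    def test_recovers_true_median_curve(self, ws_lms, ws_params):
        grid = np.linspace(20, 95, 40)
        fitted = ws_lms.predict_quantiles(grid, (0.5,))[:, 0]
        truth = true_quantile(np.full(40, 0.5), grid, ws_params)
        assert np.max(np.abs(fitted - truth)) < 0.03

    def test_pit_uniformity_on_well_specified_data(self, ws_lms, ws_cohort1600):
        pit = ws_lms.centile(ws_cohort1600["age_years"].to_numpy(),
                             ws_cohort1600["immax"].to_numpy())
        assert 0.48 <= pit.mean() <= 0.52
        assert kstest(pit, "uniform").pvalue > 0.01

    def test_centiles_uncorrelated_with_age(self, ws_lms, ws_cohort1600):
        pit = ws_lms.centile(ws_cohort1600["age_years"].to_numpy(),
                             ws_cohort1600["immax"].to_numpy())
        rho = spearmanr(pit, ws_cohort1600["age_years"]).statistic
        assert abs(rho) < 0.05

    def test_centile_of_fitted_median_is_half(self, ws_lms):
        for age in (25.0, 50.0, 80.0):
            p50 = ws_lms.predict_quantiles(np.array([age]), (0.5,))[0, 0]
            assert ws_lms.centile(age, p50) == pytest.approx(0.5, abs=1e-6)

    def test_centile_limits_and_monotonicity(self, ws_lms):
        assert ws_lms.centile(50.0, 1e-5) < 1e-6
        # probe inside the conditional distribution's effective support
        # (far outside it the CDF saturates at double precision)
        band = ws_lms.predict_quantiles(np.array([60.0]))[0]
        ys = np.linspace(band[0], band[-1], 25)
        cents = ws_lms.centile(np.full(25, 60.0), ys)
        assert np.all(np.diff(cents) > 0)

    def test_band_widens_with_age_when_spread_increases(self, ws_lms):
        q25 = ws_lms.predict_quantiles(np.array([25.0]))[0]
        q70 = ws_lms.predict_quantiles(np.array([70.0]))[0]
        assert (q70[-1] - q70[0]) > (q25[-1] - q25[0])

    def test_response_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            fit_lms(np.linspace(18, 100, 30), np.linspace(-0.1, 0.9, 30))

    def test_nonconvergence_raises_with_trace(self, ws_cohort1600):
        with pytest.raises(ConvergenceError) as err:
            LMSCentileModel(max_iter=0).fit(
                ws_cohort1600["age_years"].to_numpy()[:200],
                ws_cohort1600["immax"].to_numpy()[:200])
        assert len(err.value.trace) >= 1

    def test_individual_centile_unsupported_for_quantile_models(self, fitted_models):
        with pytest.raises(UnsupportedOperationError):
            individual_centile(fitted_models["LQR"], 50.0, 0.4)
        assert 0.0 < individual_centile(fitted_models["LMS"], 50.0, 0.4) < 1.0


class TestSharedContracts:
    @pytest.mark.parametrize("name", ["LMS", "LQR", "NQR"])
    def test_curves_never_cross_on_dense_grid(self, fitted_models, name):
        model = fitted_models[name]
        lo, hi = model.age_range_
        grid = np.linspace(lo, hi, 200)
        Q = model.predict_quantiles(grid)
        assert np.all(np.diff(Q, axis=1) >= 0)
        assert np.all((Q >= 0) & (Q <= 1))

    @pytest.mark.parametrize("name", ["LMS", "LQR", "NQR"])
    def test_training_coverage_within_binomial_tolerance(self, fitted_models, name):
        n = 1600
        for tau, frac in fitted_models[name].coverage_.items():
            tol = 2.0 * np.sqrt(tau * (1 - tau) / n)
            assert abs(frac - tau) <= tol + 2.0 / n, (name, tau, frac)

    def test_rearrangement_sorts_crossing_curves(self):
        # a tiny, noisy fit can produce crossing raw lines; the prediction
        # contract sorts them at every age
        rng = np.random.default_rng(17)
        age = rng.uniform(18, 100, 12)
        y = rng.uniform(0, 1, 12)
        model = fit_lqr(age, y, taus=(0.25, 0.5, 0.75))
        Q = model.predict_quantiles(np.linspace(0, 130, 60))
        assert np.all(np.diff(Q, axis=1) >= 0)
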