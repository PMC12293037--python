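"""Observed curves: analytic/Monte-Carlo agreement, shape labels, curve fits."""

import numpy as np
import pytest
from scipy import stats

from forgetsim import (
    ExponentialForgetting,
    LinearForgetting,
    Mixture,
    Normal,
    ObservedCurve,
    PowerForgetting,
    Uniform,
    analytic_observed,
    classify_shape,
    fit_observed,
    monte_carlo_observed,
    regime_comparison,
)

BIMODAL = Mixture([(0.6, Normal(4, 0.5)), (0.4, Normal(0.5, 0.5))])


class TestAnalyticObserved:
    def test_peak_on_threshold_gives_half(self):
        """When the shared decrement moves the mode onto the threshold, p = 0.5."""
        mu, theta, rate = 2.0, 0.0, 0.1
        t_half = (mu - theta) / rate
        curve = analytic_observed(Normal(mu, 1.0), LinearForgetting(mu, rate), theta, [t_half])
        assert curve.p[0] == pytest.approx(0.5)

    def test_uniform_straddle_is_exactly_linear(self):
        """A straddling uniform loses the same fraction per unit time."""
        dist, fn, theta = Uniform(0, 10), LinearForgetting(10, 0.2), 4.0
        times = np.linspace(0, 20, 21)  # support straddles theta throughout
        curve = analytic_observed(dist, fn, theta, times)
        expected = (10.0 - theta - 0.2 * times) / 10.0
        assert np.allclose(curve.p, expected, atol=1e-12)

    def test_matches_normal_cdf_oracle(self):
        """Normal + power decrement equals 1 - Phi((theta + d(t) - mu)/sigma)."""
        times = np.arange(0, 51, dtype=float)
        curve = analytic_observed(Normal(2, 1), PowerForgetting(2, 0.4, 0.5), 0.0, times)
        oracle = 1.0 - stats.norm.cdf((0.0 + 0.4 * np.sqrt(times) - 2.0) / 1.0)
        assert np.max(np.abs(curve.p - oracle)) < 1e-8

    def test_monotone_when_decrement_non_decreasing(self):
        for dist in (Normal(2, 1), Uniform(-1, 5), BIMODAL):
            curve = analytic_observed(dist, PowerForgetting(0, 0.3, 0.7), 0.0, np.linspace(0, 40, 81))
            assert np.all(np.diff(curve.p) <= 1e-12)

    def test_step_function_limit_at_tiny_sd(self):
        """A near-degenerate distribution crosses within one grid step."""
        curve = analytic_observed(Normal(2.05, 1e-6), LinearForgetting(2.05, 0.1), 0.0,
                                  np.arange(0, 41, dtype=float))  # crossing at t = 20.5
        drop = np.flatnonzero(curve.p < 0.5)[0]
        assert curve.p[drop - 1] > 0.999
        assert curve.p[drop] < 0.001


class TestMonteCarloObserved:
    CONFIGS = [
        (Normal(2, 1), LinearForgetting(2, 0.05)),
        (Normal(2, 1), PowerForgetting(2, 0.4, 0.5)),
        (Uniform(-1, 5), LinearForgetting(5, 0.08)),
        (Uniform(0, 6), ExponentialForgetting(6, 1.05)),
        (BIMODAL, PowerForgetting(4, 0.5, 0.6)),
        (BIMODAL, ExponentialForgetting(4, 1.04)),
    ]

    @pytest.mark.parametrize("dist,fn", CONFIGS, ids=lambda v: repr(v))
    def test_homogeneous_agrees_with_analytic(self, dist, fn):
        times = np.linspace(0, 40, 21)
        exact = analytic_observed(dist, fn, 0.0, times)
        mc = monte_carlo_observed((dist, fn), 0.0, times, n_items=100_000, seed=5)
        tol = max(3 * float(mc.se.max()), 1e-9)
        assert np.max(np.abs(mc.p - exact.p)) <= tol

    def test_single_immortal_item(self):
        curve = monte_carlo_observed((Normal(5, 1e-9), LinearForgetting(5, 0.0)), 0.0,
                                     np.linspace(0, 100, 11), n_items=1, seed=0)
        assert np.all(curve.p == 1.0)

    def test_same_seed_identical(self):
        args = ((Normal(2, 1), PowerForgetting(2, 0.4, 0.5)), 0.0, np.arange(0, 20, dtype=float))
        a = monte_carlo_observed(*args, n_items=5000, seed=9)
        b = monte_carlo_observed(*args, n_items=5000, seed=9)
        assert np.array_equal(a.p, b.p)

    def test_rejects_missing_n_items(self):
        with pytest.raises(ValueError):
            monte_carlo_observed((Normal(2, 1), LinearForgetting(2, 0.1)), 0.0, [0, 1, 2])


class TestClassifyShape:
    def test_experiment_group_means_are_concave(self):
        """The high-recall experiment pattern: slopes steepen across intervals."""
        report = classify_shape(ObservedCurve(times=[2, 20, 80], p=[0.958, 0.913, 0.658]))
        assert abs(report.slopes[1]) > abs(report.slopes[0])
        assert report.overall == "concave"

    def test_collinear_points_are_linear(self):
        report = classify_shape(ObservedCurve(times=[0, 5, 10, 20], p=[0.9, 0.8, 0.7, 0.5]))
        assert report.overall == "linear"
        assert report.r_squared == pytest.approx(1.0)

    def test_low_recall_tail_is_convex(self):
        """Where p < 0.3 the distribution amplifies the item curve's convexity."""
        times = np.arange(19, 41, dtype=float)
        curve = analytic_observed(Normal(2, 1), PowerForgetting(2, 0.25, 0.8), 0.0, times)
        assert np.all(curve.p < 0.3)
        assert classify_shape(curve).overall == "convex"

    def test_wide_uniform_with_linear_decrement_is_linear(self):
        curve = analytic_observed(Uniform(-50, 50), LinearForgetting(50, 0.5), 0.0,
                                  np.linspace(0, 40, 21))
        assert classify_shape(curve).overall == "linear"

    def test_requires_three_points(self):
        with pytest.raises(ValueError):
            classify_shape(ObservedCurve(times=[0, 1], p=[1.0, 0.5]))

    def test_mixed_when_curvature_changes_sign(self):
        report = classify_shape(ObservedCurve(times=[0, 1, 2, 3], p=[1.0, 0.9, 0.75, 0.65]))
        assert report.overall == "mixed"


class TestRegimeComparison:
    def test_flatter_at_high_recall_curvier_at_low(self):
        """The distribution opposes item-curve convexity at high recall and
        amplifies it at low recall."""
        rc = regime_comparison(Normal(2, 1), PowerForgetting(2, 0.25, 0.8), 0.0,
                               np.arange(0, 51, dtype=float))
        assert rc.observed_high < rc.item_high
        assert rc.observed_low > rc.item_low


class TestFitObserved:
    def test_power_self_fit_recovers_parameters(self):
        t = np.linspace(0, 50, 26)
        p = 0.9 - 0.05 * t**0.6
        fit = fit_observed(t, p, "power")
        assert fit.sse < 1e-10
        assert fit.params["c"] == pytest.approx(0.9, abs=1e-4)
        assert fit.params["a"] == pytest.approx(0.05, abs=1e-4)
        assert fit.params["b"] == pytest.approx(0.6, abs=1e-4)

    def test_correct_family_wins_or_ties(self):
        t = np.linspace(0, 60, 31)
        p = np.clip(1.8 - 1.015**t, 0, 1)
        sse_exp = fit_observed(t, p, "exponential").sse
        sse_pow = fit_observed(t, p, "power").sse
        assert sse_exp <= sse_pow + 1e-10

    def test_constant_input_flagged(self):
        fit = fit_observed([0, 1, 2, 3], [0.8, 0.8, 0.8, 0.8], "power")
        assert fit.constant_input
        assert fit.sse == pytest.approx(0.0)

    def test_heterogeneous_exponential_average_prefers_power(self):
        """Averaging many exponential item curves yields a power-like aggregate."""
        from forgetsim import PopulationSpec, sample_population

        spec = PopulationSpec(family="exponential", s_mean=2.0, s_sd=1.0, rho=0.0,
                              a_base=0.05, kappa=0.5)
        times = np.arange(0, 51, dtype=float)
        pop = sample_population(spec, 200, seed=12)
        curve = monte_carlo_observed(pop, 0.0, times)
        assert fit_observed(times, curve.p, "power").sse <= fit_observed(
            times, curve.p, "exponential"
        ).sse


class TestObservedCurveIO:
    def test_csv_round_trip(self, tmp_path):
        curve = monte_carlo_observed((Normal(2, 1), LinearForgetting(2, 0.1)), 0.0,
                                     np.arange(0, 10, dtype=float), n_items=500, seed=2)
        path = tmp_path / "curve.csv"
        curve.to_csv(path)
        back = ObservedCurve.from_csv(path)
        assert np.allclose(back.p, curve.p)
        assert back.n_items == 500

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            ObservedCurve(times=[0, 1], p=[0.5, 1.4])
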