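"""Study-design scenarios: learning to criterion, retrieval practice, bifurcation."""

import numpy as np
import pytest

from forgetsim import (
    Empirical,
    LinearForgetting,
    Mixture,
    Normal,
    bimodality_coefficient,
    compare_early_forgetting,
    learn_to_criterion,
    recall_fraction,
    retrieval_practice,
)
from forgetsim.distributions import StrengthDistribution


class TestLearnToCriterion:
    def test_single_large_gain_ends_one_step_up(self):
        initial = np.array([0.2, 0.5, 0.9])
        final = learn_to_criterion(initial, thr=1.0, criterion=1, gain=5.0, gain_sd=0.0, seed=0)
        assert np.allclose(final, initial + 5.0)
        assert np.all(final > 1.0)

    def test_zero_noise_homogeneous_start_ends_equal(self):
        final = learn_to_criterion(np.zeros(20), thr=1.0, criterion=3, gain=0.4,
                                   gain_sd=0.0, seed=1)
        assert np.ptp(final) == pytest.approx(0.0)

    def test_all_final_strengths_above_threshold(self):
        rng = np.random.default_rng(2)
        final = learn_to_criterion(rng.normal(-1, 1, 500), thr=0.5, criterion=3,
                                   gain=0.3, gain_sd=0.15, seed=3)
        assert np.all(final > 0.5)

    def test_criterion_shrinks_spread_versus_uncapped_control(self):
        """Retiring items at criterion homogenises strengths relative to giving
        every item the same number of increments without retirement."""
        rng = np.random.default_rng(4)
        initial = rng.normal(0, 1, 10_000)
        theta, gain, gain_sd = 0.5, 0.3, 0.15

        strengths = initial.copy()
        corrects = np.zeros(strengths.size, dtype=int)
        active = np.ones(strengths.size, dtype=bool)
        increments = np.zeros(strengths.size, dtype=int)
        sim_rng = np.random.default_rng(5)
        while active.any():
            k = int(active.sum())
            strengths[active] += gain + gain_sd * sim_rng.standard_normal(k)
            increments[active] += 1
            corrects[active & (strengths > theta)] += 1
            active = corrects < 3

        # control: same total study budget spread evenly, no retirement
        rounds = int(round(increments.mean()))
        ctrl_rng = np.random.default_rng(6)
        control = initial + gain * rounds + gain_sd * np.sqrt(rounds) * ctrl_rng.standard_normal(initial.size)
        assert np.std(strengths, ddof=1) < np.std(control, ddof=1)

    def test_unreachable_criterion_raises(self):
        with pytest.raises(RuntimeError):
            learn_to_criterion([0.0], thr=1e9, criterion=1, gain=0.1, gain_sd=0.0,
                               seed=0, max_rounds=50)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            learn_to_criterion([0.0], thr=1.0, criterion=0, gain=0.5)
        with pytest.raises(ValueError):
            learn_to_criterion([0.0], thr=1.0, criterion=1, gain=-0.5)


class TestRetrievalPractice:
    def test_all_below_threshold_unchanged_without_feedback(self):
        strengths = np.array([-2.0, -1.0, -0.5])
        out = retrieval_practice(strengths, thr=0.0, boost=3.0, feedback="none")
        assert np.array_equal(out, strengths)

    def test_feedback_boosts_everything(self):
        strengths = np.array([-2.0, 0.5, 3.0])
        out = retrieval_practice(strengths, thr=0.0, boost=3.0, feedback="full")
        assert np.allclose(out, strengths + 3.0)

    def test_no_feedback_never_decreases_or_touches_weak_items(self):
        rng = np.random.default_rng(7)
        strengths = rng.normal(0.1, 1.0, 2000)
        out = retrieval_practice(strengths, thr=0.0, boost=3.0, feedback="none")
        assert np.all(out >= strengths)
        below = strengths <= 0.0
        assert np.array_equal(out[below], strengths[below])

    def test_no_feedback_bifurcates_the_distribution(self):
        rng = np.random.default_rng(8)
        strengths = rng.normal(0.1, 1.0, 5000)
        out = retrieval_practice(strengths, thr=0.0, boost=3.0, feedback="none")
        assert bimodality_coefficient(out) > bimodality_coefficient(strengths)

    def test_invalid_feedback_mode(self):
        with pytest.raises(ValueError):
            retrieval_practice([1.0], thr=0.0, boost=1.0, feedback="partial")


def _matched_bifurcated_and_unimodal(theta=0.0):
    """Analytic populations with identical initial recall fractions.

    Unimodal: Normal(theta + 1, 1). Bifurcated: the same above-threshold mass
    parked far above the threshold, the rest far below.
    """
    unimodal = Normal(theta + 1.0, 1.0)
    p0 = recall_fraction(unimodal, theta)
    bifurcated = Mixture([
        (p0, Normal(theta + 5.0, 0.1)),
        (1.0 - p0, Normal(theta - 5.0, 0.1)),
    ])
    return bifurcated, unimodal


class TestCompareEarlyForgetting:
    def test_identical_populations_drop_equally(self):
        rng = np.random.default_rng(9)
        pop = rng.normal(1.0, 1.0, 1000)
        fn = LinearForgetting(1.0, 0.2)
        d1, d2 = compare_early_forgetting(pop, pop.copy(), fn, thr=0.0, window=2.0)
        assert d1 == pytest.approx(d2)

    def test_zero_window_drops_nothing(self):
        rng = np.random.default_rng(10)
        pop = rng.normal(1.0, 1.0, 100)
        fn = LinearForgetting(1.0, 0.2)
        assert compare_early_forgetting(pop, pop, fn, thr=0.0, window=0.0) == (0.0, 0.0)

    def test_bifurcated_population_appears_to_forget_more_slowly(self):
        """Matched initial recall: the bifurcated distribution's above-threshold
        mass sits far from the threshold, so few items cross in a short window."""
        bifurcated, unimodal = _matched_bifurcated_and_unimodal()
        assert recall_fraction(bifurcated, 0.0) == pytest.approx(
            recall_fraction(unimodal, 0.0), abs=1e-9
        )
        fn = LinearForgetting(0.0, 0.5)
        drop_bi, drop_uni = compare_early_forgetting(bifurcated, unimodal, fn,
                                                     thr=0.0, window=1.0)
        assert drop_bi < drop_uni

    @pytest.mark.parametrize("offset", [3.0, 5.0, 8.0])
    def test_bifurcation_advantage_whenever_mass_clears_the_window(self, offset):
        """Parameterised form: holds whenever the above-threshold mass sits at
        least d(window) above the threshold."""
        unimodal = Normal(1.0, 1.0)
        p0 = recall_fraction(unimodal, 0.0)
        bifurcated = Empirical(
            np.concatenate([np.full(int(round(1000 * p0)), offset),
                            np.full(1000 - int(round(1000 * p0)), -offset)])
        )
        fn = LinearForgetting(0.0, 0.5)
        window = 2.0
        assert fn.decrement_at(window) <= offset
        drop_bi, drop_uni = compare_early_forgetting(bifurcated, unimodal, fn,
                                                     thr=0.0, window=window)
        assert drop_bi <= drop_uni


class TestBimodalityCoefficient:
    def test_reference_values(self):
        rng = np.random.default_rng(11)
        normal_bc = bimodality_coefficient(rng.normal(size=20_000))
        uniform_bc = bimodality_coefficient(rng.uniform(size=20_000))
        assert normal_bc == pytest.approx(1 / 3, abs=0.02)
        assert uniform_bc == pytest.approx(5 / 9, abs=0.02)

    def test_needs_four_values(self):
        with pytest.raises(ValueError):
            bimodality_coefficient([1.0, 2.0, 3.0])
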