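import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from anchormi import (
    PatternSummary,
    anchored_variance,
    classify_information,
    crossover_variance,
    delta_Q_term,
    expected_full_variance_primary,
    expected_full_variance_sensitivity,
    info_loss_percent,
    info_simple_mean,
    inflate_to_anchored,
    sample_size_per_arm,
    theorem1_first_term,
)

SIGMA = np.array([[0.4, 0.2, 0.2], [0.2, 0.5, 0.2], [0.2, 0.2, 0.6]])


class TestSimpleMeanInformation:
    def test_no_heterogeneity_recovers_full_information(self):
        i_full, _, i_sens = info_simple_mean(100, 20, 1.0, 1.0)
        assert i_sens == pytest.approx(i_full) == pytest.approx(100.0)

    def test_crossover_point_equals_observed_information(self):
        _, i_obs, i_sens = info_simple_mean(100, 20, 1.0, 2.25)
        assert i_sens == pytest.approx(i_obs) == pytest.approx(80.0)

    def test_information_decreasing_and_vanishing_in_missing_variance(self):
        grid = np.linspace(0.1, 50.0, 200)
        vals = [info_simple_mean(100, 20, 1.0, s)[2] for s in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert info_simple_mean(100, 20, 1.0, 1e9)[2] < 1e-4

    def test_crossover_solved_by_root_finding(self):
        assert crossover_variance(100, 20, 1.0) == pytest.approx(2.25, abs=1e-9)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            info_simple_mean(100, 100, 1.0, 1.0)
        with pytest.raises(ValueError):
            info_simple_mean(100, 20, -1.0, 1.0)


class TestClassification:
    def test_equal_ratios_anchored(self):
        rep = classify_information(100, 80, 90, 72)
        assert rep.classification == "anchored"

    def test_half_ratio_negative(self):
        rep = classify_information(100, 80, 100, 40)
        assert rep.classification == "negative"

    def test_larger_ratio_positive(self):
        rep = classify_information(100, 80, 100, 95)
        assert rep.classification == "positive"


def _pattern(n, n_dev, arm="active"):
    return PatternSummary(arm=arm, n=n, n_complete=n - sum(n_dev.values()), n_dev=n_dev)


class TestExpectedVariances:
    def test_asthma_design_values(self):
        assert expected_full_variance_primary(SIGMA, 250, baseline_adjusted=False) == pytest.approx(
            2 * 0.6 / 250
        )
        assert expected_full_variance_primary(SIGMA, 250, baseline_adjusted=True) == pytest.approx(
            2 * (0.6 - 0.04 / 0.4) / 250
        )

    def test_no_deviators_reduces_to_primary(self):
        tv = expected_full_variance_sensitivity(
            SIGMA, 250, _pattern(250, {2: 0, 3: 0}), {2: 1.9, 3: 1.9}, 2.2
        )
        assert tv.v_full_sensitivity == pytest.approx(tv.v_full_primary)
        assert tv.q_term == 0.0

    def test_mar_like_means_add_nothing(self):
        tv = expected_full_variance_sensitivity(
            SIGMA, 250, _pattern(250, {2: 38, 3: 37}), {2: 2.2, 3: 2.2}, 2.2
        )
        assert tv.q_term == pytest.approx(0.0)

    def test_jump_to_reference_arithmetic(self):
        """30% active-arm dropout under jump-to-reference: both patterns end
        at the reference mean 1.9, giving 0.09*(175*75)/250^3 extra variance."""
        tv = expected_full_variance_sensitivity(
            SIGMA, 250, _pattern(250, {2: 38, 3: 37}), {2: 1.9, 3: 1.9}, 2.2
        )
        expected_extra = 0.3**2 * 175 * 75 / 250**3
        assert tv.q_term == pytest.approx(expected_extra)
        assert tv.v_full_sensitivity == pytest.approx(0.004 + expected_extra)

    @given(
        n_d2=st.integers(0, 100),
        n_d3=st.integers(0, 100),
        mu2=st.floats(-3, 3),
        mu3=st.floats(-3, 3),
    )
    def test_sensitivity_variance_never_below_primary(self, n_d2, n_d3, mu2, mu3):
        tv = expected_full_variance_sensitivity(
            SIGMA, 250, _pattern(250, {2: n_d2, 3: n_d3}), {2: mu2, 3: mu3}, 2.2
        )
        assert tv.v_full_sensitivity >= tv.v_full_primary - 1e-15


class TestDeltaQ:
    def test_zero_delta(self):
        assert delta_Q_term(_pattern(250, {2: 38, 3: 37}), 0.0, 3, 250) == 0.0

    def test_single_pattern_reduction(self):
        """Only visit-2 deviators: Q collapses to n_o*n_d2*(J-1)^2*delta^2/n^3."""
        q = delta_Q_term(_pattern(100, {2: 20}), -0.5, 3, 100)
        assert q == pytest.approx(80 * 20 * 4 * 0.25 / 100**3)

    def test_two_pattern_hand_sum(self):
        """n_o=200, n_d2=n_d3=25, delta=-1, J=3:
        Q = (200*25*4 + 200*25*1 + 2*25*25*1)/250^3."""
        q = delta_Q_term(_pattern(250, {2: 25, 3: 25}), -1.0, 3, 250)
        assert q == pytest.approx((20000 + 5000 + 1250) / 250**3)


class TestAnchoredVariance:
    def test_no_missing_data_returns_sensitivity_variance(self):
        assert anchored_variance(0.004, 0.004, 0.005) == pytest.approx(0.005)

    def test_arithmetic(self):
        assert anchored_variance(0.006, 0.004, 0.005) == pytest.approx(0.0075)

    def test_never_below_full_sensitivity(self):
        assert anchored_variance(0.0061, 0.004, 0.005) >= 0.005

    def test_impossible_information_gain_warns(self):
        with pytest.warns(UserWarning, match="cannot increase"):
            anchored_variance(0.003, 0.004, 0.005)


class TestTheorem1FirstTerm:
    def _history_means(self):
        return {2: np.array([1.0, 2.0]), 3: np.array([1.0, 2.0, 2.21])}

    def test_fixed_delta_exactly_zero(self):
        rep = theorem1_first_term(
            SIGMA, _pattern(250, {2: 38, 3: 37}), self._history_means(), 250, 175, "delta"
        )
        assert rep.first_term == 0.0
        assert all(v == 0.0 for v in rep.per_pattern_contributions.values())

    def test_no_deviators_zero(self):
        rep = theorem1_first_term(
            SIGMA, _pattern(250, {2: 0, 3: 0}), self._history_means(), 250, 250, "reference_full"
        )
        assert rep.first_term == 0.0

    def test_reference_full_small_relative_to_design_variance(self):
        """At the asthma design with 30% dropout the leading discrepancy is
        O(n^-2): under 5% of the 2*sigma_{J.1}/n design variance."""
        rep = theorem1_first_term(
            SIGMA, _pattern(250, {2: 38, 3: 37}), self._history_means(), 250, 175,
            "reference_full",
        )
        assert rep.first_term > 0
        assert rep.first_term / 0.004 < 0.05
        assert rep.first_term == pytest.approx(sum(rep.per_pattern_contributions.values()))

    def test_history_at_its_mean_collapses_to_residual_variance_scale(self):
        """Evaluated at the true history means, the quadratic form equals
        pi_dj^2 * sigma^2_{J|hist} * (1/n_o - 1/n) exactly."""
        pat = _pattern(250, {2: 38, 3: 0})
        rep = theorem1_first_term(
            SIGMA, pat, {2: np.array([1.0, 2.0])}, 250, 175, "reference_full"
        )
        resid = 0.6 - 0.2**2 / 0.4
        pi = 38 / 250
        assert rep.per_pattern_contributions[2] == pytest.approx(
            pi**2 * resid * (1 / 175 - 1 / 250)
        )

    def test_vanishes_like_one_over_n_squared(self):
        hist = {2: np.array([1.0, 2.0]), 3: np.array([1.0, 2.0, 2.21])}
        small = theorem1_first_term(
            SIGMA, _pattern(250, {2: 38, 3: 37}), hist, 250, 175, "reference_full"
        ).first_term
        big = theorem1_first_term(
            SIGMA, _pattern(2500, {2: 380, 3: 370}), hist, 2500, 1750, "reference_full"
        ).first_term
        assert small / big == pytest.approx(10.0, rel=0.01)

    def test_random_delta_is_negative_pi_squared_sigma_delta(self):
        rep = theorem1_first_term(
            SIGMA, _pattern(250, {2: 38, 3: 37}), self._history_means(), 250, 175,
            "delta_random", sigma_delta=0.46,
        )
        assert rep.first_term == pytest.approx(-(0.3**2) * 0.46**2)
        assert sum(rep.per_pattern_contributions.values()) == pytest.approx(rep.first_term)


class TestInfoLoss:
    def test_equal_ses_no_loss(self):
        assert info_loss_percent(0.07, 0.07) == 0.0

    def test_peer_review_worked_example(self):
        loss = info_loss_percent(0.072, 0.132)
        assert loss == pytest.approx(70.2479, abs=1e-3)
        assert round(loss) == 70

    def test_root_two_halves_information(self):
        assert info_loss_percent(1.0, np.sqrt(2.0)) == pytest.approx(50.0)

    def test_negative_loss_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            info_loss_percent(0.2, 0.1)


class TestInflateToAnchored:
    def test_equal_variances_identity(self):
        assert inflate_to_anchored(0.3, 0.004, 0.004, np.random.default_rng(0)) == 0.3

    def test_smaller_anchored_variance_rejected(self):
        with pytest.raises(ValueError):
            inflate_to_anchored(0.3, 0.005, 0.004, np.random.default_rng(0))

    def test_fixed_seed_reproducible(self):
        a = inflate_to_anchored(0.3, 0.004, 0.006, np.random.default_rng(1))
        b = inflate_to_anchored(0.3, 0.004, 0.006, np.random.default_rng(1))
        assert a == b

    def test_long_run_variance_recovers_anchored_variance(self):
        v_ml, v_anchor = 0.004, 0.007
        rng = np.random.default_rng(2)
        base = rng.normal(0.3, np.sqrt(v_ml), size=10_000)
        adjusted = np.array([inflate_to_anchored(b, v_ml, v_anchor, rng) for b in base])
        assert adjusted.var(ddof=1) == pytest.approx(v_anchor, rel=0.05)
        assert adjusted.mean() == pytest.approx(0.3, abs=3 * np.sqrt(v_anchor / 10_000))


class TestSampleSize:
    def test_asthma_design(self):
        assert sample_size_per_arm(0.23, 0.5, 0.05, 0.80) == 75

    def test_doubling_sd_quadruples_n(self):
        n1 = sample_size_per_arm(0.1, 1.0, 0.05, 0.80)
        n2 = sample_size_per_arm(0.1, 2.0, 0.05, 0.80)
        assert abs(n2 - 4 * n1) <= 3  # rounding only

    def test_returned_n_achieves_the_target_power(self):
        """Normal-approximation power at the returned n is >= 80% and drops
        below at n-1 (minimality)."""
        n = sample_size_per_arm(0.23, 0.5, 0.05, 0.80)

        def analytic_power(n_arm):
            se = 0.5 * np.sqrt(2.0 / n_arm)
            return stats.norm.sf(stats.norm.ppf(0.975) - 0.23 / se)

        assert analytic_power(n) >= 0.80
        assert analytic_power(n - 1) < 0.80

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sample_size_per_arm(0.0, 0.5, 0.05, 0.8)
        with pytest.raises(ValueError):
            sample_size_per_arm(0.2, 0.5, 1.5, 0.8)
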