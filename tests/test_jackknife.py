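"""Leave-one-out correlation estimator: closed-form cases, brute-force
oracle agreement, bias-gated selection."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from dmnconn import (
    SubjectSpec,
    confidence_interval,
    correlation_matrices,
    estimate_pair,
    jackknife_bias,
    jackknife_se,
    jackknife_theta,
    loo_correlations,
    select_estimate,
    simulate_subject,
)
from dmnconn.jackknife import (
    RULE_CI_LIMIT,
    RULE_JACKKNIFE_MEAN,
    DegenerateSeriesError,
    LooCorrelations,
)


def brute_force_loo(x, y):
    """Independent oracle: explicit deletion loop + reference Pearson."""
    n = len(x)
    return np.array(
        [
            scipy.stats.pearsonr(np.delete(x, i), np.delete(y, i))[0]
            for i in range(n)
        ]
    )


class TestLooCorrelations:
    def test_perfect_collinearity_is_deletion_invariant(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        loo = loo_correlations(x, x.copy())
        np.testing.assert_allclose(loo.values, 1.0, atol=1e-12)

    def test_removing_the_outlier_restores_collinearity(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        loo = loo_correlations(x, y)
        assert loo.values[4] == pytest.approx(1.0, abs=1e-12)
        assert np.all(loo.values[:4] < 1.0)

    def test_matches_brute_force_on_fixed_example(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        np.testing.assert_allclose(
            loo_correlations(x, y).values, brute_force_loo(x, y), atol=1e-12
        )

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(10):
            x = rng.standard_normal(25)
            y = rng.standard_normal(25)
            np.testing.assert_allclose(
                loo_correlations(x, y).values, brute_force_loo(x, y), atol=1e-12
            )

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            loo_correlations(np.arange(4.0), np.arange(4.0))

    def test_degenerate_after_deletion_raises(self):
        # constant except one element: removing it leaves a constant series
        x = np.array([1.0, 1.0, 1.0, 1.0, 2.0])
        y = np.array([0.3, 1.1, 0.2, 0.9, 0.5])
        with pytest.raises(DegenerateSeriesError, match="volume 4"):
            loo_correlations(x, y)

    @settings(deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**16))
    def test_values_always_in_unit_interval(self, seed):
        g = np.random.default_rng(seed)
        loo = loo_correlations(g.standard_normal(12), g.standard_normal(12))
        assert np.all(np.abs(loo.values) <= 1.0)


class TestPointEstimates:
    def test_theta_is_arithmetic_mean(self):
        loo = LooCorrelations(np.array([0.2, 0.4, 0.6]))
        assert jackknife_theta(loo) == pytest.approx(0.4, abs=1e-15)
        assert jackknife_theta(LooCorrelations(np.ones(5))) == 1.0

    def test_se_zero_without_dispersion(self):
        assert jackknife_se(LooCorrelations(np.full(7, 0.3))) == 0.0

    def test_se_two_point_closed_form(self):
        # sqrt((1/2) * (0.25 + 0.25)) = 0.5
        loo = LooCorrelations(np.array([0.0, 1.0]))
        assert jackknife_se(loo) == pytest.approx(0.5, abs=1e-15)

    @settings(deadline=None, derandomize=True)
    @given(c=st.floats(0.05, 1.0), seed=st.integers(0, 1000))
    def test_se_homogeneous_in_deviations(self, c, seed):
        g = np.random.default_rng(seed)
        dev = g.uniform(-0.2, 0.2, size=9)
        dev -= dev.mean()
        base = LooCorrelations(0.1 + dev)
        scaled = LooCorrelations(0.1 + c * dev)
        assert jackknife_se(scaled) == pytest.approx(
            c * jackknife_se(base), rel=1e-9
        )

    def test_bias_zero_when_estimators_agree(self):
        assert jackknife_bias(0.37, 0.37, 100) == 0.0

    def test_bias_closed_form(self):
        assert jackknife_bias(0.5, 0.4, 11) == pytest.approx(1.0, abs=1e-12)

    def test_bias_sign_follows_gap(self):
        assert jackknife_bias(0.5, 0.6, 10) < 0
        assert jackknife_bias(0.6, 0.5, 10) > 0


class TestConfidenceInterval:
    def test_degenerate_interval_at_zero_se(self):
        assert confidence_interval(0.4, 0.0, 50) == (0.4, 0.4)

    def test_contains_theta_and_is_ordered(self, rng):
        for _ in range(20):
            theta = rng.uniform(-0.9, 0.9)
            se = rng.uniform(0.0, 0.3)
            lo, hi = confidence_interval(theta, se, 30)
            assert lo <= theta <= hi

    def test_t_quantile_half_width(self):
        # t_{0.025, 220} * 0.1 ~= 0.1971
        lo, hi = confidence_interval(0.0, 0.1, n=221, level=0.95)
        assert (hi - lo) / 2 == pytest.approx(0.1971, abs=5e-4)

    def test_bounds_clamped_to_correlation_range(self):
        lo, hi = confidence_interval(0.9, 1.0, 10)
        assert lo >= -1.0 and hi <= 1.0

    def test_bad_level_rejected(self):
        with pytest.raises(ValueError):
            confidence_interval(0.0, 0.1, 10, level=1.5)


class TestSelection:
    def test_small_bias_keeps_jackknife_mean(self):
        r, rule = select_estimate(0.5, 0.0, 0.3, 0.7, bias_tol=0.05)
        assert r == 0.5 and rule == RULE_JACKKNIFE_MEAN

    def test_large_bias_takes_lower_limit_for_positive_r(self):
        r, rule = select_estimate(0.5, 5.0, 0.3, 0.7, bias_tol=0.05)
        assert r == 0.3 and rule == RULE_CI_LIMIT

    def test_large_bias_takes_bound_nearer_zero_for_negative_r(self):
        r, rule = select_estimate(-0.5, 5.0, -0.7, -0.3, bias_tol=0.05)
        assert r == -0.3 and rule == RULE_CI_LIMIT

    def test_selection_never_inflates_magnitude_beyond_interval(self, rng):
        for _ in range(100):
            theta = rng.uniform(-0.8, 0.8)
            se = rng.uniform(0.01, 0.2)
            lo, hi = confidence_interval(theta, se, 40)
            r, rule = select_estimate(theta, 1.0, lo, hi, bias_tol=0.05)
            assert rule == RULE_CI_LIMIT
            assert abs(r) <= max(abs(lo), abs(hi))
            assert abs(r) == min(abs(lo), abs(hi))


class TestEstimatePair:
    def test_agrees_with_brute_force_summaries(self, rng):
        for _ in range(10):
            x = rng.standard_normal(20)
            y = rng.standard_normal(20)
            est = estimate_pair(x, y)
            loo = brute_force_loo(x, y)
            theta = loo.mean()
            se = np.sqrt(19 / 20 * np.sum((loo - theta) ** 2))
            r_full = scipy.stats.pearsonr(x, y)[0]
            assert est.theta == pytest.approx(theta, abs=1e-12)
            assert est.se == pytest.approx(se, abs=1e-12)
            assert est.bias == pytest.approx(19 * (theta - r_full), abs=1e-12)


class TestCorrelationMatrices:
    def test_pair_count_for_full_atlas_size(self):
        ts = simulate_subject(
            np.eye(48), SubjectSpec(t_volumes=30, spike_rate=0.0), seed=0
        )
        mats = correlation_matrices(ts)
        iu = np.triu_indices(48, 1)
        assert iu[0].size == 1128
        assert np.all(np.isfinite(mats.theta[iu]))

    def test_duplicated_column_gives_unit_correlation(self, rng):
        x = rng.standard_normal((60, 3))
        x[:, 2] = x[:, 0]
        mats = correlation_matrices(x)
        assert mats.r_selected[0, 2] == pytest.approx(1.0, abs=1e-9)

    def test_matrices_symmetric_with_convention_diagonals(self, rng):
        mats = correlation_matrices(rng.standard_normal((40, 6)))
        for m in (mats.theta, mats.se, mats.bias, mats.r_selected):
            np.testing.assert_array_equal(m, m.T)
        np.testing.assert_array_equal(np.diag(mats.theta), 1.0)
        np.testing.assert_array_equal(np.diag(mats.r_selected), 1.0)
        np.testing.assert_array_equal(np.diag(mats.se), 0.0)
        np.testing.assert_array_equal(np.diag(mats.bias), 0.0)

    def test_matches_per_pair_path(self, rng):
        data = rng.standard_normal((30, 5))
        mats = correlation_matrices(data)
        for i in range(5):
            for j in range(i + 1, 5):
                est = estimate_pair(data[:, i], data[:, j])
                assert mats.theta[i, j] == pytest.approx(est.theta, abs=1e-10)
                assert mats.se[i, j] == pytest.approx(est.se, abs=1e-10)
                assert mats.bias[i, j] == pytest.approx(est.bias, abs=1e-10)
                assert mats.r_selected[i, j] == pytest.approx(
                    est.r_selected, abs=1e-10
                )

    def test_clean_data_jackknife_tracks_plain_pearson(self):
        ts = simulate_subject(
            np.eye(20), SubjectSpec(t_volumes=220, ar1_phi=0.0, spike_rate=0.0), seed=3
        )
        mats = correlation_matrices(ts)
        iu = np.triu_indices(20, 1)
        assert np.max(np.abs(mats.theta[iu] - mats.r_full[iu])) <= 0.01

    def test_clean_data_rarely_triggers_ci_rule(self):
        ts = simulate_subject(
            np.eye(20), SubjectSpec(t_volumes=220, ar1_phi=0.0, spike_rate=0.0), seed=4
        )
        mats = correlation_matrices(ts)
        iu = np.triu_indices(20, 1)
        assert mats.ci_limit_mask[iu].mean() <= 0.01

    def test_constant_column_raises_named_error(self, rng):
        data = rng.standard_normal((30, 4))
        data[:, 1] = 7.0
        with pytest.raises(DegenerateSeriesError, match="column 1"):
            correlation_matrices(data)
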