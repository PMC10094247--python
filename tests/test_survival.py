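import numpy as np
import pytest
from scipy import stats

from isomed.grouping import AnalysisError
from isomed.survival import (
    FOUR_GROUP_LABELS,
    SurvivalData,
    _two_group_logrank_chi2,
    cox_univariate,
    km_estimate,
    logrank_test,
    optimal_cutpoint,
    stratify_four_groups,
    weibull_aft_fit,
)


def _product_limit_oracle(time, event, t):
    """Direct product over distinct event times <= t."""
    time, event = np.asarray(time, float), np.asarray(event, bool)
    s = 1.0
    for u in np.unique(time[event]):
        if u > t:
            break
        at_risk = np.sum(time >= u)
        d = np.sum((time == u) & event)
        s *= 1.0 - d / at_risk
    return s


class TestKaplanMeier:
    def test_two_events_closed_form(self):
        s = km_estimate(SurvivalData([1.0, 2.0], [1, 1]))
        assert s(1.0) == pytest.approx(0.5)
        assert s(2.0) == pytest.approx(0.0)

    def test_all_censored_curve_is_one(self):
        s = km_estimate(SurvivalData([1.0, 2.0, 3.0], [0, 0, 0]))
        assert s(3.0) == pytest.approx(1.0)

    def test_censoring_between_events(self):
        # product-limit: S(1) = 2/3, unchanged at the censoring time,
        # and the last subject's event empties the risk set
        s = km_estimate(SurvivalData([1.0, 2.0, 3.0], [1, 0, 1]))
        assert s(1.0) == pytest.approx(2 / 3)
        assert s(2.5) == pytest.approx(2 / 3)
        assert s(3.0) == pytest.approx(0.0)

    def test_matches_product_limit_oracle_on_random_instances(self, rng):
        for _ in range(20):
            n = rng.integers(3, 15)
            time = rng.exponential(2.0, n) + 0.01
            event = rng.random(n) < 0.7
            if not event.any():
                continue
            s = km_estimate(SurvivalData(time, event))
            for t in np.unique(time):
                assert s(t) == pytest.approx(
                    _product_limit_oracle(time, event, t), abs=1e-12
                )

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            SurvivalData([0.0, 1.0], [1, 1])


class TestLogrank:
    def test_identical_groups_calibrated_under_permutation(self, rng):
        time = rng.exponential(2.0, 80) + 0.01
        event = rng.random(80) < 0.8
        data = SurvivalData(time, event)
        rejections = 0
        for _ in range(200):
            labels = rng.permutation(np.arange(80) < 40)
            _, _, p = logrank_test(data, labels)
            rejections += p < 0.05
        margin = 2.58 * np.sqrt(0.05 * 0.95 / 200)
        assert rejections / 200 <= 0.05 + margin

    def test_strong_hazard_ratio_detected(self, rng):
        n = 100
        g = np.r_[np.zeros(n), np.ones(n)]
        time = -np.log(rng.random(2 * n)) / np.exp(np.log(4.0) * g)
        data = SurvivalData(time + 1e-9, np.ones(2 * n))
        _, df, p = logrank_test(data, g)
        assert df == 1 and p < 0.01

    def test_single_group_rejected(self):
        data = SurvivalData([1.0, 2.0], [1, 1])
        with pytest.raises(AnalysisError):
            logrank_test(data, np.array(["a", "a"]))

    def test_fast_two_group_statistic_matches_lifelines(self, rng):
        time = rng.exponential(1.0, 60) + 0.01
        event = rng.random(60) < 0.7
        groups = rng.random(60) < 0.5
        data = SurvivalData(time, event)
        chi2, _, _ = logrank_test(data, groups)
        fast = _two_group_logrank_chi2(data.time, data.event, groups)
        assert fast == pytest.approx(chi2, rel=1e-8)


def _breslow_loglik_oracle(beta, time, event, x):
    """Independent, literal Breslow partial log-likelihood."""
    ll = 0.0
    for i in range(len(time)):
        if not event[i]:
            continue
        risk = time >= time[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestCoxUnivariate:
    def test_null_covariate_wald_calibrated(self):
        hits = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            time = rng.exponential(1.0, 200) + 1e-9
            x = rng.normal(size=200)
            fit = cox_univariate(SurvivalData(time, np.ones(200)), x)
            hits += abs(fit.log_hr) < 2 * fit.se
        assert hits >= 95

    def test_parameter_recovery(self, rng):
        n = 500
        x = rng.normal(size=n)
        time = -np.log(rng.random(n)) / np.exp(0.7 * x)
        fit = cox_univariate(SurvivalData(time + 1e-9, np.ones(n)), x)
        assert fit.converged
        assert abs(fit.log_hr - 0.7) < 3 * fit.se

    def test_score_residual_small_when_converged(self, rng):
        x = rng.normal(size=100)
        time = rng.exponential(1.0, 100) + 1e-9
        fit = cox_univariate(SurvivalData(time, np.ones(100)), x)
        assert fit.converged and fit.score_residual < 1e-6

    def test_four_subject_grid_oracle(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 0, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0])
        fit = cox_univariate(SurvivalData(time, event), x)
        grid = np.linspace(-4, 4, 8001)
        lls = [_breslow_loglik_oracle(b, time, event, x) for b in grid]
        beta_grid = grid[int(np.argmax(lls))]
        assert fit.log_hr == pytest.approx(beta_grid, abs=2e-3)

    def test_constant_covariate_rejected(self):
        with pytest.raises(AnalysisError):
            cox_univariate(SurvivalData([1.0, 2.0], [1, 1]), np.ones(2))


class TestOptimalCutpoint:
    def test_monotone_marker_separates_extremes(self, rng):
        n = 60
        time = np.sort(rng.exponential(2.0, n)) + 0.01
        data = SurvivalData(time, np.ones(n))
        cut, stat = optimal_cutpoint(data, time, min_fraction=0.1)
        assert stat > 0
        # split puts short survivors on one side of the cutoff
        assert np.min(time) <= cut <= np.max(time)

    def test_two_valued_marker_has_unique_split(self, rng):
        time = rng.exponential(1.0, 40) + 0.01
        marker = np.r_[np.zeros(20), np.ones(20)]
        cut, _ = optimal_cutpoint(SurvivalData(time, np.ones(40)), marker, 0.1)
        assert cut == 0.0

    def test_equals_independent_reverse_order_scan(self, rng):
        n = 50
        time = rng.exponential(1.0, n) + 0.01
        event = rng.random(n) < 0.8
        marker = rng.normal(size=n)
        data = SurvivalData(time, event)
        cut, stat = optimal_cutpoint(data, marker, 0.1)

        best = (None, -np.inf)
        for c in np.unique(marker)[:-1][::-1]:  # reversed iteration order
            high = marker > c
            if min(high.sum(), (~high).sum()) < 0.1 * n:
                continue
            s = _two_group_logrank_chi2(data.time, data.event, high)
            if s > best[1] or (s == best[1] and c < best[0]):
                best = (float(c), float(s))
        assert (cut, stat) == pytest.approx(best)

    def test_selection_inflation_documented(self):
        # the maximally selected statistic stochastically dominates a
        # prespecified median split under the null
        max_stats, fixed_stats = [], []
        for s in range(60):
            rng = np.random.default_rng(s)
            n = 60
            time = rng.exponential(1.0, n) + 0.01
            marker = rng.normal(size=n)
            data = SurvivalData(time, np.ones(n))
            _, stat = optimal_cutpoint(data, marker, 0.1)
            max_stats.append(stat)
            fixed_stats.append(
                _two_group_logrank_chi2(data.time, data.event, marker > np.median(marker))
            )
        assert np.median(max_stats) > np.median(fixed_stats)

    def test_no_admissible_split_rejected(self):
        data = SurvivalData([1.0, 2.0, 3.0, 4.0, 5.0], np.ones(5))
        marker = np.array([0.0, 1.0, 1.0, 1.0, 1.0])
        with pytest.raises(AnalysisError):
            optimal_cutpoint(data, marker, min_fraction=0.4)


class TestFourGroupStratification:
    def test_corner_cases(self):
        labels = stratify_four_groups(
            np.array([1.0, 0.0]), np.array([1.0, 0.0]), 0.5, 0.5
        )
        assert labels.tolist() == [FOUR_GROUP_LABELS[0], FOUR_GROUP_LABELS[3]]

    def test_all_below_both_cuts_single_group(self):
        labels = stratify_four_groups(np.zeros(5), np.zeros(5), 0.5, 0.5)
        assert set(labels) == {FOUR_GROUP_LABELS[3]}

    def test_median_cuts_balance_groups_on_average(self):
        sizes = np.zeros(4)
        n_seeds = 20
        for s in range(n_seeds):
            rng = np.random.default_rng(s)
            iso1, iso2 = rng.normal(size=400), rng.normal(size=400)
            labels = stratify_four_groups(
                iso1, iso2, float(np.median(iso1)), float(np.median(iso2))
            )
            for i, lab in enumerate(FOUR_GROUP_LABELS):
                sizes[i] += np.sum(labels == lab)
        np.testing.assert_allclose(sizes / n_seeds, 100.0, atol=5.0)


class TestWeibullAft:
    def test_parameter_recovery_with_censoring(self, rng):
        n = 1000
        x = rng.normal(size=n)
        sigma = 0.6
        w = np.log(-np.log(rng.random(n)))
        T = np.exp(2.0 - 0.5 * x + sigma * w)
        C = rng.uniform(0, np.quantile(T, 0.99) * 1.5, size=n)
        data = SurvivalData(np.minimum(T, C), T <= C)
        fit = weibull_aft_fit(data, x)
        assert fit.converged
        se = np.sqrt(np.diag(fit.covariance))
        assert abs(fit.coefficients[0] - 2.0) < 3 * se[0]
        assert abs(fit.coefficients[1] + 0.5) < 3 * se[1]
        assert abs(fit.log_scale - np.log(sigma)) < 3 * se[2]

    def test_covariance_symmetric(self, rng):
        x = rng.normal(size=200)
        T = np.exp(1.0 + 0.3 * x + 0.5 * np.log(-np.log(rng.random(200))))
        fit = weibull_aft_fit(SurvivalData(T, np.ones(200)), x)
        np.testing.assert_allclose(fit.covariance, fit.covariance.T, atol=1e-10)

    def test_exponential_closed_form_limit(self, rng):
        # sigma fixed at 1 and no censoring: MLE intercept = log(mean time)
        T = rng.exponential(3.0, 300)
        fit = weibull_aft_fit(SurvivalData(T, np.ones(300)), None, fixed_log_scale=0.0)
        assert fit.coefficients[0] == pytest.approx(np.log(T.mean()), abs=1e-6)

    def test_duplicated_covariate_rejected(self, rng):
        x = rng.normal(size=50)
        T = rng.exponential(1.0, 50) + 1e-9
        with pytest.raises(AnalysisError):
            weibull_aft_fit(SurvivalData(T, np.ones(50)), np.column_stack([x, x]))

    def test_no_events_rejected(self, rng):
        T = rng.exponential(1.0, 30) + 1e-9
        with pytest.raises(AnalysisError):
            weibull_aft_fit(SurvivalData(T, np.zeros(30)), None)

    def test_matches_lifelines_weibull_aft(self, rng):
        import pandas as pd
        from lifelines import WeibullAFTFitter

        n = 400
        x = rng.normal(size=n)
        T = np.exp(1.5 - 0.4 * x + 0.5 * np.log(-np.log(rng.random(n))))
        C = rng.uniform(0, np.quantile(T, 0.95) * 2, size=n)
        time, event = np.minimum(T, C), T <= C
        fit = weibull_aft_fit(SurvivalData(time, event), x)
        df = pd.DataFrame({"T": time, "E": event.astype(int), "x": x})
        ll = WeibullAFTFitter().fit(df, "T", "E")
        # lifelines: log lambda_ = intercept + coef * x; same log-time scale
        assert fit.coefficients[1] == pytest.approx(
            ll.params_[("lambda_", "x")], abs=1e-3
        )
        assert fit.coefficients[0] == pytest.approx(
            ll.params_[("lambda_", "Intercept")], abs=1e-3
        )
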