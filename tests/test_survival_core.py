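"""Unit, oracle, and property tests for the survival statistics core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from roscore.survival import (
    ConstantCovariateError,
    auc_mann_whitney,
    cox_fit,
    km_estimate,
    km_median,
    logrank_test,
    pearson_r,
)

# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def km_oracle_redistribute(times, events):
    """Redistribute-to-the-right estimate of S at each distinct event time.

    Every observation starts with mass 1/n; walking forward in time,
    a censored observation's mass is split equally over the strictly later
    observations. S(t) is one minus the cumulated event mass. Censored
    observations tie-break after events at the same time (at-risk rule).
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    order = np.lexsort((1 - events, times))  # events first within a tie
    t, e = times[order], events[order]
    n = len(t)
    mass = np.full(n, 1.0 / n)
    s = 1.0
    out_t, out_s = [], []
    for i in range(n):
        if e[i] == 1:
            s -= mass[i]
            out_t.append(t[i])
            out_s.append(s)
        else:
            later = np.arange(n) > i
            if later.any():
                mass[later] += mass[i] / later.sum()
            mass[i] = 0.0
    # collapse tied event times (keep last S at each time)
    collapsed = {}
    for ti, si in zip(out_t, out_s):
        collapsed[ti] = si
    return np.array(sorted(collapsed)), np.array([collapsed[k] for k in sorted(collapsed)])


def efron_loglik(beta, times, events, x):
    """Hand-coded Efron log partial likelihood for one covariate (loops)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    ll = 0.0
    for ut in np.unique(times[events == 1]):
        D = (times == ut) & (events == 1)
        R = times >= ut
        d = int(D.sum())
        wR = np.exp(beta * x[R]).sum()
        wD = np.exp(beta * x[D]).sum()
        ll += beta * x[D].sum()
        for ell in range(d):
            ll -= np.log(wR - (ell / d) * wD)
    return ll


def golden_max(f, lo, hi, tol=1e-10):
    phi = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    c, d = b - phi * (b - a), a + phi * (b - a)
    while abs(b - a) > tol:
        if f(c) > f(d):
            b, d = d, c
            c = b - phi * (b - a)
        else:
            a, c = c, d
            d = a + phi * (b - a)
    return (a + b) / 2


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


class TestKM:
    def test_closed_form_no_censoring(self):
        c = km_estimate([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(c.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(c.at_risk, [3, 2, 1])

    def test_censoring_after_last_event(self):
        c = km_estimate([1, 2], [1, 0])
        np.testing.assert_allclose(c.survival, [0.5])
        assert c.event_times.tolist() == [1.0]

    def test_all_censored_curve_is_one(self):
        c = km_estimate([1, 2, 3], [0, 0, 0])
        assert c.event_times.size == 0
        assert c.median is None

    def test_equals_empirical_survival_without_censoring(self, rng):
        t = rng.exponential(2.0, 100)
        c = km_estimate(t, np.ones(100))
        for q in [0.1, 0.5, 1.0, 3.0]:
            np.testing.assert_allclose(c.survival_at(q), (t > q).mean(), atol=1e-12)

    def test_redistribute_oracle_with_censoring(self, rng):
        t = np.round(rng.exponential(2.0, 50), 1) + 0.1  # forces ties
        e = (rng.random(50) < 0.7).astype(int)
        c = km_estimate(t, e)
        ot, os_ = km_oracle_redistribute(t, e)
        np.testing.assert_allclose(c.event_times, ot)
        np.testing.assert_allclose(c.survival, os_, atol=1e-12)

    def test_greenwood_matches_direct_formula(self, rng):
        t = rng.exponential(1.0, 40)
        e = (rng.random(40) < 0.6).astype(int)
        c = km_estimate(t, e)
        acc = 0.0
        for i in range(len(c.event_times)):
            acc += c.events[i] / (c.at_risk[i] * (c.at_risk[i] - c.events[i]))
            np.testing.assert_allclose(c.greenwood_se[i], c.survival[i] * np.sqrt(acc))

    def test_survival_non_increasing_and_at_risk_decreasing(self, rng):
        t = np.round(rng.exponential(1.0, 80), 1) + 0.1
        e = (rng.random(80) < 0.5).astype(int)
        c = km_estimate(t, e)
        assert np.all(np.diff(c.survival) <= 1e-15)
        assert np.all(np.diff(c.at_risk) < 0)

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            km_estimate([], [])

    def test_nonpositive_time_error(self):
        with pytest.raises(ValueError, match="positive"):
            km_estimate([0.0, 1.0], [1, 1])


class TestKMMedian:
    def test_first_time_at_half(self):
        c = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        assert km_median(c) == 2.0  # S(2) = 0.5 exactly

    def test_all_censored_undefined(self):
        assert km_median(km_estimate([1, 2, 3, 4], [0, 0, 0, 0])) is None

    def test_monte_carlo_exponential_median(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(1 / np.log(2), 200)  # analytic median = 1
        med = km_median(km_estimate(t, np.ones(200)))
        assert abs(med - 1.0) < 0.15


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------


class TestLogRank:
    def test_identical_groups(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 1, 0, 1, 1, 1, 0, 1]
        g = [0, 0, 0, 0, 1, 1, 1, 1]
        res = logrank_test(t, e, g)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_observed_minus_expected_sums_to_zero(self, rng):
        t = rng.exponential(1, 60)
        e = (rng.random(60) < 0.7).astype(int)
        g = rng.integers(0, 3, 60)
        res = logrank_test(t, e, g)
        assert (res.observed - res.expected).sum() == pytest.approx(0.0, abs=1e-9)

    def test_permutation_oracle_ten_patients(self):
        t = [3.8, 1.1, 8.3, 4.1, 0.5, 5.3, 1.0, 2.0, 2.3, 0.1]
        e = [1, 0, 0, 1, 1, 0, 0, 1, 1, 1]
        g = np.array([0] * 5 + [1] * 5)
        res = logrank_test(t, e, g)
        prng = np.random.default_rng(5)
        B = 20_000
        obs = res.chi_square
        hits = sum(
            logrank_test(t, e, prng.permutation(g)).chi_square >= obs - 1e-12 for _ in range(B)
        )
        assert abs(hits / B - res.p) < 0.02

    def test_three_group_sign(self):
        # group 0's events all precede the others' -> observed > expected there
        t = [1, 2, 3, 10, 11, 12, 13, 14, 15]
        e = [1, 1, 1, 1, 1, 0, 1, 1, 0]
        g = [0, 0, 0, 1, 1, 1, 2, 2, 2]
        res = logrank_test(t, e, g)
        assert res.observed[0] - res.expected[0] > 0

    def test_single_group_error(self):
        with pytest.raises(ValueError, match="two groups"):
            logrank_test([1, 2], [1, 1], [0, 0])

    def test_null_p_uniform(self):
        # rejection rate at alpha = 0.05 over 1000 null two-group datasets
        rng = np.random.default_rng(2024)
        rejections = 0
        for _ in range(1000):
            t = rng.exponential(1.0, 60)
            e = (rng.random(60) < 0.7).astype(int)
            g = rng.integers(0, 2, 60)
            if len(np.unique(g)) < 2:
                continue
            rejections += logrank_test(t, e, g).p < 0.05
        assert abs(rejections / 1000 - 0.05) < 0.02


# ---------------------------------------------------------------------------
# Cox
# ---------------------------------------------------------------------------


class TestCox:
    def test_no_effect_symmetry(self):
        # both covariate levels have identical event patterns
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 1, 0, 1, 1, 1, 0, 1]
        x = [0, 0, 0, 0, 1, 1, 1, 1]
        fit = cox_fit(t, e, np.asarray(x, float))
        assert abs(fit.coef[0]) < 1e-6
        assert fit.hr[0] == pytest.approx(1.0, abs=1e-6)

    def test_brute_force_likelihood_oracle_8_patients(self):
        t = [2.0, 3.1, 4.0, 4.0, 5.5, 6.1, 7.0, 9.3]
        e = [1, 0, 1, 1, 1, 0, 1, 1]
        x = [0.5, -1.2, 0.3, 1.7, -0.4, 0.9, -1.0, 0.2]
        fit = cox_fit(t, e, np.asarray(x, float))
        beta_star = golden_max(lambda b: efron_loglik(b, t, e, x), -5, 5)
        assert fit.coef[0] == pytest.approx(beta_star, abs=1e-4)
        assert fit.loglik == pytest.approx(efron_loglik(beta_star, t, e, x), abs=1e-6)

    def test_parameter_recovery_binary_covariate(self):
        rng = np.random.default_rng(17)
        n = 500
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(np.exp(0.8 * x))  # beta = -0.8 on the hazard scale
        e = np.ones(n)
        fit = cox_fit(t, e, x)
        assert abs(fit.coef[0] - (-0.8)) < 0.2

    def test_loglik_at_estimate_beats_null(self, rng):
        t = rng.exponential(1, 80)
        e = (rng.random(80) < 0.7).astype(int)
        x = rng.standard_normal(80)
        fit = cox_fit(t, e, x)
        assert fit.loglik >= fit.loglik_null

    def test_ci_brackets_hr(self, rng):
        t = rng.exponential(1, 100)
        e = np.ones(100)
        x = rng.standard_normal((100, 2))
        fit = cox_fit(t, e, x)
        assert np.all(fit.ci_low < fit.hr)
        assert np.all(fit.hr < fit.ci_high)
        assert np.all(fit.hr > 0)

    def test_score_test_equals_logrank_untied(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(1, 60)  # continuous -> untied a.s.
        e = (rng.random(60) < 0.8).astype(int)
        x = (rng.random(60) < 0.5).astype(float)
        lr = logrank_test(t, e, x.astype(int))
        fit = cox_fit(t, e, x, ties="breslow")
        assert fit.score_chi2 == pytest.approx(lr.chi_square, abs=1e-6)

    def test_hr_invariant_to_time_scaling(self, rng):
        t = rng.exponential(1, 120)
        e = (rng.random(120) < 0.7).astype(int)
        x = rng.standard_normal(120)
        f1 = cox_fit(t, e, x)
        f2 = cox_fit(t * 7.3, e, x)
        np.testing.assert_allclose(f1.hr, f2.hr, rtol=1e-8)

    def test_constant_covariate_error(self):
        with pytest.raises(ConstantCovariateError, match="flat"):
            cox_fit([1, 2, 3, 4], [1, 1, 1, 1], np.ones((4, 1)), names=["flat"])

    def test_separation_flags_nonconvergence(self):
        # perfect separation: all x=1 die first -> monotone likelihood
        t = [1, 2, 3, 4, 10, 11, 12, 13]
        e = [1, 1, 1, 1, 1, 1, 1, 1]
        x = np.array([1, 1, 1, 1, 0, 0, 0, 0], float)
        with pytest.warns(RuntimeWarning, match="converge"):
            fit = cox_fit(t, e, x)
        assert not fit.converged

    def test_n_le_p_error(self):
        with pytest.raises(ValueError, match="more observations"):
            cox_fit([1, 2], [1, 1], np.eye(2))

    def test_breslow_matches_efron_without_ties(self, rng):
        t = rng.exponential(1, 50)
        e = (rng.random(50) < 0.7).astype(int)
        x = rng.standard_normal(50)
        f1 = cox_fit(t, e, x, ties="efron")
        f2 = cox_fit(t, e, x, ties="breslow")
        np.testing.assert_allclose(f1.coef, f2.coef, atol=1e-8)

    def test_lifelines_cross_check_with_ties(self):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        rng = np.random.default_rng(1)
        n = 150
        x = rng.standard_normal((n, 2))
        t = np.round(rng.exponential(np.exp(-0.5 * x[:, 0]), n), 1) + 0.05
        e = (rng.random(n) < 0.7).astype(int)
        fit = cox_fit(t, e, x)
        df = pd.DataFrame({"t": t, "e": e, "a": x[:, 0], "b": x[:, 1]})
        ll = lifelines.CoxPHFitter().fit(df, "t", "e")
        np.testing.assert_allclose(fit.coef, ll.params_.values, atol=1e-5)
        np.testing.assert_allclose(fit.se, ll.standard_errors_.values, atol=1e-5)


# ---------------------------------------------------------------------------
# Pearson
# ---------------------------------------------------------------------------


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        r, p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0)

    def test_perfect_negative(self):
        x = np.arange(5.0)
        r, _ = pearson_r(x, -x)
        assert r == pytest.approx(-1.0)

    def test_direct_formula_oracle(self, rng):
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        r, p = pearson_r(x, y)
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert r == pytest.approx(num / den, abs=1e-12)
        sp_r, sp_p = stats.pearsonr(x, y)
        assert r == pytest.approx(sp_r, abs=1e-12)
        assert p == pytest.approx(sp_p, abs=1e-10)

    def test_constant_vector_error(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_too_short_error(self):
        with pytest.raises(ValueError, match="3 pairs"):
            pearson_r([1, 2], [3, 4])


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------


class TestAUC:
    def test_perfect_separation(self):
        roc = auc_mann_whitney([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert roc.auc == 1.0

    def test_all_tied(self):
        roc = auc_mann_whitney([5, 5, 5, 5], [0, 1, 0, 1])
        assert roc.auc == 0.5

    def test_brute_force_pairwise_oracle(self, rng):
        s = np.round(rng.standard_normal(30), 1)  # rounding creates ties
        y = (rng.random(30) < 0.4).astype(int)
        if y.sum() in (0, 30):
            y[0] = 1 - y[0]
        roc = auc_mann_whitney(s, y)
        pos, neg = s[y == 1], s[y == 0]
        conc = sum((pi > ni) + 0.5 * (pi == ni) for pi in pos for ni in neg)
        assert roc.auc == pytest.approx(conc / (len(pos) * len(neg)), abs=1e-12)

    def test_sklearn_cross_check(self, rng):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        s = np.round(rng.standard_normal(100), 1)
        y = (rng.random(100) < 0.5).astype(int)
        roc = auc_mann_whitney(s, y)
        assert roc.auc == pytest.approx(sklearn_metrics.roc_auc_score(y, s), abs=1e-12)

    def test_operating_points_monotone(self, rng):
        s = rng.standard_normal(50)
        y = (rng.random(50) < 0.5).astype(int)
        roc = auc_mann_whitney(s, y)
        assert np.all(np.diff(roc.sensitivity) >= 0)
        assert np.all(np.diff(roc.specificity) <= 0)
        assert roc.sensitivity[0] == 0.0 and roc.sensitivity[-1] == 1.0

    def test_one_class_empty_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            auc_mann_whitney([1, 2, 3], [1, 1, 1])

    @given(
        st.lists(st.integers(-100, 100), min_size=6, max_size=40),
        st.integers(0, 2**32 - 1),
    )
    @settings(max_examples=40, deadline=None)
    def test_monotone_transform_invariance(self, scores, seed):
        # integer grid keeps ties exact under the transform (no float collapse)
        s = np.asarray(scores, dtype=float) / 2.0
        y = np.random.default_rng(seed).integers(0, 2, len(s))
        if y.sum() in (0, len(y)):
            y[0] = 1 - y[0]
        a1 = auc_mann_whitney(s, y).auc
        a2 = auc_mann_whitney(np.exp(s / 25.0), y).auc  # strictly monotone
        assert a1 == pytest.approx(a2, abs=1e-12)
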