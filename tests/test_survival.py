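"""Survival machinery: product-limit estimates against hand computations,
log-rank against hypergeometric summation, cut-point selection, and Cox
fits against closed forms and a brute-force partial-likelihood oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import optimize

import centrosurv as cs
from centrosurv.survival import (
    MonotoneLikelihoodError,
    _cox_blocks,
    _cox_ll_grad_info,
)


class TestKaplanMeier:
    def test_hand_product_limit(self):
        km = cs.km_estimate([1, 2, 3, 4], [1, 0, 1, 1])
        np.testing.assert_allclose(km.event_times, [1, 3, 4])
        np.testing.assert_allclose(km.survival_prob, [0.75, 0.375, 0.0])

    def test_all_censored_flat_at_one(self):
        km = cs.km_estimate([3, 1, 5], [0, 0, 0])
        assert km.event_times.size == 0
        assert km.survival_at(10.0) == 1.0

    def test_single_event_steps_to_zero(self):
        km = cs.km_estimate([5], [1])
        assert km.survival_at(4.9) == 1.0
        assert km.survival_at(5.0) == 0.0

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            cs.km_estimate([-1, 2], [1, 1])

    @given(st.lists(st.floats(0.1, 50), min_size=1, max_size=30, unique=True))
    def test_no_censoring_matches_empirical_fraction(self, times):
        km = cs.km_estimate(times, np.ones(len(times)))
        t = np.asarray(times)
        for at in km.event_times:
            assert km.survival_at(at) == pytest.approx((t > at).mean())

    def test_survival_nonincreasing(self, rng):
        t = rng.exponential(10, 200)
        e = (rng.uniform(size=200) < 0.6).astype(int)
        km = cs.km_estimate(t, e)
        assert np.all(np.diff(km.survival_prob) <= 1e-12)

    def test_estimator_wrapper(self):
        est = cs.KaplanMeier().fit(y=([1, 2, 3, 4], [1, 0, 1, 1]))
        np.testing.assert_allclose(est.predict([1, 3, 4]), [0.75, 0.375, 0.0])


class TestLogRank:
    def test_hand_hypergeometric_example(self):
        # group A events at 1, 2; group B at 3, 4; no censoring
        res = cs.logrank_test([1, 2, 3, 4], [1, 1, 1, 1], [0, 0, 1, 1])
        assert res.chi2 == pytest.approx(49 / 17)
        np.testing.assert_allclose(res.observed, [2, 2])
        assert res.variance == pytest.approx(0.25 + 2 / 9)

    def test_identical_groups_null(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [1, 0, 1, 1, 0, 1]
        res = cs.logrank_test(t, e, [0, 0, 0, 1, 1, 1])
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_symmetric_in_group_labels(self, rng):
        t = rng.exponential(5, 60)
        e = (rng.uniform(size=60) < 0.7).astype(int)
        g = (rng.uniform(size=60) < 0.5).astype(int)
        a = cs.logrank_test(t, e, g)
        b = cs.logrank_test(t, e, 1 - g)
        assert a.chi2 == pytest.approx(b.chi2)
        assert a.p_value == pytest.approx(b.p_value)

    def test_invariant_to_monotone_time_transform(self, rng):
        t = rng.exponential(5, 60)
        e = (rng.uniform(size=60) < 0.7).astype(int)
        g = (rng.uniform(size=60) < 0.5).astype(int)
        a = cs.logrank_test(t, e, g)
        b = cs.logrank_test(np.exp(t / 10), e, g)
        assert a.chi2 == pytest.approx(b.chi2)

    def test_one_group_empty_fails(self):
        with pytest.raises(ValueError, match="2 non-empty groups"):
            cs.logrank_test([1, 2], [1, 1], [0, 0])


class TestOptimalCutpoint:
    def test_recovers_true_changepoint(self):
        """Marker 1..8 with an 8-fold hazard jump at >= 5 (n = 200)."""
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            m = r.choice(np.arange(1, 9, dtype=float), size=200)
            haz = np.where(m >= 5, 0.64, 0.08)
            t = r.exponential(1 / haz)
            cp = cs.optimal_cutpoint(m, t, np.ones(200))
            hits += 4 < cp.threshold < 5
        assert hits >= 18

    def test_constant_marker_fails(self):
        with pytest.raises(ValueError, match="constant marker"):
            cs.optimal_cutpoint(np.ones(30), np.arange(1, 31), np.ones(30))

    def test_min_group_frac_unsatisfiable(self):
        m = np.r_[np.zeros(29), 1.0]   # only a 1/30 split available
        with pytest.raises(ValueError, match="group-size"):
            cs.optimal_cutpoint(m, np.arange(1, 31), np.ones(30),
                                min_group_frac=0.2)

    def test_max_chi2_bounds_median_split(self, rng):
        m = rng.normal(size=100)
        t = rng.exponential(10, 100)
        e = (rng.uniform(size=100) < 0.6).astype(int)
        cp = cs.optimal_cutpoint(m, t, e)
        med = cs.logrank_test(t, e, (m > np.median(m)).astype(int))
        assert cp.chi2_max >= med.chi2 - 1e-12
        assert cp.chi2_max == pytest.approx(cp.scan_table["chi2"].max())

    def test_group_sizes_respect_constraint(self, rng):
        m = rng.normal(size=80)
        t = rng.exponential(10, 80)
        e = np.ones(80)
        cp = cs.optimal_cutpoint(m, t, e, min_group_frac=0.25)
        assert min(cp.n_low, cp.n_high) >= 20
        assert cp.n_low + cp.n_high == 80

    def test_permutation_p_deterministic_under_seed(self, rng):
        m = rng.normal(size=60)
        t = rng.exponential(10, 60)
        e = (rng.uniform(size=60) < 0.5).astype(int)
        a = cs.optimal_cutpoint(m, t, e, n_permutations=99, seed=5)
        b = cs.optimal_cutpoint(m, t, e, n_permutations=99, seed=5)
        assert a.p_adjusted == b.p_adjusted


def _brute_force_beta(x, time, event, ties="efron"):
    """Independent oracle: numerically maximize the partial likelihood."""
    xs, ts, es = _cox_blocks(x[:, None].astype(float),
                             np.asarray(time, float), np.asarray(event, float))

    def negll(b):
        ll, _, _ = _cox_ll_grad_info(np.array([b]), xs, ts, es, ties)
        return -ll

    res = optimize.minimize_scalar(negll, bounds=(-10, 10), method="bounded",
                                   options={"xatol": 1e-10})
    return res.x


class TestCoxPH:
    def test_closed_form_interleaved_events(self):
        # score equation reduces to u^2 - u - 4 = 0 with u = exp(beta)
        fit = cs.cox_fit(np.array([1.0, 0.0, 1.0, 0.0])[:, None],
                         [1, 2, 3, 4], [1, 1, 1, 1])
        expected = np.log((1 + np.sqrt(17)) / 2)
        assert fit.coef[0] == pytest.approx(expected, abs=1e-6)
        assert fit.hazard_ratios[0] == pytest.approx(np.exp(expected), rel=1e-6)

    def test_matches_grid_search_oracle(self, rng):
        for _ in range(5):
            n = 30
            x = rng.standard_normal(n)
            t = rng.exponential(1 / (0.1 * np.exp(0.6 * x)))
            e = (rng.uniform(size=n) < 0.8).astype(int)
            fit = cs.CoxPH(tol=1e-12).fit(x[:, None], (t, e))
            assert fit.coef_[0] == pytest.approx(
                _brute_force_beta(x, t, e), abs=1e-6)

    def test_perfect_separation_raises(self):
        with pytest.raises(MonotoneLikelihoodError):
            cs.cox_fit(np.array([1.0, 1.0, 0.0, 0.0])[:, None],
                       [1, 2, 3, 4], [1, 1, 1, 1])

    def test_loglik_nondecreasing_over_iterations(self, rng):
        x = rng.standard_normal((80, 2))
        t = rng.exponential(1 / (0.1 * np.exp(x @ [0.5, -0.5])))
        e = (rng.uniform(size=80) < 0.7).astype(int)
        est = cs.CoxPH().fit(x, (t, e))
        assert np.all(np.diff(est.loglik_path_) >= -1e-10)
        assert est.converged_

    def test_efron_equals_breslow_without_ties(self, rng):
        x = rng.standard_normal(40)
        t = rng.permutation(np.arange(1.0, 41.0))   # distinct times
        e = (rng.uniform(size=40) < 0.7).astype(int)
        a = cs.cox_fit(x[:, None], t, e, ties="efron")
        b = cs.cox_fit(x[:, None], t, e, ties="breslow")
        assert a.coef[0] == pytest.approx(b.coef[0], abs=1e-8)

    def test_ci_brackets_hr(self, rng):
        x = rng.standard_normal(60)
        t = rng.exponential(1 / (0.1 * np.exp(0.4 * x)))
        e = np.ones(60)
        fit = cs.cox_fit(x[:, None], t, e)
        assert fit.ci_lower[0] < fit.hazard_ratios[0] < fit.ci_upper[0]

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cs.cox_fit(np.ones((10, 1)), np.arange(1, 11), np.ones(10))

    def test_more_covariates_than_samples_rejected(self):
        with pytest.raises(ValueError, match="n > p"):
            cs.cox_fit(np.eye(3), [1, 2, 3], [1, 1, 1])


class TestStratifiedAnalysis:
    def test_site_filter_bookkeeping(self, small_cohort):
        n_primary = (small_cohort.clinical["site"] == "primary").sum()
        res = cs.stratified_survival_analysis(
            small_cohort.expression, small_cohort.clinical,
            filters={"site": "primary"})
        assert res.n == n_primary
        assert res.filters == {"site": "primary"}

    def test_univariate_and_multivariate_reported(self, small_cohort):
        res = cs.stratified_survival_analysis(
            small_cohort.expression, small_cohort.clinical)
        assert res.cox_univariate.hazard_ratios[0] > 0
        assert res.cox_multivariate is not None
        assert res.cox_multivariate.names == ["KIFC1_high", "grade", "stage"]
        # high-expression KM curve should carry the selected split sizes
        assert res.km_high.n == res.cutpoint.n_high
        assert res.km_low.n == res.cutpoint.n_low

    def test_absent_gene_fails(self, small_cohort):
        with pytest.raises(KeyError, match="NOPE"):
            cs.stratified_survival_analysis(
                small_cohort.expression, small_cohort.clinical, gene="NOPE")

    def test_overfiltered_cohort_fails(self, small_cohort):
        clin = small_cohort.clinical.copy()
        clin["site"] = "primary"
        clin.loc[clin.index[:110], "site"] = "metastatic"
        with pytest.raises(ValueError, match="< 20"):
            cs.stratified_survival_analysis(
                small_cohort.expression, clin, filters={"site": "primary"})
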