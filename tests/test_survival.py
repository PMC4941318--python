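"""Survival primitives: partial likelihood, Cox fitting, screening,
Kaplan-Meier and the log-rank test — checked against closed forms, hand
computations, brute-force oracles and lifelines."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aptrisk.survival import (CoxData, SurvivalOutcome, cox_fit,
                              cox_partial_loglik, km_estimate, logrank_test,
                              univariate_screen)
from conftest import simulate_outcome


class TestPartialLoglik:
    def test_zero_beta_closed_form(self):
        """At beta = 0 with distinct event times the partial log-likelihood
        is minus the sum of log risk-set sizes over events."""
        time = np.array([3.0, 1.0, 4.0, 2.0, 5.0])
        event = np.array([1, 0, 1, 1, 0])
        out = SurvivalOutcome(time, event)
        x = np.zeros((5, 1))
        ll = cox_partial_loglik(x, np.array([0.0]), out)
        # events at t=2 (risk 4), t=3 (risk 3), t=4 (risk 2)
        expected = -(np.log(4) + np.log(3) + np.log(2))
        assert ll == pytest.approx(expected, abs=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_zero_beta_closed_form_random(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(3, 30))
        time = r.uniform(0.5, 20, n)
        event = r.integers(0, 2, n)
        if event.sum() == 0:
            event[0] = 1
        out = SurvivalOutcome(time, event)
        ll = cox_partial_loglik(np.zeros((n, 1)), np.zeros(1), out)
        order = np.argsort(time)
        expected = -sum(np.log(np.sum(time >= time[i]))
                        for i in order if event[i])
        assert ll == pytest.approx(expected, abs=1e-9)

    def test_three_subject_hand_value(self):
        """1 covariate, 3 subjects, events at t=1 and t=3."""
        out = SurvivalOutcome(np.array([1.0, 2.0, 3.0]), np.array([1, 0, 1]))
        x = np.array([[1.0], [0.0], [-1.0]])
        beta = 0.7
        ll = cox_partial_loglik(x, np.array([beta]), out)
        hand = (beta - np.log(np.exp(beta) + 1 + np.exp(-beta))) \
            + (-beta - np.log(np.exp(-beta)))
        assert ll == pytest.approx(hand, abs=1e-12)

    def test_breslow_equals_efron_without_ties(self, medium_cox_data):
        x, out = medium_cox_data
        beta = np.array([0.4, -0.2])
        lb = cox_partial_loglik(x, beta, out, ties="breslow")
        le = cox_partial_loglik(x, beta, out, ties="efron")
        assert lb == pytest.approx(le, abs=1e-12)

    def test_nonfinite_covariates_rejected(self, medium_cox_data):
        x, out = medium_cox_data
        bad = x.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            cox_partial_loglik(bad, np.zeros(2), out)


class TestCoxFit:
    def test_matches_grid_search_oracle(self):
        """Single binary covariate: Newton solution vs two-stage grid
        maximization of an independently coded partial likelihood."""
        time = np.array([2.0, 5.0, 1.0, 7.0, 4.0, 9.0, 3.0, 8.0])
        event = np.array([1, 1, 1, 0, 1, 0, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 1.0, 0.0, 0.0])
        out = SurvivalOutcome(time, event)

        def hand_loglik(b):
            order = np.argsort(time)
            ll = 0.0
            for i in order:
                if event[i]:
                    risk = time >= time[i]
                    ll += b * x[i] - np.log(np.sum(np.exp(b * x[risk])))
            return ll

        grid = np.linspace(-4, 4, 2001)
        vals = [hand_loglik(b) for b in grid]
        b0 = grid[int(np.argmax(vals))]
        fine = np.arange(b0 - 0.01, b0 + 0.01, 1e-6)
        b_star = fine[int(np.argmax([hand_loglik(b) for b in fine]))]

        fit = cox_fit(x[:, None], out)
        assert fit.converged
        assert fit.coefficients[0] == pytest.approx(b_star, abs=1e-5)

    def test_matches_lifelines(self, medium_cox_data):
        from lifelines import CoxPHFitter
        x, out = medium_cox_data
        fit = cox_fit(x, out)
        df = pd.DataFrame({"t": out.time, "e": out.event,
                           "x0": x[:, 0], "x1": x[:, 1]})
        cph = CoxPHFitter().fit(df, "t", "e")
        assert np.allclose(fit.coefficients, cph.params_.values, atol=1e-4)
        assert np.allclose(fit.se, cph.standard_errors_.values, atol=1e-4)
        assert fit.loglik == pytest.approx(cph.log_likelihood_, abs=1e-5)

    def test_matches_lifelines_with_ties(self, medium_cox_data):
        from lifelines import CoxPHFitter
        x, out = medium_cox_data
        tied = SurvivalOutcome(np.ceil(out.time), out.event)
        fit = cox_fit(x, tied, ties="efron")
        df = pd.DataFrame({"t": tied.time, "e": tied.event,
                           "x0": x[:, 0], "x1": x[:, 1]})
        cph = CoxPHFitter().fit(df, "t", "e")
        assert np.allclose(fit.coefficients, cph.params_.values, atol=1e-3)

    def test_duplicating_subjects_preserves_coefficient_breslow(self,
                                                                medium_cox_data):
        x, out = medium_cox_data
        fit1 = cox_fit(x, out, ties="breslow")
        out2 = SurvivalOutcome(np.r_[out.time, out.time],
                               np.r_[out.event, out.event])
        fit2 = cox_fit(np.r_[x, x], out2, ties="breslow")
        assert np.allclose(fit1.coefficients, fit2.coefficients, atol=1e-6)

    def test_null_covariate_gives_small_coefficient(self):
        r = np.random.default_rng(2)
        x = r.standard_normal((500, 1))
        out = simulate_outcome(500, r, np.array([0.0]), x[:, 0],
                               rate=0.05, cens_lo=5, cens_hi=40)
        fit = cox_fit(x, out)
        assert abs(fit.coefficients[0]) < 3 / np.sqrt(out.n_events)

    def test_gradient_small_at_convergence(self, medium_cox_data):
        x, out = medium_cox_data
        fit = cox_fit(x, out)
        cd = CoxData(out)
        _, g = cd.loglik_grad(cd.sort_rows(x), fit.coefficients)
        assert np.max(np.abs(g)) < 1e-6

    def test_constant_covariate_rejected(self, medium_cox_data):
        x, out = medium_cox_data
        bad = np.c_[x, np.ones(x.shape[0])]
        with pytest.raises(ValueError, match="constant"):
            cox_fit(bad, out)

    def test_separation_flagged_not_fatal(self):
        time = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        event = np.array([1, 1, 1, 0, 0, 0])
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        out = SurvivalOutcome(time, event)
        with pytest.warns(UserWarning, match="converge|separation"):
            fit = cox_fit(x[:, None], out, max_iter=25)
        assert not fit.converged


class TestUnivariateScreen:
    def test_matches_per_feature_cox_fit(self, medium_cox_data):
        x, out = medium_cox_data
        r = np.random.default_rng(3)
        mat = pd.DataFrame(r.standard_normal((6, out.n)),
                           index=[f"f{i}" for i in range(6)])
        res = univariate_screen(mat, out, alpha=0.5)
        for i, fid in enumerate(mat.index):
            single = cox_fit(mat.loc[fid].to_numpy()[:, None], out)
            assert res.table.loc[fid, "coef"] == pytest.approx(
                single.coefficients[0], abs=1e-5)
            assert res.table.loc[fid, "p"] == pytest.approx(
                single.p_values[0], abs=1e-5)

    def test_strict_inequality_at_alpha(self, medium_cox_data):
        x, out = medium_cox_data
        r = np.random.default_rng(4)
        mat = pd.DataFrame(r.standard_normal((10, out.n)))
        res = univariate_screen(mat, out, alpha=0.3)
        assert set(res.selected_ids) == set(
            res.table.index[res.table["p"] < 0.3])

    def test_constant_feature_gets_p_one(self, medium_cox_data):
        x, out = medium_cox_data
        mat = pd.DataFrame(np.ones((2, out.n)))
        mat.iloc[1] = np.linspace(-1, 1, out.n)
        res = univariate_screen(mat, out, alpha=0.9)
        assert res.table["p"].iloc[0] == 1.0

    def test_null_type_one_calibration(self):
        """Fraction of null features passing the screen tracks alpha."""
        r = np.random.default_rng(5)
        n, p, alpha = 150, 400, 0.05
        x = r.standard_normal((n, 1))
        out = simulate_outcome(n, r, np.array([0.0]), x[:, 0],
                               rate=0.05, cens_lo=5, cens_hi=40)
        mat = pd.DataFrame(r.standard_normal((p, n)))
        res = univariate_screen(mat, out, alpha=alpha)
        frac = len(res.selected_ids) / p
        se = np.sqrt(alpha * (1 - alpha) / p)
        assert abs(frac - alpha) < 3 * se + 0.01

    def test_strong_feature_detected(self):
        r = np.random.default_rng(6)
        n = 200
        z = r.standard_normal(n)
        out = simulate_outcome(n, r, np.array([1.2]), z,
                               rate=0.03, cens_lo=10, cens_hi=60)
        mat = pd.DataFrame(np.vstack([z, r.standard_normal(n)]),
                           index=["true", "noise"])
        res = univariate_screen(mat, out, alpha=0.01)
        assert "true" in res.selected_ids

    def test_missing_values_rejected(self, medium_cox_data):
        x, out = medium_cox_data
        mat = pd.DataFrame(np.full((2, out.n), np.nan))
        with pytest.raises(ValueError, match="missing"):
            univariate_screen(mat, out)


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        out = SurvivalOutcome(np.array([1.0, 2.0, 3.0]), np.array([0, 0, 0]))
        km = km_estimate(out)
        assert km.survival_at(100.0) == 1.0

    def test_hand_product_limit(self):
        """times (2, 4+, 5): S = 2/3 on [2,5), 0 afterwards."""
        out = SurvivalOutcome(np.array([2.0, 4.0, 5.0]), np.array([1, 0, 1]))
        km = km_estimate(out)
        assert km.survival_at(1.9) == pytest.approx(1.0)
        assert km.survival_at(2.0) == pytest.approx(2 / 3, abs=1e-12)
        assert km.survival_at(4.5) == pytest.approx(2 / 3, abs=1e-12)
        assert km.survival_at(5.0) == pytest.approx(0.0, abs=1e-12)

    def test_matches_lifelines(self, medium_cox_data):
        from lifelines import KaplanMeierFitter
        _, out = medium_cox_data
        tied = SurvivalOutcome(np.ceil(out.time), out.event)
        km = km_estimate(tied)
        kmf = KaplanMeierFitter().fit(tied.time, tied.event)
        for t in (2.0, 5.0, 10.0, 20.0):
            assert km.survival_at(t) == pytest.approx(float(kmf.predict(t)),
                                                      abs=1e-10)

    def test_monotone_nonincreasing(self, medium_cox_data):
        _, out = medium_cox_data
        km = km_estimate(out)
        assert np.all(np.diff(km.surv) <= 1e-15)
        assert np.all((km.surv >= -1e-15) & (km.surv <= 1 + 1e-15))

    def test_groups(self, medium_cox_data):
        x, out = medium_cox_data
        g = np.where(x[:, 0] > 0, "hi", "lo")
        curves = km_estimate(out, g)
        assert set(curves) == {"hi", "lo"}


class TestLogrank:
    def test_identical_groups_give_zero(self):
        time = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        event = np.array([1, 0, 1, 1, 0, 1])
        out = SurvivalOutcome(time, event)
        res = logrank_test(out, np.array(list("aaabbb")))
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_six_subject_hand_computation(self):
        """All events, distinct times: the hypergeometric (O-E)^2/V sum is
        computed independently with an explicit loop."""
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.ones(6, dtype=int)
        groups = np.array([0, 0, 0, 1, 1, 1])
        out = SurvivalOutcome(time, event)
        o_minus_e = 0.0
        v = 0.0
        for i in range(6):
            at_risk = time >= time[i]
            n_tot = at_risk.sum()
            n_1 = (at_risk & (groups == 1)).sum()
            o_minus_e += (groups[i] == 1) - n_1 / n_tot
            if n_tot > 1:
                # d = 1 at each time, so V_i = (n1/n)(1 - n1/n)
                v += (n_1 / n_tot) * (1 - n_1 / n_tot)
        hand_chi = o_minus_e ** 2 / v
        res = logrank_test(out, groups)
        assert res.chi_square == pytest.approx(hand_chi, abs=1e-9)

    def test_matches_lifelines_with_ties_and_three_groups(self,
                                                          medium_cox_data):
        from lifelines.statistics import multivariate_logrank_test
        _, out = medium_cox_data
        r = np.random.default_rng(8)
        tied = SurvivalOutcome(np.ceil(out.time), out.event)
        g = r.integers(0, 3, out.n)
        res = logrank_test(tied, g)
        lt = multivariate_logrank_test(tied.time, g, tied.event)
        assert res.chi_square == pytest.approx(lt.test_statistic, abs=1e-8)
        assert res.p_value == pytest.approx(lt.p_value, abs=1e-8)

    def test_zero_events_gives_p_one(self):
        out = SurvivalOutcome(np.array([1.0, 2.0, 3.0, 4.0]),
                              np.array([0, 0, 0, 0]))
        res = logrank_test(out, np.array([0, 0, 1, 1]))
        assert res.p_value == 1.0

    def test_p_is_chi2_tail(self, medium_cox_data):
        from scipy import stats
        x, out = medium_cox_data
        g = np.where(x[:, 0] > 0.3, 1, 0)
        res = logrank_test(out, g)
        assert res.p_value == pytest.approx(stats.chi2.sf(res.chi_square, 1),
                                            abs=1e-14)

    def test_agrees_with_cox_score_test_binary_covariate(self,
                                                         medium_cox_data):
        """For a binary covariate without ties, the log-rank statistic equals
        the Cox partial-likelihood score test at beta = 0."""
        x, out = medium_cox_data
        g = (x[:, 0] > 0).astype(float)
        res = logrank_test(out, g.astype(int))
        cd = CoxData(out, ties="breslow")
        _, grad, info = cd.loglik_grad_info(cd.sort_rows(g[:, None]),
                                            np.zeros(1))
        score_stat = grad[0] ** 2 / info[0, 0]
        assert res.chi_square == pytest.approx(score_stat, rel=1e-9)

    def test_label_permutation_calibration(self):
        r = np.random.default_rng(9)
        n = 80
        out = simulate_outcome(n, r, np.array([0.0]), np.zeros(n),
                               rate=0.05, cens_lo=5, cens_hi=40)
        pvals = [logrank_test(out, r.permutation(np.r_[np.zeros(40),
                                                       np.ones(40)])).p_value
                 for _ in range(200)]
        from scipy import stats
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
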