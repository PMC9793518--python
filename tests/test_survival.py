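"""Survival statistics against independent oracles: exhaustive hypergeometric
sums, partial-likelihood grid search, O(n^2) pairwise C-index, lifelines."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from germtrace import survival as surv


# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------

class TestFisherExact:
    def test_printed_exclusion_table(self):
        assert surv.fisher_exact_2x2(9, 22, 5, 14) == pytest.approx(1.0)

    def test_symmetric_unit_table(self):
        assert surv.fisher_exact_2x2(1, 1, 1, 1) == pytest.approx(1.0)

    def test_extreme_table_enumeration_oracle(self):
        # margins force X in {0..10}; only X=10 and X=0 are as unlikely
        p = surv.fisher_exact_2x2(10, 0, 0, 10)
        from math import comb

        total = comb(20, 10)
        expected = (comb(10, 10) * comb(10, 0) + comb(10, 0) * comb(10, 10)) / total
        assert p == pytest.approx(expected, rel=1e-12)

    def test_exhaustive_against_scipy_small_tables(self):
        for a in range(0, 5):
            for b in range(0, 5):
                for c in range(0, 5):
                    for d in range(0, 5):
                        if min(a + b, c + d, a + c, b + d) == 0:
                            continue
                        ours = surv.fisher_exact_2x2(a, b, c, d)
                        ref = stats.fisher_exact([[a, b], [c, d]]).pvalue
                        assert ours == pytest.approx(ref, rel=1e-7), (a, b, c, d)

    def test_random_tables_up_to_n30(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(0, 9, size=4)
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            ours = surv.fisher_exact_2x2(int(a), int(b), int(c), int(d))
            ref = stats.fisher_exact([[a, b], [c, d]]).pvalue
            assert ours == pytest.approx(ref, rel=1e-7)

    def test_empty_margin_errors(self):
        with pytest.raises(ValueError):
            surv.fisher_exact_2x2(0, 0, 3, 4)


# ---------------------------------------------------------------------------
# Control weights
# ---------------------------------------------------------------------------

class TestControlWeight:
    def test_cohort_arithmetic(self):
        spec = surv.WeightSpec(n_cases=22, n_controls_sampled=14, incidence=0.15)
        assert spec.controls_needed == pytest.approx(22 * 0.85 / 0.15)
        assert surv.control_weight(spec) == pytest.approx(124.6666667 / 14, abs=1e-6)
        assert surv.control_weight(spec) == pytest.approx(8.904761905, abs=1e-6)

    def test_exact_sampling_weight_one(self):
        spec = surv.WeightSpec(n_cases=15, n_controls_sampled=85, incidence=0.15)
        assert surv.control_weight(spec) == pytest.approx(1.0)

    def test_half_incidence_equal_counts(self):
        spec = surv.WeightSpec(n_cases=30, n_controls_sampled=30, incidence=0.5)
        assert surv.control_weight(spec) == pytest.approx(1.0)

    def test_oversampled_warns_and_weight_below_one(self, caplog):
        import logging

        spec = surv.WeightSpec(n_cases=10, n_controls_sampled=100, incidence=0.5)
        with caplog.at_level(logging.WARNING, logger="germtrace"):
            w = surv.control_weight(spec)
        assert w < 1.0
        assert "more controls" in caplog.text

    def test_cohort_weights_vector(self):
        events = np.array([True] * 22 + [False] * 14)
        w = surv.cohort_weights(events, 0.15)
        assert np.all(w[:22] == 1.0)
        assert w[22] == pytest.approx(8.904761905, abs=1e-6)


# ---------------------------------------------------------------------------
# Weighted Cox: oracles
# ---------------------------------------------------------------------------

def _grid_search_beta(times, events, x, lo=-5.0, hi=5.0, step=1e-4):
    """Independent maximizer: dense grid over the Breslow partial likelihood."""
    betas = np.arange(lo, hi + step / 2, step)
    order = np.argsort(-times, kind="stable")
    t, d, xs = times[order], events[order], x[order]
    E = np.exp(np.outer(xs, betas))  # n x B
    S0 = np.cumsum(E, axis=0)
    ll = np.zeros_like(betas)
    i, n = 0, t.size
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        for k in range(i, j + 1):
            if d[k]:
                ll += xs[k] * betas - np.log(S0[j])
        i = j + 1
    return betas[np.argmax(ll)]


class TestWeightedCox:
    def test_symmetric_risk_sets_beta_zero(self):
        times = np.array([1.0, 2.0, 1.0, 2.0])
        events = np.array([True, True, True, True])
        x = np.array([[0.0], [0.0], [1.0], [1.0]])
        fit = surv.fit_weighted_cox(times, events, x)
        assert fit.coef[0] == pytest.approx(0.0, abs=1e-8)

    def test_grid_search_oracle_12_subjects(self, rng):
        n = 12
        x = rng.standard_normal(n)
        times = rng.exponential(1.0 / np.exp(0.8 * x))
        events = np.ones(n, dtype=bool)
        fit = surv.fit_weighted_cox(times, events, x[:, None])
        beta_grid = _grid_search_beta(times, events, x)
        assert abs(fit.coef[0] - beta_grid) < 1e-4

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_grid_search_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 31))
        x = rng.standard_normal(n)
        t = rng.exponential(1.0 / np.exp(0.5 * x))
        e = rng.random(n) < 0.8
        if e.sum() == 0:
            e[0] = True
        fit = surv.fit_weighted_cox(t, e, x[:, None])
        assert abs(fit.coef[0] - _grid_search_beta(t, e, x)) < 1e-4

    def test_against_lifelines_weighted_no_ties(self, rng):
        # lifelines handles ties by Efron, so the cross-check uses tie-free
        # data; tied data is checked against the Breslow grid-search oracle.
        import lifelines

        n = 200
        X = rng.standard_normal((n, 2))
        t = rng.exponential(1.0 / (0.2 * np.exp(X @ [0.6, -0.4])))
        e = rng.random(n) < 0.7
        w = rng.uniform(0.5, 5.0, n)
        fit = surv.fit_weighted_cox(t, e, X, w, ["a", "b"])
        df = pd.DataFrame({"t": t, "e": e, "a": X[:, 0], "b": X[:, 1], "w": w})
        cph = lifelines.CoxPHFitter().fit(
            df, "t", "e", weights_col="w", robust=True
        )
        np.testing.assert_allclose(fit.coef, cph.params_.values, atol=1e-5)
        np.testing.assert_allclose(
            fit.se_robust, cph.standard_errors_.values, rtol=1e-4
        )

    def test_breslow_ties_against_grid_search(self, rng):
        n = 40
        x = rng.standard_normal(n)
        t = np.ceil(rng.exponential(1.0 / np.exp(0.6 * x)) * 4)  # heavy ties
        e = rng.random(n) < 0.8
        if e.sum() == 0:
            e[0] = True
        fit = surv.fit_weighted_cox(t, e, x[:, None])
        assert abs(fit.coef[0] - _grid_search_beta(t, e, x)) < 1e-4

    def test_weight_scale_invariance(self, rng):
        n = 60
        x = rng.standard_normal((n, 1))
        t = rng.exponential(1.0, n)
        e = rng.random(n) < 0.7
        w = rng.uniform(1, 4, n)
        f1 = surv.fit_weighted_cox(t, e, x, w)
        f2 = surv.fit_weighted_cox(t, e, x, w * 7.5)
        np.testing.assert_allclose(f1.coef, f2.coef, atol=1e-8)

    def test_score_below_tol_at_fit(self, rng):
        n = 80
        x = rng.standard_normal((n, 2))
        t = rng.exponential(1.0, n)
        e = rng.random(n) < 0.6
        fit = surv.fit_weighted_cox(t, e, x, tol=1e-9)
        _, grad, _ = surv._breslow_loglik_grad_hess(
            fit.coef, t, e.astype(bool), x, np.ones(n)
        )
        assert np.max(np.abs(grad)) < 1e-9

    def test_no_events_errors(self):
        with pytest.raises(ValueError, match="no events"):
            surv.fit_weighted_cox(
                np.array([1.0, 2.0]), np.array([False, False]), np.array([[0.0], [1.0]])
            )

    def test_collinear_covariates_error(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([True, True, True, True])
        x = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0], [4.0, 8.0]])
        with pytest.raises(ValueError, match="singular"):
            surv.fit_weighted_cox(t, e, x)


class TestBaselineSurvival:
    def test_null_model_equals_nelson_aalen(self, rng):
        n = 40
        t = rng.exponential(3.0, n)
        e = rng.random(n) < 0.7
        if e.sum() < 2:
            e[:2] = True
        # single covariate with no effect: force beta ~ 0 via constant-ish x
        x = np.full((n, 1), 0.0)
        x[0, 0] = 1e-12
        fit = surv.fit_weighted_cox(t, e, x)
        ts, s = surv.baseline_survival(fit)
        # hand Nelson-Aalen
        H = 0.0
        expected = []
        for tk in ts:
            d = np.sum(e & (t == tk))
            at_risk = np.sum(t >= tk)
            H += d / at_risk
            expected.append(np.exp(-H))
        np.testing.assert_allclose(s, expected, atol=1e-10)

    def test_five_subject_hand_breslow(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        e = np.array([True, True, False, True, False])
        x = np.array([0.5, -0.5, 1.0, 0.0, -1.0])
        fit = surv.fit_weighted_cox(t, e, x[:, None])
        beta = fit.coef[0]
        xc = x - fit.x_reference[0]
        risk = np.exp(beta * xc)
        H = []
        acc = 0.0
        for tk, di in zip(t, e):
            if not di:
                continue
            acc += 1.0 / risk[t >= tk].sum()
            H.append(acc)
        np.testing.assert_allclose(fit.baseline_cumhaz, H, atol=1e-10)
        np.testing.assert_allclose(fit.baseline_times, t[e], atol=0)

    def test_higher_prs_lower_survival(self, rng):
        n = 300
        prs = rng.standard_normal(n)
        t = rng.exponential(1.0 / (0.1 * np.exp(0.7 * prs)))
        e = t < 10
        tt = np.minimum(t, 10)
        fit = surv.fit_weighted_cox(tt, e, prs[:, None], covariate_names=["PRS"])
        curves = surv.prs_percentile_curves(fit, "PRS", prs, percentiles=(10, 90))
        s10 = curves[curves.percentile == 10].survival.to_numpy()
        s90 = curves[curves.percentile == 90].survival.to_numpy()
        assert np.all(s90 <= s10 + 1e-12)
        assert s90.min() < s10.min()

    def test_non_converged_fit_errors(self, rng):
        fit = surv.fit_weighted_cox(
            np.array([1.0, 2.0, 3.0]),
            np.array([True, True, False]),
            np.array([[0.1], [0.2], [0.3]]),
        )
        fit.converged = False
        with pytest.raises(ValueError):
            surv.baseline_survival(fit)


class TestHarrellC:
    def test_perfect_discrimination(self):
        t = np.array([3.0, 1.0, 4.0, 2.0])
        e = np.ones(4, dtype=bool)
        assert surv.harrell_c(-t, t, e) == pytest.approx(1.0)

    def test_constant_predictor_half(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.ones(4, dtype=bool)
        assert surv.harrell_c(np.zeros(4), t, e) == pytest.approx(0.5)

    def test_random_fixture_against_pairwise_oracle(self, rng):
        n = 50
        lp = rng.standard_normal(n)
        t = rng.exponential(1.0, n)
        e = rng.random(n) < 0.6
        w = rng.uniform(0.5, 3.0, n)
        ours = surv.harrell_c(lp, t, e, w)
        num = den = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                comparable = e[i] and (t[i] < t[j] or (t[i] == t[j] and not e[j]))
                if not comparable:
                    continue
                pw = w[i] * w[j]
                den += pw
                if lp[i] > lp[j]:
                    num += pw
                elif lp[i] == lp[j]:
                    num += 0.5 * pw
        assert ours == pytest.approx(num / den, abs=1e-12)

    def test_no_events_errors(self):
        with pytest.raises(ValueError):
            surv.harrell_c(np.array([1.0, 2.0]), np.array([1.0, 2.0]), np.array([False, False]))


class TestPHCheck:
    def test_residuals_sum_to_zero_at_fit(self, rng):
        n = 100
        x = rng.standard_normal((n, 1))
        t = rng.exponential(1.0 / np.exp(0.5 * x[:, 0]))
        e = np.ones(n, dtype=bool)
        fit = surv.fit_weighted_cox(t, e, x)
        resid = surv.schoenfeld_residuals(fit)
        assert resid.iloc[:, 1].sum() == pytest.approx(0.0, abs=1e-6)

    def test_time_varying_effect_detected(self, rng):
        # effect switches off after t0: strong PH violation
        n = 1000
        x = rng.standard_normal(n)
        t0, rate = 1.0, 0.5
        t1 = rng.exponential(1.0 / (rate * np.exp(1.5 * x)))
        t2 = t0 + rng.exponential(1.0 / rate, n)
        t = np.where(t1 < t0, t1, t2)
        e = t < 8.0
        tt = np.minimum(t, 8.0)
        fit = surv.fit_weighted_cox(tt, e, x[:, None])
        ph = surv.ph_assumption_check(fit)
        assert ph.p.iloc[0] < 0.01

    def test_too_few_events_errors(self, rng):
        fit = surv.fit_weighted_cox(
            np.array([1.0, 2.0, 3.0]),
            np.array([True, False, False]),
            np.array([[0.3], [0.1], [0.2]]),
        )
        with pytest.raises(ValueError):
            surv.ph_assumption_check(fit)


class TestLiJiMeff:
    def test_independent_columns(self, rng):
        M = rng.standard_normal((50, 5))
        Q, _ = np.linalg.qr(M - M.mean(axis=0))  # exactly orthogonal columns
        res = surv.li_ji_meff(Q)
        assert res.m_eff == pytest.approx(5.0, abs=1e-9)

    def test_perfectly_correlated_columns(self, rng):
        v = rng.standard_normal(30)
        M = np.column_stack([v, 2 * v + 1, -v, 0.5 * v])
        res = surv.li_ji_meff(M)
        assert res.m_eff == pytest.approx(1.0, abs=1e-9)

    def test_two_columns_rho_half_closed_form(self, rng):
        u = rng.standard_normal(100)
        u = (u - u.mean()) / u.std()
        w = rng.standard_normal(100)
        w = w - u * (w @ u) / (u @ u)
        w = (w - w.mean()) / w.std()
        # re-orthogonalize after centering to make corr exactly 0.5
        w = w - u * (w @ u) / (u @ u)
        w /= w.std()
        v = 0.5 * u + np.sqrt(0.75) * w
        res = surv.li_ji_meff(np.column_stack([u, v]))
        np.testing.assert_allclose(sorted(res.eigenvalues), [0.5, 1.5], atol=1e-9)
        assert res.m_eff == pytest.approx(2.0, abs=1e-9)

    def test_meff_bounds(self, rng):
        M = rng.standard_normal((40, 6))
        M[:, 3] = M[:, 0] * 0.9 + 0.1 * M[:, 3]
        res = surv.li_ji_meff(M)
        assert 1.0 <= res.m_eff <= 6.0

    def test_q_values(self):
        res = surv.MeffResult(eigenvalues=np.array([1.0, 1.0]), m_eff=2.0)
        np.testing.assert_allclose(res.q_values([0.01, 0.9]), [0.02, 1.0])

    def test_constant_column_errors(self, rng):
        M = rng.standard_normal((20, 3))
        M[:, 1] = 4.2
        with pytest.raises(ValueError):
            surv.li_ji_meff(M)


class TestGroupComparison:
    def test_identical_distributions(self):
        prs = np.array([0.1, -0.5, 1.2, 0.1, -0.5, 1.2])
        flags = np.array([True, True, True, False, False, False])
        res = surv.prs_group_comparison(prs, flags)
        assert res["fold_change"] == pytest.approx(1.0)
        assert res["p_value"] > 0.9

    def test_shifted_groups_significant(self, rng):
        g0 = rng.standard_normal(200)
        g1 = rng.standard_normal(200) + 1.0
        prs = np.concatenate([g1, g0])
        flags = np.concatenate([np.ones(200, bool), np.zeros(200, bool)])
        res = surv.prs_group_comparison(prs, flags)
        assert res["p_value"] < 0.01

    def test_single_member_group_means_only(self):
        res = surv.prs_group_comparison(
            np.array([1.0, 0.2, 0.3]), np.array([True, False, False])
        )
        assert res["p_value"] is None
        assert res["mean_event"] == pytest.approx(1.0)


class TestBuildDesign:
    def test_missing_size_excluded_and_age_midpoint(self):
        from germtrace.types import CohortRecord

        cohort = [
            CohortRecord("P1", True, 100.0, 2, 1.5, "41-50", True, {"B": 0.5}),
            CohortRecord("P2", False, 200.0, 1, None, "51-60", False, {"B": -0.1}),
            CohortRecord("P3", False, 300.0, 3, 0.8, "71-80", True, {"B": 0.2}),
        ]
        times, events, design, names = surv.build_design(cohort, "B")
        assert len(times) == 2  # P2 dropped for missing size
        assert design.loc["P1", "age"] == pytest.approx(45.5)
        assert names[0] == "B"

    def test_missing_grade_raises_until_imputed(self):
        from germtrace.types import CohortRecord

        cohort = [CohortRecord("P1", True, 100.0, None, 1.0, "41-50", True, {"B": 0.0})]
        with pytest.raises(ValueError, match="grade"):
            surv.build_design(cohort, "B")
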