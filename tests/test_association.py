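"""Association layer: logistic fits, t-test, chi-square, KM/log-rank, Spearman."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from mimiscan.association import (arb_category_chisq, benjamini_hochberg,
                                  compare_group_means, fit_diagnosis_logistic,
                                  km_logrank, stratified_spearman)


class TestLogistic:
    def test_toy_fit_matches_direct_likelihood_optimizer(self):
        x = np.array([0.1, 0.5, 1.2, 2.0, 2.5, 3.1, 3.8, 4.4])
        y = np.array([0, 0, 0, 1, 0, 1, 1, 1], dtype=float)

        def nll(theta):
            eta = theta[0] + theta[1] * x
            p = expit(eta)
            return -np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))

        oracle = minimize(nll, x0=[0.0, 0.0], method="Nelder-Mead",
                          options={"xatol": 1e-10, "fatol": 1e-12,
                                   "maxiter": 10000})
        fit = fit_diagnosis_logistic(x, y)
        assert fit.converged
        assert fit.coefficient == pytest.approx(oracle.x[1], abs=1e-5)
        assert fit.odds_ratio == pytest.approx(math.exp(oracle.x[1]), rel=1e-4)

    def test_null_confidence_interval_calibration(self, rng):
        """Predictor independent of outcome: the 95% CI covers OR=1 ~95%."""
        cover = 0
        reps = 150
        for _ in range(reps):
            x = rng.normal(size=400)
            y = (rng.random(400) < 0.4).astype(float)
            fit = fit_diagnosis_logistic(x, y)
            lo, hi = fit.conf_int_or
            cover += lo <= 1.0 <= hi
        assert 0.90 <= cover / reps <= 0.99

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_diagnosis_logistic(np.ones(10),
                                   np.array([0, 1] * 5, dtype=float))

    def test_one_class_outcome_rejected(self):
        with pytest.raises(ValueError, match="case"):
            fit_diagnosis_logistic(np.arange(6), np.zeros(6))

    def test_separation_flagged_not_silent(self):
        x = np.array([0., 1, 2, 3, 10, 11, 12, 13])
        y = np.array([0., 0, 0, 0, 1, 1, 1, 1])
        fit = fit_diagnosis_logistic(x, y)
        assert fit.separation or not fit.converged


class TestTTest:
    def test_identical_groups_give_zero_statistic(self):
        a = [1.0, 2.0, 3.0]
        res = compare_group_means(a, a)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_three_vs_three(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 6.0])
        sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4  # pooled variance
        t_hand = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        res = compare_group_means(a, b)
        assert res.statistic == pytest.approx(t_hand)
        assert res.df == 4
        assert res.mean_diff == pytest.approx(-2.0)

    def test_swapping_groups_negates_t(self, rng):
        a, b = rng.normal(size=10), rng.normal(1.0, size=12)
        r1, r2 = compare_group_means(a, b), compare_group_means(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)


class TestChiSquare:
    def test_identical_row_distributions_independent(self):
        res = arb_category_chisq([[10, 20, 30], [20, 40, 60]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_2x2_closed_form(self):
        # chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), no correction
        a, b, c, d = 10, 20, 20, 10
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d))
        res = arb_category_chisq([[a, b], [c, d]])
        assert res.statistic == pytest.approx(expected)
        assert res.df == 1

    def test_df_for_3x4_table(self, rng):
        tab = rng.integers(5, 50, size=(3, 4))
        assert arb_category_chisq(tab).df == 6

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            arb_category_chisq([[0, 0], [5, 10]])


class TestSurvival:
    def test_identical_strata_give_zero_logrank(self):
        t = [3.0, 5.0, 7.0, 9.0]
        e = [1, 1, 0, 1]
        res = km_logrank(t + t, e + e, ["A"] * 4 + ["B"] * 4)
        assert res.logrank_statistic == pytest.approx(0.0, abs=1e-10)
        assert res.logrank_p == pytest.approx(1.0)

    def test_six_subject_hand_tabulation(self):
        """times 1..6, all events, strata ABABAB, checked by hand."""
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = [1] * 6
        strata = ["A", "B", "A", "B", "A", "B"]
        res = km_logrank(times, events, strata)
        # stratum A: deaths at 1, 3, 5 -> S = 2/3, 1/3, 0
        curve_a = res.curves["A"].set_index("time")["survival"]
        assert curve_a.loc[1.0] == pytest.approx(2 / 3)
        assert curve_a.loc[3.0] == pytest.approx(1 / 3)
        assert curve_a.loc[5.0] == pytest.approx(0.0)
        # hand log-rank: O_A = 3; E_A = sum over death times of n_A/n
        e_a = 3 / 6 + 3 / 5 + 2 / 4 + 2 / 3 + 1 / 2 + 1 / 1
        v = sum(
            (na / nn) * (1 - na / nn)
            for na, nn in [(3, 6), (3, 5), (2, 4), (2, 3), (1, 2), (1, 1)]
        )
        stat_hand = (3 - e_a) ** 2 / v
        assert res.logrank_statistic == pytest.approx(stat_hand, rel=1e-9)

    def test_km_without_censoring_is_empirical_survival(self, rng):
        t = rng.exponential(100.0, size=40)
        res = km_logrank(np.concatenate([t, t * 0.5]),
                         np.ones(80), ["A"] * 40 + ["B"] * 40)
        curve = res.curves["A"]
        st = np.sort(t)
        for k, time in enumerate(curve["time"]):
            assert curve["survival"].iloc[k] == pytest.approx(
                (st > time).mean(), abs=1e-12)

    def test_power_against_hazard_ratio_two(self, rng):
        hits = 0
        reps = 60
        for _ in range(reps):
            t1 = rng.exponential(1.0, size=200)
            t2 = rng.exponential(0.5, size=200)
            res = km_logrank(np.concatenate([t1, t2]), np.ones(400),
                             ["A"] * 200 + ["B"] * 200)
            hits += res.logrank_p < 0.05
        assert hits / reps >= 0.95

    def test_all_censored_warns_and_returns_zero(self, caplog):
        res = km_logrank([5.0, 6.0, 7.0, 8.0], [0, 0, 0, 0],
                         ["A", "A", "B", "B"])
        assert res.logrank_statistic == 0.0

    def test_missing_metadata_dropped_with_count(self):
        res = km_logrank([1.0, 2.0, np.nan, 4.0], [1, 1, 1, np.nan],
                         ["A", "B", "A", "B"])
        assert res.n_dropped == 2


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.arange(10.0)
        res = stratified_spearman(x, x ** 3, ["s"] * 10)
        assert res[0].rho == pytest.approx(1.0)
        res_rev = stratified_spearman(x, -x, ["s"] * 10)
        assert res_rev[0].rho == pytest.approx(-1.0)

    def test_seven_point_toy_matches_rank_formula(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0, 2.0])
        y = np.array([8.0, 6.0, 7.0, 5.0, 3.0, 0.0, 9.0])
        from scipy.stats import rankdata
        rx, ry = rankdata(x), rankdata(y)
        rho_hand = np.corrcoef(rx, ry)[0, 1]
        res = stratified_spearman(x, y, ["s"] * 7)
        assert res[0].rho == pytest.approx(rho_hand, abs=1e-12)

    def test_per_stratum_separation(self, rng):
        x = rng.normal(size=40)
        y = np.concatenate([x[:20] + rng.normal(0, 0.1, 20),
                            rng.normal(size=20)])
        strata = ["pos"] * 20 + ["neg"] * 20
        res = {r.stratum: r for r in stratified_spearman(x, y, strata)}
        assert res["pos"].rho > 0.8
        assert abs(res["neg"].rho) < 0.5

    def test_tiny_stratum_undefined(self):
        res = stratified_spearman([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0],
                                  ["a", "a", "a", "b"])
        by = {r.stratum: r for r in res}
        assert math.isnan(by["b"].rho)
        assert by["b"].n == 1


def test_benjamini_hochberg_orders_and_bounds():
    out = benjamini_hochberg([0.001, 0.02, 0.5, 0.04])
    assert (out["p_adjusted"] >= out["p"]).all()
    assert out.loc[0, "reject"]
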