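"""Kaplan–Meier, log-rank, Cox regression and concordance."""

import numpy as np
import pandas as pd
import pytest

from oncomodules.survival import (concordance_index, cox_fit, cox_reports,
                                  kaplan_meier, logrank_test)

from _oracles import brute_concordance


def records(times, events, ids=None):
    idx = ids or [f"p{i}" for i in range(len(times))]
    return pd.DataFrame({"time": times, "event": events}, index=idx)


class TestKaplanMeier:
    def test_hand_product_limit(self):
        table = kaplan_meier(records([1.0, 2.0, 3.0], [1, 0, 1]))
        s = dict(zip(table["time"], table["survival"]))
        assert s[1.0] == pytest.approx(2 / 3)
        assert s[3.0] == pytest.approx(0.0)

    def test_no_events_flat_curve(self):
        table = kaplan_meier(records([1.0, 2.0, 5.0], [0, 0, 0]))
        assert (table["survival"] == 1.0).all()

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(10, size=40).round(2)
        table = kaplan_meier(records(times, [1] * 40))
        for t, s in zip(table["time"], table["survival"]):
            ecdf = np.mean(times <= t)
            assert s == pytest.approx(1.0 - ecdf, abs=1e-12)

    def test_survival_nonincreasing(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(5, size=30)
        events = rng.integers(0, 2, size=30)
        events[0] = 1
        table = kaplan_meier(records(times, events))
        assert (np.diff(table["survival"]) <= 1e-12).all()

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier(records([0.0, 1.0], [1, 1]))


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        rec = records([1, 2, 3, 1, 2, 3.0], [1, 0, 1, 1, 0, 1])
        res = logrank_test(rec, np.array([0, 0, 0, 1, 1, 1]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("g", [2, 3, 5])
    def test_degrees_of_freedom(self, g):
        rng = np.random.default_rng(g)
        n = 20 * g
        rec = records(rng.exponential(5, n), rng.integers(0, 2, n))
        res = logrank_test(rec, np.repeat(np.arange(g), 20))
        assert res.df == g - 1

    def test_two_group_statistic_is_squared_standardized_score(self):
        """Internal consistency: chi-square equals (O-E)^2/V for g=2."""
        rng = np.random.default_rng(7)
        n = 60
        times = rng.exponential(5, n)
        events = np.ones(n, dtype=int)
        groups = rng.integers(0, 2, n)
        rec = records(times, events)
        res = logrank_test(rec, groups)
        # hand computation of the two-sample log-rank score
        order = np.argsort(times)
        t_sorted, g_sorted = times[order], groups[order]
        o_minus_e, var = 0.0, 0.0
        for t in np.unique(t_sorted):
            at_risk = t_sorted >= t
            d = np.sum(t_sorted == t)
            n_risk = at_risk.sum()
            n1 = np.sum(at_risk & (g_sorted == 1))
            d1 = np.sum((t_sorted == t) & (g_sorted == 1))
            o_minus_e += d1 - d * n1 / n_risk
            if n_risk > 1:
                var += (d * (n1 / n_risk) * (1 - n1 / n_risk)
                        * (n_risk - d) / (n_risk - 1))
        assert res.statistic == pytest.approx(o_minus_e ** 2 / var, rel=1e-6)

    def test_group_with_zero_events_handled(self):
        rec = records([1, 2, 3, 4.0], [1, 1, 0, 0])
        res = logrank_test(rec, np.array([0, 0, 1, 1]))
        assert np.isfinite(res.statistic)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(records([1.0], [1]), np.array([0]))


def simulate_cox(rng, n=500, beta=0.7, censor_frac=0.3):
    x = rng.integers(0, 2, size=n).astype(float)
    rate = 0.01 * np.exp(beta * x)
    death = rng.exponential(1.0 / rate)
    c = np.quantile(death, 1.0 - censor_frac) * 1.3
    censor = rng.uniform(0, c, size=n)
    time = np.minimum(death, censor)
    event = (death <= censor).astype(int)
    return pd.DataFrame({"x": x}), records(time, event)


class TestCox:
    def test_recovers_known_coefficient(self):
        rng = np.random.default_rng(11)
        X, rec = simulate_cox(rng)
        X.index = rec.index
        fit = cox_fit(X, rec)
        assert fit.coefficients["x"] == pytest.approx(0.7, abs=0.15)
        assert 0.0 <= fit.c_index <= 1.0

    def test_null_effect_converges_near_zero(self):
        rng = np.random.default_rng(12)
        X, rec = simulate_cox(rng, beta=0.0)
        X.index = rec.index
        fit = cox_fit(X, rec)
        assert abs(fit.coefficients["x"]) < 0.2
        assert not fit.summary["significant"].iloc[0] or \
            fit.summary["p"].iloc[0] > 0.001  # null rarely flags strongly

    def test_duplicated_dataset_same_coefficients(self):
        """Partial likelihood is essentially invariant to duplicating every
        subject (exactly invariant under Breslow ties; Efron's correction
        perturbs the duplicated-tie risk sets only slightly)."""
        rng = np.random.default_rng(13)
        X, rec = simulate_cox(rng, n=120)
        X.index = rec.index
        single = cox_fit(X, rec)
        X2 = pd.concat([X, X.set_index(X.index + "_b")])
        rec2 = pd.concat([rec, rec.set_index(rec.index + "_b")])
        double = cox_fit(X2, rec2)
        assert double.coefficients["x"] == pytest.approx(
            single.coefficients["x"], abs=0.02)

    def test_constant_column_rejected_by_name(self):
        rng = np.random.default_rng(14)
        X, rec = simulate_cox(rng, n=50)
        X.index = rec.index
        X["flat"] = 1.0
        with pytest.raises(ValueError, match="flat"):
            cox_fit(X, rec)

    def test_collinear_columns_rejected(self):
        rng = np.random.default_rng(15)
        X, rec = simulate_cox(rng, n=50)
        X.index = rec.index
        X["x2"] = 2.0 * X["x"]
        with pytest.raises(ValueError, match="collinear"):
            cox_fit(X, rec)

    def test_per_group_reports(self):
        rng = np.random.default_rng(16)
        X, rec = simulate_cox(rng, n=200)
        X.index = rec.index
        groups = pd.Series(rng.integers(1, 3, size=200), index=rec.index)
        reports = cox_reports(X, rec, groups=groups)
        assert "all" in reports
        assert {"group_1", "group_2"} <= set(reports)


class TestConcordance:
    def test_perfect_ranking(self):
        rec = records([5, 4, 3, 2, 1.0], [1] * 5)
        risk = np.array([1, 2, 3, 4, 5.0])  # highest risk dies first
        assert concordance_index(risk, rec) == 1.0

    def test_anti_ranking(self):
        rec = records([1, 2, 3, 4, 5.0], [1] * 5)
        risk = np.array([1, 2, 3, 4, 5.0])
        assert concordance_index(risk, rec) == 0.0

    def test_matches_exhaustive_pair_enumeration(self):
        rng = np.random.default_rng(17)
        n = 30
        times = rng.exponential(5, n).round(1)
        events = rng.integers(0, 2, n)
        events[:3] = 1
        risk = rng.normal(size=n).round(2)
        rec = records(times, events)
        assert concordance_index(risk, rec) == pytest.approx(
            brute_concordance(risk, times, events), abs=1e-12)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(18)
        n = 2000
        rec = records(rng.exponential(5, n), np.ones(n, dtype=int))
        c = concordance_index(rng.normal(size=n), rec)
        assert abs(c - 0.5) < 0.03

    def test_true_risk_beats_permuted(self, default_cohort):
        """The generating log-hazard out-ranks its permutation, per seed."""
        cohort = default_cohort
        truth = cohort.truth
        act = pd.DataFrame(truth["activation"]).T
        risk = act.to_numpy() @ np.asarray(truth["hazard_coefficients"])
        rec = cohort.survival.loc[act.index]
        c_true = concordance_index(risk, rec)
        rng = np.random.default_rng(19)
        c_perm = concordance_index(rng.permutation(risk), rec)
        assert c_true > c_perm
        assert c_true > 0.6
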