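"""Kaplan-Meier, log-rank, Cox and backward-conditional elimination."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from emtprog.dichotomize import logrank_uv
from emtprog.simulate import simulate_two_group_exponential
from emtprog.survival import (
    cox_backward_conditional,
    cox_fit,
    events_from_cause,
    five_year_os,
    km_curve,
    logrank_test,
    null_partial_log_likelihood,
    survival_at,
)


class TestKaplanMeier:
    def test_all_censored_curve_is_one(self):
        curve = km_curve([5.0, 10.0, 20.0], [False, False, False])
        assert survival_at(curve, 15.0) == 1.0
        assert five_year_os(curve) == 100.0

    def test_single_event_quarter_drop(self):
        curve = km_curve([5.0, 8.0, 9.0, 12.0], [True, False, False, False])
        assert survival_at(curve, 5.0) == pytest.approx(0.75)
        assert survival_at(curve, 4.999) == 1.0

    def test_equals_empirical_survival_without_censoring(self, rng):
        # brute-force counting oracle: S(t) = #(T > t) / n
        t = rng.exponential(30, 60)
        curve = km_curve(t, np.ones(60, bool))
        for tt in curve.event_times:
            assert survival_at(curve, tt) == pytest.approx((t > tt).mean())

    def test_time_rescaling_leaves_probabilities(self, rng):
        t = rng.exponential(30, 40)
        e = rng.random(40) < 0.7
        a = km_curve(t, e)
        b = km_curve(3.5 * t, e)
        assert np.allclose(a.survival_prob, b.survival_prob)
        assert np.allclose(3.5 * a.event_times, b.event_times)

    def test_five_year_os_exponential_closed_form(self):
        lam = 0.012
        df = simulate_two_group_exponential(20000, 0.0, 1.0,
                                            baseline_hazard=lam, seed=3)
        curve = km_curve(df["time_months"], df["event"])
        assert five_year_os(curve) == pytest.approx(100 * math.exp(-60 * lam), abs=1.5)

    def test_negative_time_rejected(self):
        curve = km_curve([5.0], [True])
        with pytest.raises(ValueError):
            survival_at(curve, -1.0)
        with pytest.raises(ValueError):
            km_curve([], [])


class TestLogrank:
    def test_duplicated_groups_give_zero(self, rng):
        t = np.tile(rng.exponential(30, 15), 2)
        e = np.tile(rng.random(15) < 0.8, 2)
        g = np.r_[np.zeros(15), np.ones(15)]
        assert logrank_test(t, e, g).chi2 == pytest.approx(0.0, abs=1e-10)

    def test_label_swap_invariance(self, rng):
        t = rng.exponential(30, 30)
        e = rng.random(30) < 0.8
        g = rng.random(30) < 0.4
        assert logrank_test(t, e, g).chi2 == pytest.approx(
            logrank_test(t, e, ~g).chi2
        )

    def test_matches_exhaustive_permutation_p(self, rng):
        # n = 12, 6 per arm: compare the chi-square p with the exact
        # permutation distribution of the statistic over all 924 splits
        t = rng.exponential(30, 12)
        e = np.ones(12, bool)
        g = np.zeros(12, bool)
        g[:6] = True
        obs = logrank_test(t, e, g)
        perm_stats = []
        for idx in itertools.combinations(range(12), 6):
            gp = np.zeros(12, bool)
            gp[list(idx)] = True
            perm_stats.append(logrank_test(t, e, gp).chi2)
        p_perm = np.mean(np.asarray(perm_stats) >= obs.chi2 - 1e-12)
        assert obs.p == pytest.approx(p_perm, abs=0.08)

    def test_consistent_with_cutpoint_statistic(self, rng):
        # two-group chi2 equals the square of the standardized statistic the
        # cutpoint scan maximises (cross-module consistency)
        t = rng.exponential(40, 50)
        e = rng.random(50) < 0.7
        g = rng.random(50) < 0.5
        u, v = logrank_uv(t, e, g)
        assert logrank_test(t, e, g).chi2 == pytest.approx(u * u / v, abs=1e-8)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [True, True], [0, 0])
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [False, False], [0, 1])


class TestCoxFit:
    def test_null_covariate_hr_near_one(self):
        df = simulate_two_group_exponential(4000, 0.5, 1.0, seed=11)
        fit = cox_fit(df[["high"]], df["time_months"], df["event"])
        s = fit.summary.iloc[0]
        assert abs(s["coef"]) < 3 * s["se"]
        assert s["ci_lower"] < 1.0 < s["ci_upper"]

    def test_flip_coding_inverts_hr(self):
        df = simulate_two_group_exponential(500, 0.4, 2.5, seed=5)
        fit = cox_fit(df[["high"]], df["time_months"], df["event"])
        flipped = (1 - df[["high"]]).rename(columns={"high": "low"})
        fit2 = cox_fit(flipped, df["time_months"], df["event"])
        assert fit2.hr.iloc[0] == pytest.approx(1.0 / fit.hr.iloc[0], rel=1e-5)
        assert fit2.log_likelihood == pytest.approx(fit.log_likelihood, abs=1e-6)

    def test_log_hr_bias_shrinks_with_n(self):
        true = math.log(2.0)
        errs = {}
        for n in (500, 5000, 50000):
            df = simulate_two_group_exponential(n, 0.5, 2.0, seed=21)
            fit = cox_fit(df[["high"]], df["time_months"], df["event"])
            errs[n] = abs(fit.coefficients.iloc[0] - true)
        assert errs[50000] < 0.05
        assert errs[50000] < errs[500]

    def test_ci_brackets_hr(self):
        df = simulate_two_group_exponential(800, 0.3, 3.0, seed=2)
        fit = cox_fit(df[["high"]], df["time_months"], df["event"])
        s = fit.summary.iloc[0]
        assert s["ci_lower"] <= s["hr"] <= s["ci_upper"]
        assert s["hr"] == pytest.approx(math.exp(s["coef"]))

    def test_constant_covariate_rejected(self):
        df = simulate_two_group_exponential(100, 0.5, 1.0, seed=0)
        df["flat"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            cox_fit(df[["flat"]], df["time_months"], df["event"])

    def test_null_partial_log_likelihood_matches_lifelines(self):
        from lifelines import CoxPHFitter

        df = simulate_two_group_exponential(200, 0.5, 2.0, seed=8)
        d = df.rename(columns={"time_months": "T", "event": "E"})
        cph = CoxPHFitter().fit(d, "T", "E")
        ll0 = cph.log_likelihood_ - cph.log_likelihood_ratio_test().test_statistic / 2
        assert null_partial_log_likelihood(df["time_months"], df["event"]) == (
            pytest.approx(ll0, abs=1e-6)
        )


class TestEventDefinition:
    def test_cancer_specific_vs_all_death(self):
        cause = pd.Series(
            ["cancer_death", "noncancer_death", "censored", "alive"]
        )
        assert events_from_cause(cause).tolist() == [True, False, False, False]
        assert events_from_cause(cause, "all_death").tolist() == [
            True, True, False, False
        ]
        with pytest.raises(ValueError):
            events_from_cause(pd.Series(["dead"]))


class TestBackwardConditional:
    @staticmethod
    def _simulate(n, rng, strong_hr=5.0):
        X = pd.DataFrame(
            {f"x{i}": (rng.random(n) < 0.5).astype(float) for i in range(4)}
        )
        X["prognostic"] = (rng.random(n) < 0.5).astype(float)
        rate = 0.01 * np.where(X["prognostic"] == 1, strong_hr, 1.0)
        t = rng.exponential(1.0 / rate)
        return X, t, np.ones(n, bool)

    def test_alpha_one_returns_full_model(self, rng):
        X, t, e = self._simulate(300, rng)
        full = cox_fit(X, t, e)
        res = cox_backward_conditional(X, t, e, removal_alpha=1.0)
        assert res.trace == ()
        assert list(res.retained) == list(X.columns)
        assert res.final.log_likelihood == pytest.approx(full.log_likelihood)

    def test_retains_truly_prognostic_covariate(self):
        hits, keeps_only = 0, 0
        reps = 20
        for seed in range(reps):
            rng = np.random.default_rng(100 + seed)
            X, t, e = self._simulate(2000, rng)
            res = cox_backward_conditional(X, t, e, removal_alpha=0.10)
            if "prognostic" in res.retained:
                hits += 1
            if res.retained == ("prognostic",):
                keeps_only += 1
        assert hits >= int(0.95 * reps)
        assert keeps_only >= reps // 2  # nulls are usually all eliminated

    def test_all_null_model_usually_empties(self):
        empty = 0
        reps = 30
        for seed in range(reps):
            rng = np.random.default_rng(500 + seed)
            X, t, e = self._simulate(300, rng, strong_hr=1.0)
            res = cox_backward_conditional(X, t, e, removal_alpha=0.10)
            if res.final is None:
                empty += 1
        assert empty >= reps // 2

    def test_trace_records_each_removal(self, rng):
        X, t, e = self._simulate(800, rng)
        res = cox_backward_conditional(X, t, e, removal_alpha=0.10)
        removed = [s.removed for s in res.trace]
        assert set(removed) | set(res.retained) == set(X.columns)
        assert all(s.p_removal >= 0.10 for s in res.trace)
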