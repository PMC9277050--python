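"""Kaplan-Meier, log-rank and Cox proportional-hazards fitting."""

import numpy as np
import pandas as pd
import pytest

from fragmeth.survival import (
    cox_fit,
    cox_loglik,
    cox_score,
    km_fit,
    logrank,
    multivariate_selection,
    select_by_entry_p,
)
from fragmeth.synthdata import SurvivalSimDesign, simulate_clinical


class TestKaplanMeier:
    def test_product_limit_by_hand(self):
        fit = km_fit([1, 2, 3], [1, 1, 1])
        assert fit.survival == pytest.approx([2 / 3, 1 / 3, 0.0])
        assert fit.at_risk.tolist() == [3, 2, 1]

    def test_all_censored_curve_stays_at_one(self):
        fit = km_fit([5.0, 7.0, 2.0], [0, 0, 0])
        assert fit.survival_at(100.0) == 1.0

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, size=200)
        fit = km_fit(t, np.ones_like(t, dtype=int))
        for q in np.quantile(t, [0.1, 0.5, 0.9]):
            assert fit.survival_at(q) == pytest.approx((t > q).mean())

    def test_nonincreasing_and_empty_input(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, size=100)
        e = rng.integers(0, 2, size=100)
        fit = km_fit(t, e)
        assert (np.diff(fit.survival) <= 1e-12).all()
        assert (np.diff(fit.at_risk) <= 0).all()
        with pytest.raises(ValueError):
            km_fit([], [])


class TestLogrank:
    def test_identical_groups(self):
        stat, p = logrank([1, 2, 3, 1, 2, 3], [1, 1, 1, 1, 1, 1], [0, 0, 0, 1, 1, 1])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(10, size=80)
        e = rng.integers(0, 2, size=80)
        g = rng.integers(0, 2, size=80)
        if g.sum() in (0, 80):
            g[0] = 1 - g[0]
        assert logrank(t, e, g)[0] == pytest.approx(logrank(t, e, 1 - g)[0])

    def test_null_rejection_rate_is_calibrated(self):
        """Permuting labels on null data rejects at ~alpha."""
        rng = np.random.default_rng(3)
        t = rng.exponential(10, size=60)
        e = rng.integers(0, 2, size=60)
        rejections = 0
        n_reps = 1000
        for _ in range(n_reps):
            g = rng.permutation(np.r_[np.zeros(30, int), np.ones(30, int)])
            if logrank(t, e, g)[1] < 0.05:
                rejections += 1
        assert abs(rejections / n_reps - 0.05) <= 0.02

    def test_power_under_strong_hazard_ratio(self):
        """HR = 3 with 200 subjects per arm is detected at p < 0.001."""
        rng = np.random.default_rng(4)
        hits = 0
        n_reps = 40
        for _ in range(n_reps):
            g = np.r_[np.zeros(200, int), np.ones(200, int)]
            haz = 0.02 * 3.0**g
            t = rng.exponential(1 / haz)
            c = rng.exponential(1 / 0.005, size=400)
            time = np.minimum(t, c)
            ev = (t <= c).astype(int)
            if logrank(time, ev, g)[1] < 0.001:
                hits += 1
        assert hits / n_reps >= 0.95

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            logrank([1, 2], [1, 1], [1, 1])


class TestCox:
    def _sim(self, n=400, beta=0.7, seed=5, round_times=False):
        rng = np.random.default_rng(seed)
        x = (rng.random(n) < 0.4).astype(float)
        t = rng.exponential(1 / (0.05 * np.exp(beta * x)))
        c = rng.exponential(1 / 0.02, size=n)
        time = np.minimum(t, c)
        if round_times:
            time = np.ceil(time)  # force ties
        ev = (t <= c).astype(int)
        return x, time, ev

    def test_null_covariate_gives_unit_hazard_ratio(self):
        x, t, e = self._sim(beta=0.0, n=1000, seed=6)
        fit = cox_fit(x, t, e)
        assert abs(fit.coef[0]) < 0.2
        assert fit.ci_low[0] < 1.0 < fit.ci_high[0]

    def test_parameter_recovery_single_fit(self):
        x, t, e = self._sim(n=2000, seed=7)
        fit = cox_fit(x, t, e)
        assert fit.converged
        assert fit.coef[0] == pytest.approx(0.7, abs=0.15)
        assert fit.hazard_ratio[0] == pytest.approx(np.exp(fit.coef[0]))
        assert fit.ci_low[0] < fit.hazard_ratio[0] < fit.ci_high[0]

    def test_score_vanishes_at_optimum(self):
        x, t, e = self._sim()
        fit = cox_fit(x, t, e)
        s = cox_score(fit.coef, x[:, None], t, e)
        assert np.abs(s).max() < 1e-6

    def test_analytic_score_matches_numerical_gradient(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(150, 3))
        t = rng.exponential(10, size=150)
        e = rng.integers(0, 2, size=150)
        beta = np.array([0.4, -0.3, 0.1])
        s = cox_score(beta, X, t, e)
        eps = 1e-6
        for i in range(3):
            d = np.zeros(3)
            d[i] = eps
            num = (cox_loglik(beta + d, X, t, e) - cox_loglik(beta - d, X, t, e)) / (
                2 * eps
            )
            assert abs(s[i] - num) < 1e-5

    def test_matches_lifelines_with_ties(self):
        from lifelines import CoxPHFitter

        x, t, e = self._sim(round_times=True)
        fit = cox_fit(x, t, e, covariate_names=["x"])
        df = pd.DataFrame({"x": x, "t": t, "e": e})
        cph = CoxPHFitter()
        cph.fit(df, duration_col="t", event_col="e")
        assert fit.coef[0] == pytest.approx(cph.params_["x"], abs=1e-4)
        assert fit.se[0] == pytest.approx(cph.standard_errors_["x"], abs=1e-4)

    def test_breslow_differs_from_efron_only_with_ties(self):
        x, t, e = self._sim()
        assert cox_fit(x, t, e, ties="efron").coef[0] == pytest.approx(
            cox_fit(x, t, e, ties="breslow").coef[0], abs=1e-8
        )
        x, t, e = self._sim(round_times=True)
        assert cox_fit(x, t, e, ties="efron").coef[0] != pytest.approx(
            cox_fit(x, t, e, ties="breslow").coef[0], abs=1e-8
        )

    def test_perfect_separation_is_flagged(self):
        # group 1 all fails early, group 0 all censored late: monotone likelihood
        t = np.r_[np.ones(20), np.full(20, 50.0)]
        e = np.r_[np.ones(20, int), np.zeros(20, int)]
        x = np.r_[np.ones(20), np.zeros(20)]
        fit = cox_fit(x, t, e)
        assert not fit.converged

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            cox_fit(np.ones(10), np.arange(1, 11), np.ones(10, int))

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            cox_fit(np.r_[np.zeros(5), np.ones(5)], np.arange(1, 11),
                    np.zeros(10, int))


class TestMultivariateSelection:
    def test_entry_rule_is_strict_threshold(self):
        p = {"v1": 0.042, "v2": 0.756, "v3": 0.199, "v4": 0.21}
        assert select_by_entry_p(p) == ["v1", "v3"]

    def test_published_univariate_column_selection(self):
        # univariate p-values of a published OS model: six variables enter
        # at P < 0.200, four are excluded
        p = {
            "meth": 0.042, "age": 0.000, "ipss": 0.042,
            "cebpa": 0.403, "idh": 0.958, "u2af1": 0.756, "sf3b1": 0.450,
            "srsf2": 0.031, "setbp1": 0.031, "dnmt3a": 0.053,
        }
        selected = select_by_entry_p(p)
        assert selected == ["meth", "age", "ipss", "srsf2", "setbp1", "dnmt3a"]

    def test_joint_fit_over_selected_covariates(self):
        tab = simulate_clinical(
            SurvivalSimDesign(n=600, beta_meth=0.8,
                              covariate_freqs={"mutA": 0.3}, seed=9)
        )
        uni, multi, selected = multivariate_selection(
            tab, ["hypermethylated", "mutA"], "os_time", "os_event"
        )
        assert "hypermethylated" in selected
        assert multi is not None
        assert multi.covariates == selected
        i = selected.index("hypermethylated")
        assert multi.coef[i] == pytest.approx(0.8, abs=0.35)

    def test_empty_selection_reports_univariate_only(self):
        rng = np.random.default_rng(17)
        tab = pd.DataFrame(
            {
                "noise": rng.random(100).round(),  # pure noise covariate
                "os_time": rng.exponential(10, 100),
                "os_event": rng.integers(0, 2, 100),
            }
        )
        uni, multi, selected = multivariate_selection(
            tab, ["noise"], "os_time", "os_event", entry_p=uni_p_floor(tab)
        )
        assert multi is None and selected == []


def uni_p_floor(tab) -> float:
    """Entry threshold guaranteed to exclude the noise covariate."""
    fit = cox_fit(tab["noise"].to_numpy(float), tab["os_time"], tab["os_event"])
    return min(0.2, float(fit.p_value[0]))
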