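"""Kaplan-Meier, log-rank, Cox partial likelihood, baseline hazard, per-SD HR."""

import numpy as np
import pandas as pd
import pytest

from methrisk import SimConfig, generate_cohort
from methrisk.cox import breslow_baseline, fit_cox, per_sd_hr
from methrisk.km import kaplan_meier, logrank


class TestKaplanMeier:
    def test_no_events_survival_stays_one(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [0, 0, 0])
        assert km.survival_at([0.5, 2.5, 10.0]).tolist() == [1.0, 1.0, 1.0]

    def test_classic_six_subject_toy(self):
        # events at 1,3,5,6; censored at 2,4
        km = kaplan_meier([1, 2, 3, 4, 5, 6], [1, 0, 1, 0, 1, 1])
        # hand product-limit: 5/6, 5/6*3/4, *1/2, *0
        assert np.allclose(km.survival, [5 / 6, 5 / 8, 5 / 16, 0.0])
        assert km.at_risk.tolist() == [6, 4, 2, 1]

    def test_no_censoring_equals_one_minus_ecdf(self, rng):
        t = rng.permutation(np.arange(1.0, 21.0))
        km = kaplan_meier(t, np.ones(20, int))
        expected = 1.0 - np.arange(1, 21) / 20.0
        assert np.allclose(km.survival, expected)

    def test_greenwood_variance_positive_and_growing(self, rng):
        t = rng.exponential(1, 50) + 0.01
        e = rng.integers(0, 2, 50)
        e[0] = 1
        km = kaplan_meier(t, e)
        pos = km.survival > 0
        ratio = km.greenwood_var[pos] / km.survival[pos] ** 2
        assert (km.greenwood_var >= 0).all()
        assert (np.diff(ratio) >= -1e-15).all()  # cumulative Greenwood sum grows

    def test_nonpositive_times_raise(self):
        with pytest.raises(ValueError, match="positive"):
            kaplan_meier([0.0, 1.0], [1, 1])


class TestLogrank:
    def test_identical_groups_give_null(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 0, 1, 1, 1, 0, 1, 1]
        g = ["a"] * 4 + ["b"] * 4
        chi2, df, p = logrank(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1 and p == pytest.approx(1.0)

    def test_matches_lifelines_on_toy(self):
        from lifelines.statistics import logrank_test
        t = np.array([1.0, 2, 3, 4, 5, 1.5, 2.5, 3.5, 6, 7])
        e = np.array([1, 1, 0, 1, 1, 1, 0, 1, 1, 0])
        g = np.array(["a"] * 5 + ["b"] * 5)
        chi2, df, p = logrank(t, e, g)
        ref = logrank_test(t[g == "a"], t[g == "b"], e[g == "a"], e[g == "b"])
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-10)
        assert p == pytest.approx(ref.p_value, abs=1e-10)

    def test_asymptotic_p_near_permutation_p(self, rng):
        t = np.concatenate([rng.exponential(1.0, 6), rng.exponential(2.5, 6)])
        e = np.ones(12, int)
        g = np.array(["a"] * 6 + ["b"] * 6)
        chi2, _, p_asym = logrank(t, e, g)
        count = 0
        n_perm = 20000
        prng = np.random.default_rng(5)
        for _ in range(n_perm):
            chi_p, _, _ = logrank(t, e, prng.permutation(g))
            count += chi_p >= chi2 - 1e-12
        p_perm = (count + 1) / (n_perm + 1)
        # slack covers Monte-Carlo error plus the chi-square approximation
        # gap at 12 subjects
        assert abs(p_asym - p_perm) < 0.05

    def test_no_events_raises(self):
        with pytest.raises(ValueError, match="events"):
            logrank([1, 2], [0, 0], ["a", "b"])


def _toy_no_ties():
    t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
    e = np.array([1, 1, 0, 1, 1, 0, 1, 1])
    x = np.array([1.0, 0, 1, 1, 0, 0, 1, 0])
    return t, e, x


class TestCox:
    def test_matches_grid_search_on_binary_toy(self):
        t, e, x = _toy_no_ties()
        fit = fit_cox(t, e, x[:, None])
        # dense grid maximisation of the partial likelihood, written directly
        grid = np.arange(-3.0, 3.0, 1e-5)
        order = np.argsort(t)
        ts, es, xs = t[order], e[order], x[order]
        ll = np.zeros_like(grid)
        for i in np.flatnonzero(es == 1):
            risk = xs[i:]
            ll += grid * xs[i] - np.log(np.exp(np.outer(grid, risk)).sum(axis=1))
        best = grid[np.argmax(ll)]
        assert fit.coef[0] == pytest.approx(best, abs=1e-5)

    def test_all_zero_design_gives_null_model(self):
        t, e, _ = _toy_no_ties()
        fit = fit_cox(t, e, np.zeros((8, 2)))
        assert np.allclose(fit.coef, 0.0)
        assert fit.neg2_loglik == pytest.approx(fit.neg2_loglik_null)

    def test_matches_lifelines_with_ties(self, rng):
        from lifelines import CoxPHFitter
        n = 300
        x = rng.standard_normal((n, 2))
        t = np.ceil(rng.exponential(np.exp(-0.6 * x[:, 0] + 0.3 * x[:, 1])) * 8)
        c = np.ceil(rng.uniform(1, 15, n))
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
        df = pd.DataFrame({"t": time, "e": event, "x0": x[:, 0], "x1": x[:, 1]})
        fit_e = fit_cox(time, event, x, ties="efron")
        cph = CoxPHFitter().fit(df, "t", "e")  # lifelines uses Efron ties
        assert np.allclose(fit_e.coef, cph.params_.to_numpy(), atol=1e-4)
        assert np.allclose(fit_e.se, cph.standard_errors_.to_numpy(), atol=1e-4)

    def test_breslow_equals_efron_without_ties(self, rng):
        n = 150
        x = rng.standard_normal((n, 2))
        t = rng.exponential(np.exp(-0.5 * x[:, 0]))
        e = (rng.random(n) < 0.7).astype(int)
        e[0] = 1
        fb = fit_cox(t, e, x, ties="breslow")
        fe = fit_cox(t, e, x, ties="efron")
        assert np.allclose(fb.coef, fe.coef, atol=1e-12)
        assert fb.neg2_loglik == pytest.approx(fe.neg2_loglik, abs=1e-9)

    def test_duplicated_cohort_invariance(self, rng):
        n = 120
        x = rng.standard_normal((n, 2))
        t = rng.exponential(np.exp(-0.5 * x[:, 0]))
        e = (rng.random(n) < 0.8).astype(int)
        e[0] = 1
        f1 = fit_cox(t, e, x, ties="breslow")
        f2 = fit_cox(np.tile(t, 2), np.tile(e, 2), np.tile(x, (2, 1)),
                     ties="breslow")
        assert np.allclose(f1.coef, f2.coef, atol=1e-6)
        assert np.allclose(np.diag(f2.cov), np.diag(f1.cov) / 2, atol=1e-6)

    def test_parameter_recovery_from_generator(self):
        d = generate_cohort(SimConfig(n_participants=10000, seed=17))
        X = np.column_stack([
            d.truth["true_score"],
            (d.cohort["age"] - 62) / 10,
            (d.cohort["sex"] == "male").astype(float),
        ])
        fit = fit_cox(d.survival["time"].to_numpy(),
                      d.survival["event"].to_numpy(), X)
        assert abs(fit.coef[0] - 0.62) < 0.05

    def test_monotone_likelihood_flagged(self):
        t = np.array([1.0, 2, 3, 4, 5, 6])
        e = np.ones(6, int)
        x = np.array([1.0, 1, 1, 0, 0, 0])  # all x=1 fail first: separation
        fit = fit_cox(t, e, x[:, None])
        assert not fit.converged

    def test_rank_deficient_design_raises(self, rng):
        x = rng.standard_normal(30)
        X = np.column_stack([x, 2 * x])
        t = rng.exponential(1, 30)
        with pytest.raises(ValueError, match="rank"):
            fit_cox(t, np.ones(30, int), X)


class TestBaseline:
    def test_null_fit_reduces_to_nelson_aalen(self, rng):
        t = rng.exponential(1, 60)
        e = (rng.random(60) < 0.7).astype(int)
        e[0] = 1
        fit = fit_cox(t, e, np.zeros((60, 1)))
        h0 = breslow_baseline(fit)
        # Nelson-Aalen by hand
        na = []
        acc = 0.0
        for te in h0.times:
            d = ((t == te) & (e == 1)).sum()
            r = (t >= te).sum()
            acc += d / r
            na.append(acc)
        assert np.allclose(h0.cumhaz, na)

    def test_five_subject_hand_computation(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        e = np.array([1, 0, 1, 1, 0])
        x = np.array([0.0, 1.0, 0.0, 1.0, 0.0])
        fit = fit_cox(t, e, x[:, None])
        b = fit.coef[0]
        w = np.exp(b * x)
        expected = [1.0 / w.sum(),
                    1.0 / w.sum() + 1.0 / w[2:].sum(),
                    1.0 / w.sum() + 1.0 / w[2:].sum() + 1.0 / w[3:].sum()]
        h0 = breslow_baseline(fit)
        assert np.allclose(h0.cumhaz, expected, atol=1e-10)

    def test_zero_at_time_zero_and_extrapolation_flag(self, rng):
        t = rng.exponential(1, 40) + 0.1
        e = np.ones(40, int)
        fit = fit_cox(t, e, rng.standard_normal((40, 1)))
        h0 = breslow_baseline(fit)
        assert h0.cumhaz_at(np.array([0.0]))[0] == 0.0
        assert h0.extrapolates(t.max() + 1)
        assert not h0.extrapolates(t.max() / 2)


class TestPerSdHr:
    def _fit(self, rng, x_scale=1.0):
        n = 400
        x = rng.standard_normal(n) * x_scale
        z = rng.standard_normal(n)
        t = np.random.default_rng(0).exponential(np.exp(0.4 * x / x_scale))
        e = np.ones(n, int)
        return fit_cox(t, e, pd.DataFrame({"meth": x, "z": z}))

    def test_zero_coefficient_gives_unit_hr(self, rng):
        n = 200
        x = rng.standard_normal(n)
        t = rng.exponential(1, n)
        fit = fit_cox(t, np.ones(n, int), pd.DataFrame({"meth": x}))
        fit.coef[0] = 0.0
        assert per_sd_hr(fit, "meth")["hr"] == pytest.approx(1.0)

    def test_unit_sd_negative_coefficient(self, rng):
        n = 200
        fit = fit_cox(rng.exponential(1, n), np.ones(n, int),
                      pd.DataFrame({"meth": rng.standard_normal(n)}))
        fit.coef[0] = -0.47
        out = per_sd_hr(fit, "meth", sd=1.0)
        assert out["hr"] == pytest.approx(np.exp(0.47))

    def test_invariant_to_stored_units(self):
        f1 = self._fit(np.random.default_rng(3), x_scale=1.0)
        f2 = self._fit(np.random.default_rng(3), x_scale=2.0)
        assert per_sd_hr(f1, "meth")["hr"] == pytest.approx(
            per_sd_hr(f2, "meth")["hr"], rel=1e-6)

    def test_zero_sd_raises(self, rng):
        n = 50
        fit = fit_cox(rng.exponential(1, n), np.ones(n, int),
                      pd.DataFrame({"meth": np.zeros(n), "z": rng.standard_normal(n)}))
        with pytest.raises(ValueError, match="deviation"):
            per_sd_hr(fit, "meth")
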