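"""Risk-prediction evaluation: absolute risk, C-statistic, optimism, NRI,
IDI, calibration, model comparison, collinearity."""

import numpy as np
import pandas as pd
import pytest

from methrisk import SimConfig, generate_cohort
from methrisk.config import CPG_SITES, SCORE_CPGS, CpGProfile
from methrisk.cox import breslow_baseline, fit_cox
from methrisk.evaluate import (absolute_risk, aic_value, calibration_gb,
                               categorize_risk, collinearity, harrell_c, idi,
                               model_compare, nri, optimism_corrected_c,
                               score_model_design)


class TestAbsoluteRisk:
    def test_zero_lp_equals_baseline_risk(self, rng):
        t = rng.exponential(1, 60)
        e = np.ones(60, int)
        fit = fit_cox(t, e, np.zeros((60, 1)))
        risk, extrap = absolute_risk(fit, float(np.median(t)))
        h0 = breslow_baseline(fit)
        expected = 1 - np.exp(-h0.cumhaz_at(np.array([np.median(t)]))[0])
        assert np.allclose(risk, expected)
        assert not extrap

    def test_five_subject_hand_computation(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        e = np.array([1, 0, 1, 1, 0])
        x = np.array([0.0, 1.0, 0.0, 1.0, 0.0])
        fit = fit_cox(t, e, x[:, None])
        b = fit.coef[0]
        w = np.exp(b * x)
        H3 = 1.0 / w.sum() + 1.0 / w[2:].sum()  # cumulative hazard at t=3
        expected = 1 - np.exp(-H3 * w)
        risk, _ = absolute_risk(fit, 3.0)
        assert np.allclose(risk, expected, atol=1e-10)

    def test_monotone_in_linear_predictor(self, rng):
        n = 100
        x = np.sort(rng.standard_normal(n))
        t = rng.exponential(np.exp(-0.8 * x))
        fit = fit_cox(t, np.ones(n, int), x[:, None])
        risk, _ = absolute_risk(fit, 1.0)
        assert (np.diff(risk) >= 0).all()

    def test_extrapolation_flagged(self, rng):
        t = rng.exponential(1, 40)
        fit = fit_cox(t, np.ones(40, int), rng.standard_normal((40, 1)))
        _, extrap = absolute_risk(fit, t.max() * 2)
        assert extrap


class TestHarrellC:
    def test_perfect_ordering_gives_one(self):
        t = np.arange(1.0, 11.0)
        out = harrell_c(t, np.ones(10, int), -t)
        assert out["c"] == 1.0

    def test_constant_score_gives_half(self, rng):
        t = rng.exponential(1, 30)
        out = harrell_c(t, np.ones(30, int), np.zeros(30))
        assert out["c"] == 0.5

    def test_matches_brute_force_enumeration(self, rng):
        t = np.round(rng.exponential(1, 20), 2) + 0.01
        d = rng.integers(0, 2, 20)
        d[:2] = 1
        r = np.round(rng.normal(0, 1, 20), 1)  # induce some risk ties
        num = den = 0.0
        for i in range(20):
            for j in range(20):
                if i == j:
                    continue
                usable = ((t[i] < t[j] and d[i] == 1)
                          or (t[i] == t[j] and d[i] == 1 and d[j] == 0))
                if usable:
                    den += 1
                    num += 1.0 if r[i] > r[j] else (0.5 if r[i] == r[j] else 0.0)
        out = harrell_c(t, d, r)
        assert out["c"] == num / den
        assert out["ci_low"] <= out["c"] <= out["ci_high"]

    def test_no_usable_pairs_raises(self):
        with pytest.raises(ValueError, match="usable"):
            harrell_c([1.0, 2.0], [0, 0], [0.1, 0.2])


class TestOptimism:
    def test_identity_resample_gives_apparent(self, rng, monkeypatch):
        n = 80
        x = rng.standard_normal((n, 1))
        t = rng.exponential(np.exp(-0.5 * x[:, 0]))
        e = np.ones(n, int)

        class _Identity:
            def integers(self, lo, hi, size):
                return np.arange(size)

        monkeypatch.setattr("methrisk.evaluate.np.random.default_rng",
                            lambda seed: _Identity())
        out = optimism_corrected_c(t, e, x, B=1, seed=0)
        assert out["corrected"] == pytest.approx(out["apparent"], abs=1e-12)

    def test_correction_shrinks_noise_model_on_average(self):
        gaps_app, gaps_corr = [], []
        for rep in range(12):
            rng = np.random.default_rng(300 + rep)
            n = 200
            X = rng.standard_normal((n, 1))
            t = rng.exponential(1.0, n)
            c = rng.uniform(0.5, 3, n)
            tm, ev = np.minimum(t, c), (t <= c).astype(int)
            out = optimism_corrected_c(tm, ev, X, B=40, seed=rep)
            gaps_app.append(abs(out["apparent"] - 0.5))
            gaps_corr.append(abs(out["corrected"] - 0.5))
        assert np.mean(gaps_corr) < np.mean(gaps_app)

    def test_pure_noise_model_pulled_toward_half(self):
        """Overfit multi-noise-predictor model: correction moves C toward 0.5."""
        closer = 0
        n_rep = 10
        for rep in range(n_rep):
            rng = np.random.default_rng(500 + rep)
            n = 200
            X = rng.standard_normal((n, 8))
            t = rng.exponential(1.0, n)
            c = rng.uniform(0.5, 3, n)
            tm, ev = np.minimum(t, c), (t <= c).astype(int)
            out = optimism_corrected_c(tm, ev, X, B=40, seed=rep)
            closer += abs(out["corrected"] - 0.5) < abs(out["apparent"] - 0.5)
        assert closer / n_rep >= 0.9


class TestCategorize:
    def test_boundary_membership(self):
        cats = categorize_risk([0.0, 0.05, 0.0501, 0.10, 0.15, 0.20, 0.25])
        assert cats.tolist() == [1, 1, 2, 2, 3, 3, 4]

    def test_vector_example(self):
        assert categorize_risk([0.01, 0.07, 0.15, 0.30]).tolist() == [1, 2, 3, 4]

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError, match="0,1"):
            categorize_risk([1.2])
        with pytest.raises(ValueError, match="increasing"):
            categorize_risk([0.5], boundaries=[0.2, 0.1])


def _movement_vectors(n_cases, case_up, case_dn, n_ctrl, ctrl_up, ctrl_dn):
    old, new, case = [], [], []
    for n_grp, up, dn, flag in ((n_cases, case_up, case_dn, True),
                                (n_ctrl, ctrl_up, ctrl_dn, False)):
        for _ in range(up):
            old.append(1), new.append(2), case.append(flag)
        for _ in range(dn):
            old.append(2), new.append(1), case.append(flag)
        for _ in range(n_grp - up - dn):
            old.append(2), new.append(2), case.append(flag)
    return np.array(old), np.array(new), np.array(case)


class TestNri:
    def test_no_movement_gives_zero(self):
        old = np.array([1, 2, 3, 4] * 5)
        case = np.array([True, False] * 10)
        _, val, p = nri(old, old, case)
        assert val == 0.0

    def test_direct_arithmetic_example(self):
        old, new, case = _movement_vectors(50, 10, 5, 200, 20, 40)
        tab, val, _ = nri(old, new, case)
        assert val == pytest.approx(20.0)
        assert tab.movements() == {"cases_up": 10, "cases_down": 5,
                                   "controls_up": 20, "controls_down": 40}

    def test_printed_movement_counts_reproduce_published_nri(self):
        """18/11 case and 82/151 control moves with 50/871 complete-case
        denominators give 21.92%."""
        old, new, case = _movement_vectors(50, 18, 11, 871, 82, 151)
        _, val, p = nri(old, new, case)
        assert round(val, 2) == 21.92
        assert 0 < p < 1

    def test_zero_cases_raise(self):
        with pytest.raises(ValueError, match="cases"):
            nri([1, 2], [1, 2], [False, False])


class TestIdi:
    def test_identical_models_give_zero(self, rng):
        p = rng.random(50)
        case = rng.random(50) < 0.3
        case[0], case[1] = True, False
        val, _ = idi(p, p, case)
        assert val == 0.0

    def test_six_subject_hand_example(self):
        p_old = np.array([0.10, 0.20, 0.30, 0.15, 0.25, 0.05])
        p_new = np.array([0.20, 0.15, 0.40, 0.10, 0.20, 0.05])
        case = np.array([True, True, True, False, False, False])
        # hand arithmetic: mean case diff = (0.10-0.05+0.10)/3 = 0.05
        # mean control diff = (-0.05-0.05+0.0)/3
        expected = 100 * (0.15 / 3 - (-0.10 / 3))
        val, _ = idi(p_old, p_new, case)
        assert val == pytest.approx(expected, abs=1e-12)

    def test_noise_augmentation_centred_at_zero(self):
        vals = []
        for rep in range(60):
            rng = np.random.default_rng(700 + rep)
            n = 400
            x = rng.standard_normal(n)
            t = rng.exponential(np.exp(-0.5 * x))
            c = rng.uniform(0.5, 3, n)
            tm, ev = np.minimum(t, c), (t <= c).astype(int)
            base = fit_cox(tm, ev, x[:, None])
            noise = np.column_stack([x, rng.standard_normal(n)])
            augd = fit_cox(tm, ev, noise)
            r0, _ = absolute_risk(base, 1.0)
            r1, _ = absolute_risk(augd, 1.0)
            vals.append(idi(r0, r1, ev.astype(bool))[0])
        assert abs(np.mean(vals)) < 0.5


class TestCalibration:
    def test_group_aligned_binary_covariate_is_exactly_calibrated(self, rng):
        # balanced binary covariate with groups=2: the rank grouping matches
        # the covariate levels, so the score equations force O=E per group
        n = 80
        x = np.repeat([0.0, 1.0], n // 2)
        t = rng.exponential(np.exp(-0.8 * x))
        e = np.ones(n, int)
        fit = fit_cox(t, e, x[:, None])
        table, chi2, p = calibration_gb(fit, groups=2)
        assert np.allclose(table["observed"], table["expected"], atol=1e-6)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_expected_counts_match_martingale_oracle(self, rng):
        n = 150
        x = rng.standard_normal((n, 2))
        t = rng.exponential(np.exp(-0.5 * x[:, 0]))
        c = rng.uniform(0.5, 3, n)
        tm, ev = np.minimum(t, c), (t <= c).astype(int)
        fit = fit_cox(tm, ev, x)
        table, _, _ = calibration_gb(fit, groups=5)
        h0 = breslow_baseline(fit)
        exp_i = h0.cumhaz_at(fit.times) * np.exp(fit.linear_predictor)
        assert table["expected"].sum() == pytest.approx(exp_i.sum(), abs=1e-8)
        assert table["observed"].sum() == fit.events.sum()

    def test_type_one_error_controlled(self):
        rej = 0
        n_rep = 40
        for rep in range(n_rep):
            rng = np.random.default_rng(900 + rep)
            n = 300
            x = rng.standard_normal((n, 2))
            t = rng.exponential(np.exp(-(0.5 * x[:, 0] + 0.3 * x[:, 1])))
            c = rng.uniform(0.5, 3, n)
            tm, ev = np.minimum(t, c), (t <= c).astype(int)
            fit = fit_cox(tm, ev, x)
            _, _, p = calibration_gb(fit)
            rej += p < 0.05
        assert rej / n_rep <= 0.1

    def test_power_against_omitted_nonlinearity(self):
        rej = 0
        for rep in range(8):
            rng = np.random.default_rng(1100 + rep)
            n = 2000
            x = rng.standard_normal(n)
            t = rng.exponential(np.exp(-(0.8 * x + 0.8 * x * x)))
            c = rng.uniform(0.5, 3, n)
            tm, ev = np.minimum(t, c), (t <= c).astype(int)
            fit = fit_cox(tm, ev, x[:, None])
            _, _, p = calibration_gb(fit)
            rej += p < 0.05
        assert rej / 8 >= 0.6


class TestModelCompare:
    @pytest.mark.parametrize("neg2, k, expected", [
        (623.93, 5, 633.93),
        (597.54, 11, 619.54),
    ])
    def test_aic_identity_printed_values(self, neg2, k, expected):
        assert aic_value(neg2, k) == pytest.approx(expected, abs=1e-9)

    def test_identical_models_lr_zero(self, rng):
        n = 100
        x = rng.standard_normal((n, 2))
        t = rng.exponential(1, n)
        fit = fit_cox(t, np.ones(n, int), x)
        out = model_compare(fit, fit)
        assert out["lr"] == 0.0 and out["p"] == 1.0

    def test_lr_of_nested_models(self, rng):
        n = 300
        x = rng.standard_normal((n, 2))
        t = rng.exponential(np.exp(-0.8 * x[:, 0]))
        e = np.ones(n, int)
        base = fit_cox(t, e, x[:, :1])
        augd = fit_cox(t, e, x)
        out = model_compare(base, augd)
        assert out["df"] == 1
        assert out["lr"] >= 0
        assert out["aic_base"] == pytest.approx(base.neg2_loglik + 2)
        with pytest.raises(ValueError, match="identical rows"):
            model_compare(fit_cox(t[:100], e[:100], x[:100]), augd)


class TestCollinearity:
    def test_orthogonal_columns_unit_vif(self):
        X = pd.DataFrame({"a": [1.0, -1, 1, -1, 1, -1, 1, -1],
                          "b": [1.0, 1, -1, -1, 1, 1, -1, -1]})
        out = collinearity(X, ["a", "b"])
        assert np.allclose(out["vif"], 1.0)
        assert np.allclose(out["tolerance"], 1.0)

    def test_known_correlation_closed_form(self, rng):
        n = 20000
        a = rng.standard_normal(n)
        b = 0.7 * a + np.sqrt(1 - 0.49) * rng.standard_normal(n)
        out = collinearity(pd.DataFrame({"a": a, "b": b}), ["a"])
        assert out["vif"][0] == pytest.approx(1 / (1 - 0.49), rel=0.03)

    def test_perfect_collinearity_raises(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        with pytest.raises(ValueError, match="collinearity"):
            collinearity(X, ["a"])

    def test_score_cpg_vif_in_published_range(self):
        """Two CpGs correlated ~0.56 against the SCORE design: VIF near 1.46."""
        profiles = {c: CpGProfile(0.75, 0.0, 0.0, 0.3) for c in CPG_SITES}
        corr = np.eye(len(CPG_SITES))
        i = CPG_SITES.index(SCORE_CPGS[0])
        j = CPG_SITES.index(SCORE_CPGS[1])
        corr[i, j] = corr[j, i] = 0.56
        cfg = SimConfig(n_participants=3000, seed=61, cpg_profiles=profiles,
                        inter_cpg_correlation=corr, missing_rates={})
        d = generate_cohort(cfg)
        design = score_model_design(d.cohort, d.methylation,
                                    add_cpgs=list(SCORE_CPGS), include_batch=False)
        out = collinearity(design, list(SCORE_CPGS))
        assert np.allclose(out["vif"], 1.46, atol=0.3)
        assert np.allclose(out["tolerance"], 1 / out["vif"])
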