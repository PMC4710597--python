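"""Incremental-value evaluation of risk-prediction models for fatal CVD.

Absolute 10-year risks from the Cox fit and Breslow baseline, Harrell's C
with a jackknife CI, .632-bootstrap optimism correction, guideline risk
categories (0-5, >5-10, >10-20, >20%), category NRI, IDI, the May-Hosmer
form of the Gronnesby-Borgan calibration test, AIC / likelihood-ratio model
comparison, and VIF/tolerance collinearity checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cox import CoxFit, _PartialLikelihood, breslow_baseline, fit_cox

RISK_BOUNDARIES = (0.05, 0.10, 0.20)


def absolute_risk(fit: CoxFit, horizon: float, design=None):
    """Predicted event probability by ``horizon`` years: 1 - exp(-H0 e^lp).

    Returns (probabilities, extrapolation_flag). ``design`` defaults to the
    rows the model was fitted on.
    """
    h0 = breslow_baseline(fit)
    X = fit.X if design is None else np.asarray(design, dtype=float)
    lp = np.clip(X @ fit.coef, -500, 500)
    H = h0.cumhaz_at(np.full(X.shape[0], float(horizon))) * np.exp(lp)
    return 1.0 - np.exp(-H), h0.extrapolates(horizon)


# ----------------------------------------------------------------------
# Harrell's C
# ----------------------------------------------------------------------

def _pair_scores(times, events, risk):
    """Per-subject usable-pair counts and concordance scores (vectorised).

    A pair is usable when the earlier follow-up time ends in an event (tied
    times: one event, one censored). Concordance credits 1 when the earlier
    failure has the higher risk score, 0.5 on risk ties.
    """
    t = np.asarray(times, float)
    d = np.asarray(events, int)
    r = np.asarray(risk, float)
    ti, tj = t[:, None], t[None, :]
    di, dj = d[:, None], d[None, :]
    ri, rj = r[:, None], r[None, :]
    usable = ((ti < tj) & (di == 1)) | ((ti == tj) & (di == 1) & (dj == 0))
    conc = np.where(ri > rj, 1.0, np.where(ri == rj, 0.5, 0.0))
    score_i = np.where(usable, conc, 0.0).sum(1) + np.where(usable.T, conc.T, 0.0).sum(1)
    n_i = usable.sum(1) + usable.sum(0)
    return score_i, n_i, float(np.where(usable, conc, 0.0).sum()), int(usable.sum())


def harrell_c(times, events, risk):
    """Concordance index with a leave-one-subject-out jackknife 95% CI.

    Returns dict with c, ci_low, ci_high, n_pairs.
    """
    score_i, n_i, S, P = _pair_scores(times, events, risk)
    if P == 0:
        raise ValueError("no usable pairs")
    c = S / P
    n = len(score_i)
    denom = P - n_i
    with np.errstate(invalid="ignore", divide="ignore"):
        loo = np.where(denom > 0, (S - score_i) / denom, c)
    var = (n - 1) / n * float(((loo - loo.mean()) ** 2).sum())
    se = np.sqrt(var)
    return {"c": float(c), "ci_low": float(max(0.0, c - 1.96 * se)),
            "ci_high": float(min(1.0, c + 1.96 * se)), "n_pairs": P}


def optimism_corrected_c(times, events, design, B: int = 1000,
                         seed: int = 0, ties: str = "breslow"):
    """.632-bootstrap optimism correction of Harrell's C.

    Each replicate refits the Cox model on a bootstrap resample and scores
    the out-of-bag records; corrected C = 0.368 C_apparent + 0.632 mean(C_oob),
    with a percentile CI over the per-replicate corrected values. Resamples
    without events or without out-of-bag usable pairs are skipped and counted.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    X = design.to_numpy(dtype=float) if isinstance(design, pd.DataFrame) else np.asarray(design, float)
    names = list(design.columns) if isinstance(design, pd.DataFrame) else None
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    full = fit_cox(times, events, X, ties=ties)
    c_app = harrell_c(times, events, X @ full.coef)["c"]
    rng = np.random.default_rng(seed)
    n = len(times)
    oob_cs, skipped = [], 0
    while len(oob_cs) < B:
        idx = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), idx)
        if oob.size == 0:
            # degenerate resample covering every record: no information is
            # held out, so the replicate contributes its resample C
            oob = np.arange(n)
        if events[idx].sum() == 0 or events[oob].sum() == 0:
            skipped += 1
            if skipped > 10 * B:
                raise RuntimeError("too many degenerate bootstrap resamples")
            continue
        bfit = fit_cox(times[idx], events[idx], X[idx], ties=ties)
        try:
            c_oob = harrell_c(times[oob], events[oob], X[oob] @ bfit.coef)["c"]
        except ValueError:
            skipped += 1
            continue
        oob_cs.append(c_oob)
    oob_cs = np.asarray(oob_cs)
    per_rep = 0.368 * c_app + 0.632 * oob_cs
    corrected = 0.368 * c_app + 0.632 * float(oob_cs.mean())
    lo, hi = np.percentile(per_rep, [2.5, 97.5])
    return {"apparent": float(c_app), "corrected": float(corrected),
            "ci_low": float(lo), "ci_high": float(hi),
            "n_replicates": int(B), "n_skipped": int(skipped),
            "names": names}


# ----------------------------------------------------------------------
# Reclassification / discrimination improvement
# ----------------------------------------------------------------------

def categorize_risk(probabilities, boundaries: Sequence[float] = RISK_BOUNDARIES):
    """Guideline risk categories 1..len(boundaries)+1.

    Lower-closed at 0; a boundary value belongs to the lower category
    (0.05 -> category 1, 0.0501 -> category 2).
    """
    p = np.asarray(probabilities, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0,1]")
    b = np.asarray(boundaries, dtype=float)
    if (np.diff(b) <= 0).any() or b[0] <= 0 or b[-1] >= 1:
        raise ValueError("boundaries must be strictly increasing in (0,1)")
    return np.searchsorted(b, p, side="left") + 1


@dataclass
class ReclassTable:
    cases: np.ndarray      # k x k movement counts old -> new
    controls: np.ndarray
    n_cases: int
    n_controls: int

    def movements(self):
        iu = np.triu_indices_from(self.cases, 1)
        il = np.tril_indices_from(self.cases, -1)
        return {
            "cases_up": int(self.cases[iu].sum()),
            "cases_down": int(self.cases[il].sum()),
            "controls_up": int(self.controls[iu].sum()),
            "controls_down": int(self.controls[il].sum()),
        }


def reclassification_table(old_cat, new_cat, case_flags,
                           n_categories: int = 4) -> ReclassTable:
    old = np.asarray(old_cat, int)
    new = np.asarray(new_cat, int)
    case = np.asarray(case_flags, bool)
    k = n_categories
    tab_case = np.zeros((k, k), dtype=int)
    tab_ctrl = np.zeros((k, k), dtype=int)
    for o, nw, c in zip(old, new, case):
        (tab_case if c else tab_ctrl)[o - 1, nw - 1] += 1
    return ReclassTable(tab_case, tab_ctrl, int(case.sum()), int((~case).sum()))


def nri(old_cat, new_cat, case_flags):
    """Category net reclassification improvement, in percent, with z-test p.

    NRI = (cases up - cases down)/n_cases - (controls up - controls down)/n_controls.
    """
    tab = reclassification_table(old_cat, new_cat, case_flags)
    if tab.n_cases == 0 or tab.n_controls == 0:
        raise ValueError("need both cases and controls")
    m = tab.movements()
    pe_up = m["cases_up"] / tab.n_cases
    pe_dn = m["cases_down"] / tab.n_cases
    pc_up = m["controls_up"] / tab.n_controls
    pc_dn = m["controls_down"] / tab.n_controls
    val = (pe_up - pe_dn) - (pc_up - pc_dn)
    var = ((pe_up + pe_dn - (pe_up - pe_dn) ** 2) / tab.n_cases
           + (pc_up + pc_dn - (pc_up - pc_dn) ** 2) / tab.n_controls)
    if var > 0:
        p = float(2 * stats.norm.sf(abs(val) / np.sqrt(var)))
    else:
        p = 1.0
    return tab, 100.0 * val, p


def idi(old_prob, new_prob, case_flags):
    """Integrated discrimination improvement, in percent, with paired z p."""
    po = np.asarray(old_prob, float)
    pn = np.asarray(new_prob, float)
    case = np.asarray(case_flags, bool)
    if case.sum() == 0 or (~case).sum() == 0:
        raise ValueError("need both cases and controls")
    d = pn - po
    val = d[case].mean() - d[~case].mean()
    se = np.sqrt(d[case].var(ddof=1) / case.sum()
                 + d[~case].var(ddof=1) / (~case).sum())
    p = float(2 * stats.norm.sf(abs(val) / se)) if se > 0 else 1.0
    return 100.0 * float(val), p


# ----------------------------------------------------------------------
# Calibration
# ----------------------------------------------------------------------

def calibration_gb(fit: CoxFit, groups: int = 5):
    """Gronnesby-Borgan calibration (May-Hosmer form).

    Participants are grouped by quintiles of the ranks of their estimated
    risk; observed events per group are compared with martingale-based
    expected counts (per-group z = (O-E)/sqrt(E)); the overall statistic is
    the score test for adding the group indicators to the fitted model,
    chi-square with groups-1 df.
    """
    n = fit.n
    if n < 2 * groups:
        raise ValueError("too few participants for the requested groups")
    h0 = breslow_baseline(fit)
    lp = np.clip(fit.linear_predictor, -500, 500)
    expected_i = h0.cumhaz_at(fit.times) * np.exp(lp)
    ranks = stats.rankdata(lp, method="ordinal")
    grp = np.minimum((groups * (ranks - 1) / n).astype(int), groups - 1)
    rows = []
    U = np.zeros(groups)
    for g in range(groups):
        m = grp == g
        if not m.any():
            raise ValueError(f"empty risk group {g}")
        O = float(fit.events[m].sum())
        E = float(expected_i[m].sum())
        z = (O - E) / np.sqrt(E) if E > 0 else 0.0
        rows.append({"group": g + 1, "n": int(m.sum()), "observed": O,
                     "expected": E, "p": float(2 * stats.norm.sf(abs(z)))})
        U[g] = O - E
    # score test on the augmented design [X, first groups-1 indicators]
    D = np.zeros((n, groups - 1))
    for g in range(groups - 1):
        D[grp == g, g] = 1.0
    Xa = np.hstack([fit.X, D])
    pl = _PartialLikelihood(fit.times, fit.events, Xa, fit.ties)
    _, grad, hess = pl.evaluate(np.concatenate([fit.coef, np.zeros(groups - 1)]))
    info = -hess
    p0 = fit.X.shape[1]
    Ixx = info[:p0, :p0]
    Igg = info[p0:, p0:]
    Igx = info[p0:, :p0]
    V = Igg - Igx @ np.linalg.pinv(Ixx) @ Igx.T
    u = grad[p0:]
    chi2 = float(u @ np.linalg.pinv(V) @ u)
    overall_p = float(stats.chi2.sf(chi2, groups - 1))
    return pd.DataFrame(rows), chi2, overall_p


# ----------------------------------------------------------------------
# Model comparison & collinearity
# ----------------------------------------------------------------------

def aic_value(neg2loglik: float, n_coef: int) -> float:
    """AIC = -2 log (partial) likelihood + 2 x number of coefficients."""
    return float(neg2loglik) + 2.0 * int(n_coef)


def aic(fit: CoxFit) -> float:
    """AIC of a Cox fit from its -2 log partial likelihood."""
    return aic_value(fit.neg2_loglik, len(fit.coef))


def model_compare(base: CoxFit, augmented: CoxFit):
    """AIC pair and likelihood-ratio test of nested Cox models."""
    if base.n != augmented.n or base.n_events != augmented.n_events:
        raise ValueError("models must be fitted on identical rows")
    df = len(augmented.coef) - len(base.coef)
    lr = base.neg2_loglik - augmented.neg2_loglik
    if df < 0 or (df == 0 and abs(lr) > 1e-9):
        raise ValueError("models are not nested (augmented must extend base)")
    if df == 0 or abs(lr) < 1e-12:
        return {"aic_base": aic(base), "aic_augmented": aic(augmented),
                "lr": 0.0, "df": df, "p": 1.0}
    return {"aic_base": aic(base), "aic_augmented": aic(augmented),
            "lr": float(lr), "df": df, "p": float(stats.chi2.sf(lr, df))}


def collinearity(design: pd.DataFrame, added_cols: Sequence[str]):
    """VIF and tolerance of each added column against the full design."""
    X = design.dropna()
    rows = []
    for col in added_cols:
        y = X[col].to_numpy(float)
        others = X.drop(columns=[col]).to_numpy(float)
        A = np.column_stack([np.ones(len(X)), others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_tot = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 0.0
        if r2 > 1 - 1e-10:
            raise ValueError(f"perfect collinearity for {col}")
        rows.append({"column": col, "vif": 1.0 / (1.0 - r2),
                     "tolerance": 1.0 - r2, "r_squared": r2})
    return pd.DataFrame(rows)


def score_model_design(cohort: pd.DataFrame, methylation: Optional[pd.DataFrame] = None,
                       add_cpgs: Sequence[str] = (), include_batch: bool = True) -> pd.DataFrame:
    """Design for the SCORE fatal-CVD model: age, sex, systolic blood
    pressure, current smoking, total cholesterol (+ batch dummies), optionally
    augmented with CpG beta-value columns."""
    df = pd.DataFrame({
        "age": cohort["age"].astype(float),
        "male": (cohort["sex"] == "male").astype(float).where(cohort["sex"].notna()),
        "systolic_bp": cohort["systolic_bp"].astype(float),
        "current_smoker": (cohort["smoking_status"] == "current").astype(float)
                          .where(cohort["smoking_status"].notna()),
        "total_cholesterol": cohort["total_cholesterol"].astype(float),
    })
    if include_batch:
        b = cohort["batch"]
        for lev in sorted(b.dropna().unique())[1:]:
            df[f"batch[{lev}]"] = (b == lev).astype(float).where(b.notna())
    for cpg in add_cpgs:
        df[cpg] = methylation[cpg].astype(float).to_numpy()
    return df
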