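"""Proportional-hazards diagnostics from martingale residuals.

The primary check follows the cumulative martingale-residual (score-process)
approach: the observed score process over follow-up time is compared with
resampled realisations of its null distribution, generated by multiplying the
per-subject martingale increments by standard-normal weights and correcting
for the estimation of beta. The p-value is the fraction of resampled supremum
statistics exceeding the observed one.

A cheap scaled-Schoenfeld correlation test (residuals vs event rank) is also
provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
import pandas as pd
from scipy import stats

from .cox import CoxFit


@dataclass
class PHDiagnostic:
    covariate: str
    statistic: float
    p_value: float
    method: str


def martingale_residuals(fit: CoxFit) -> np.ndarray:
    """Per-subject martingale residual dN_i - H0(t_i) exp(lp_i); sums to ~0."""
    from .cox import breslow_baseline
    h0 = breslow_baseline(fit)
    lp = np.clip(fit.linear_predictor, -500, 500)
    return fit.events - h0.cumhaz_at(fit.times) * np.exp(lp)


def _score_process_parts(fit: CoxFit):
    """Per-subject score-process increments at each distinct event time.

    Returns (A, info_cum, ev_times) where A[i, j, :] is subject i's
    contribution d integral (x_i - xbar(t_j)) dM_i(t_j) and info_cum[j] the
    information accumulated through event time j.
    """
    order = np.argsort(fit.times, kind="stable")
    t, d, X = fit.times[order], fit.events[order], fit.X[order]
    n, p = X.shape
    w = np.exp(np.clip(X @ fit.coef, -500, 500))
    ev_times = np.unique(t[d == 1])
    T = len(ev_times)
    starts = np.searchsorted(t, ev_times, side="left")
    c0 = np.cumsum(w[::-1])[::-1]
    c1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
    A = np.zeros((n, T, p))
    info_cum = np.zeros((T, p, p))
    info = np.zeros((p, p))
    for j, (te, f) in enumerate(zip(ev_times, starts)):
        S0 = c0[f]
        xbar = c1[f] / S0
        dead = (t == te) & (d == 1)
        dj = dead.sum()
        dh0 = dj / S0
        at_risk = t >= te
        dev = X - xbar[None, :]
        # observed-event part minus compensator part
        A[dead, j, :] += dev[dead]
        A[at_risk, j, :] -= (w[at_risk] * dh0)[:, None] * dev[at_risk]
        wxx = (w[at_risk, None] * X[at_risk]).T @ X[at_risk]
        v = wxx / S0 - np.outer(xbar, xbar)
        info += dj * v
        info_cum[j] = info
    return A, info_cum, ev_times


def martingale_ph_check(fit: CoxFit, n_resample: int = 1000,
                        seed: int = 0) -> List[PHDiagnostic]:
    """Supremum test of the cumulative score process per covariate."""
    A, info_cum, ev_times = _score_process_parts(fit)
    n, T, p = A.shape
    info_tot = info_cum[-1]
    info_tot_inv = np.linalg.pinv(info_tot)
    # observed process: cumulative sum over event times of column sums of A
    obs_path = np.cumsum(A.sum(axis=0), axis=0)          # T x p
    scale = np.sqrt(np.maximum(np.diag(info_tot), 1e-300))
    obs_sup = np.abs(obs_path).max(axis=0) / scale

    rng = np.random.default_rng(seed)
    G = rng.standard_normal((n_resample, n))
    flatA = A.reshape(n, T * p)
    paths = np.cumsum((G @ flatA).reshape(n_resample, T, p), axis=1)
    totals = paths[:, -1, :]                              # B x p
    # correct for estimation of beta: W(t) = U*(t) - I(t) I(tau)^-1 U*(tau)
    corr = np.einsum("tpq,bq->btp", info_cum @ info_tot_inv, totals)
    paths = paths - corr
    sups = np.abs(paths).max(axis=1) / scale[None, :]     # B x p
    out = []
    for j, name in enumerate(fit.names):
        pval = float((sups[:, j] >= obs_sup[j] - 1e-12).mean())
        out.append(PHDiagnostic(name, float(obs_sup[j]), pval,
                                "cumulative-martingale supremum"))
    return out


def schoenfeld_ph_check(fit: CoxFit) -> List[PHDiagnostic]:
    """Correlation of scaled Schoenfeld-type residuals with event rank."""
    order = np.argsort(fit.times, kind="stable")
    t, d, X = fit.times[order], fit.events[order], fit.X[order]
    w = np.exp(np.clip(X @ fit.coef, -500, 500))
    c0 = np.cumsum(w[::-1])[::-1]
    c1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
    ev = np.flatnonzero(d == 1)
    resid = []
    for i in ev:
        f = np.searchsorted(t, t[i], side="left")
        resid.append(X[i] - c1[f] / c0[f])
    resid = np.asarray(resid)
    ranks = stats.rankdata(t[ev])
    out = []
    for j, name in enumerate(fit.names):
        if resid[:, j].std() == 0:
            out.append(PHDiagnostic(name, 0.0, 1.0, "schoenfeld-rank"))
            continue
        r, p = stats.pearsonr(resid[:, j], ranks)
        z = r * np.sqrt(len(ev) - 2) / np.sqrt(max(1 - r * r, 1e-12))
        out.append(PHDiagnostic(name, float(z * z),
                                float(2 * stats.norm.sf(abs(z))), "schoenfeld-rank"))
    return out
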