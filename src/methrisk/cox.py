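"""Cox proportional-hazards fitting by Newton-Raphson on the partial likelihood.

Breslow (default) and Efron handling of tied event times, observed-information
covariance, Breslow baseline cumulative hazard, and per-SD hazard ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy import stats


def _as_design(design):
    if isinstance(design, pd.DataFrame):
        return design.to_numpy(dtype=float), list(design.columns)
    X = np.atleast_2d(np.asarray(design, dtype=float))
    if X.shape[0] == 1 and X.size > X.shape[1]:
        X = X.T
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{j}" for j in range(X.shape[1])]


@dataclass
class CoxFit:
    names: List[str]
    coef: np.ndarray
    cov: np.ndarray
    neg2_loglik: float
    neg2_loglik_null: float
    ties: str
    converged: bool
    n: int
    n_events: int
    n_dropped: int
    times: np.ndarray = field(repr=False)
    events: np.ndarray = field(repr=False)
    X: np.ndarray = field(repr=False)

    @property
    def linear_predictor(self) -> np.ndarray:
        return self.X @ self.coef

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def summary(self) -> pd.DataFrame:
        se = self.se
        z = np.divide(self.coef, se, out=np.zeros_like(se), where=se > 0)
        clip = lambda v: np.exp(np.clip(v, -700, 700))
        return pd.DataFrame({
            "coef": self.coef,
            "hr": clip(self.coef),
            "se": se,
            "hr_low": clip(self.coef - 1.96 * se),
            "hr_high": clip(self.coef + 1.96 * se),
            "p": 2 * stats.norm.sf(np.abs(z)),
        }, index=self.names)


class _PartialLikelihood:
    """Log partial likelihood, gradient and information on sorted data."""

    def __init__(self, times, events, X, ties):
        order = np.argsort(times, kind="stable")
        self.t = times[order]
        self.d = events[order]
        self.X = X[order]
        self.ties = ties
        ev = self.d == 1
        self.event_times = np.unique(self.t[ev])
        # first sorted index of each distinct event time = start of risk set
        self.risk_start = np.searchsorted(self.t, self.event_times, side="left")
        # indices of tied death sets
        self.death_idx = [np.flatnonzero((self.t == te) & ev)
                          for te in self.event_times]

    def evaluate(self, beta, want_hess=True):
        X, t, d = self.X, self.t, self.d
        n, p = X.shape
        lp = X @ beta
        lp = np.clip(lp, -500, 500)
        w = np.exp(lp)
        wx = w[:, None] * X
        # suffix sums over the ascending-time ordering
        c0 = np.cumsum(w[::-1])[::-1]
        c1 = np.cumsum(wx[::-1], axis=0)[::-1]
        if want_hess:
            wxx = wx[:, :, None] * X[:, None, :]
            c2 = np.cumsum(wxx[::-1], axis=0)[::-1]
        ll = float(lp[d == 1].sum())
        grad = X[d == 1].sum(axis=0).astype(float)
        hess = np.zeros((p, p))
        for j, f in enumerate(self.risk_start):
            di = self.death_idx[j]
            dj = len(di)
            S0, S1 = c0[f], c1[f]
            S2 = c2[f] if want_hess else None
            if self.ties == "breslow" or dj == 1:
                ll -= dj * np.log(S0)
                grad -= dj * S1 / S0
                if want_hess:
                    xb = S1 / S0
                    hess -= dj * (S2 / S0 - np.outer(xb, xb))
            else:  # efron
                s0d = w[di].sum()
                s1d = wx[di].sum(axis=0)
                s2d = wxx[di].sum(axis=0) if want_hess else None
                for l in range(dj):
                    f0 = S0 - (l / dj) * s0d
                    f1 = S1 - (l / dj) * s1d
                    ll -= np.log(f0)
                    grad -= f1 / f0
                    if want_hess:
                        f2 = S2 - (l / dj) * s2d
                        xb = f1 / f0
                        hess -= f2 / f0 - np.outer(xb, xb)
        return ll, grad, hess


def fit_cox(times, events, design, ties: str = "breslow",
            tol_score: float = 1e-8, tol_loglik: float = 1e-10,
            max_iter: int = 60) -> CoxFit:
    """Maximum partial-likelihood Cox fit on complete cases.

    Columns with no variation get coefficient 0 (pseudo-inverse Newton
    step); a monotone likelihood (runaway coefficients) is flagged as
    non-convergence rather than raised.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")
    X, names = _as_design(design)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    keep = np.isfinite(times) & np.isfinite(X).all(axis=1)
    n_dropped = int((~keep).sum())
    times, events, X = times[keep], events[keep], X[keep]
    if events.sum() < 1:
        raise ValueError("need at least one event")
    varying = X.std(axis=0) > 0
    if varying.any():
        if np.linalg.matrix_rank(X[:, varying]) < varying.sum():
            raise ValueError("rank-deficient design")

    pl = _PartialLikelihood(times, events, X, ties)
    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = pl.evaluate(beta)
    ll_null = ll
    converged = False
    for _ in range(max_iter):
        info = -hess
        step = np.linalg.pinv(info) @ grad
        new_beta = beta + step
        new_ll, new_grad, new_hess = pl.evaluate(new_beta)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new_ll, new_grad, new_hess = pl.evaluate(new_beta)
            halvings += 1
        rel = abs(new_ll - ll) / max(abs(ll), 1.0)
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.abs(grad).max() < tol_score or rel < tol_loglik:
            converged = True
            break
    if np.abs(beta).max() > 20:
        converged = False  # monotone likelihood / separation
    cov = np.linalg.pinv(-hess)
    return CoxFit(names, beta, cov, -2.0 * ll, -2.0 * ll_null, ties,
                  converged, len(times), int(events.sum()), n_dropped,
                  times, events, X)


@dataclass
class BaselineHazard:
    """Breslow step-function estimate of the cumulative baseline hazard."""

    times: np.ndarray
    cumhaz: np.ndarray
    last_time: float

    def cumhaz_at(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        out = np.zeros(t.shape)
        pos = idx > 0
        out[pos] = self.cumhaz[idx[pos] - 1]
        return out

    def extrapolates(self, horizon: float) -> bool:
        return horizon > self.last_time


def breslow_baseline(fit: CoxFit) -> BaselineHazard:
    """H0(t) = sum over event times <= t of d_j / sum_{at risk} exp(lp)."""
    order = np.argsort(fit.times, kind="stable")
    t, d = fit.times[order], fit.events[order]
    w = np.exp(np.clip(fit.X[order] @ fit.coef, -500, 500))
    c0 = np.cumsum(w[::-1])[::-1]
    ev_times = np.unique(t[d == 1])
    starts = np.searchsorted(t, ev_times, side="left")
    dj = np.array([((t == te) & (d == 1)).sum() for te in ev_times], dtype=float)
    inc = dj / c0[starts]
    return BaselineHazard(ev_times, np.cumsum(inc), float(t.max()))


def per_sd_hr(fit: CoxFit, column: str, sd: Optional[float] = None):
    """Hazard ratio (with 95% CI) for a one-SD *decrease* in a covariate.

    ``sd`` defaults to the cohort SD of the fitted column; the result is
    invariant to the units the column was stored in.
    """
    j = fit.names.index(column)
    if sd is None:
        sd = float(fit.X[:, j].std(ddof=1))
    if sd <= 0:
        raise ValueError("zero standard deviation")
    c = -fit.coef[j] * sd
    se = fit.se[j] * sd
    return {
        "hr": float(np.exp(c)),
        "ci_low": float(np.exp(c - 1.96 * se)),
        "ci_high": float(np.exp(c + 1.96 * se)),
        "p": float(2 * stats.norm.sf(abs(c) / se)) if se > 0 else 1.0,
    }
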