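"""Kaplan-Meier product-limit estimation and the log-rank test."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class KMCurve:
    """Product-limit survival estimate with Greenwood variance.

    Arrays are aligned over the distinct event times; the estimate starts at
    S=1 before the first event and changes only at event times.
    """

    event_times: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray

    def survival_at(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right")
        out = np.ones(t.shape)
        pos = idx > 0
        out[pos] = self.survival[idx[pos] - 1]
        return out


def _km_single(times: np.ndarray, events: np.ndarray) -> KMCurve:
    order = np.argsort(times, kind="stable")
    t, d = times[order], events[order]
    ev_times = np.unique(t[d == 1])
    n = len(t)
    at_risk = np.empty(len(ev_times), dtype=int)
    n_ev = np.empty(len(ev_times), dtype=int)
    for j, te in enumerate(ev_times):
        at_risk[j] = int((t >= te).sum())
        n_ev[j] = int(((t == te) & (d == 1)).sum())
    frac = 1.0 - n_ev / at_risk
    surv = np.cumprod(frac)
    # Greenwood: var(S) = S^2 * cumsum(d / (r (r - d)))
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where(at_risk > n_ev, n_ev / (at_risk * (at_risk - n_ev)), np.inf)
        gw = np.where(surv > 0, surv ** 2 * np.cumsum(inc), 0.0)
    return KMCurve(ev_times, at_risk, n_ev, surv, gw)


def kaplan_meier(times, events, groups=None):
    """KM curve overall or per group; returns KMCurve or dict of them."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times <= 0).any():
        raise ValueError("times must be positive")
    if groups is None:
        return _km_single(times, events)
    g = pd.Series(groups, dtype=object)
    out: Dict[object, KMCurve] = {}
    for lev in pd.unique(g.dropna()):
        mask = (g == lev).to_numpy()
        if not mask.any():
            raise ValueError(f"empty group {lev!r}")
        out[lev] = _km_single(times[mask], events[mask])
    if not out:
        raise ValueError("no nonempty groups")
    return out


def logrank(times, events, groups):
    """K-sample log-rank test: (chi-square, df, p).

    Observed-minus-expected events across pooled event times, hypergeometric
    variance, quadratic form over the first k-1 groups.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    g = pd.Series(groups, dtype=object)
    keep = g.notna().to_numpy()
    times, events, g = times[keep], events[keep], g[keep]
    levels = list(pd.unique(g))
    k = len(levels)
    if k < 2:
        raise ValueError("need >=2 groups")
    if events.sum() == 0:
        raise ValueError("no events")
    gi = np.array([levels.index(x) for x in g])
    ev_times = np.unique(times[events == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for te in ev_times:
        at_risk = times >= te
        n_tot = at_risk.sum()
        d_tot = ((times == te) & (events == 1)).sum()
        n_g = np.bincount(gi[at_risk], minlength=k).astype(float)
        d_g = np.bincount(gi[(times == te) & (events == 1)], minlength=k).astype(float)
        O += d_g
        E += d_tot * n_g / n_tot
        if n_tot > 1:
            p = n_g / n_tot
            mult = d_tot * (n_tot - d_tot) / (n_tot - 1)
            V += mult * (np.diag(p) - np.outer(p, p))
    u = (O - E)[:-1]
    Vr = V[:-1, :-1]
    if np.allclose(u, 0.0):
        chi2 = 0.0
    else:
        chi2 = float(u @ np.linalg.pinv(Vr) @ u)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return chi2, df, p
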