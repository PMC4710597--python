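"""L1-penalised Cox regression by cyclic coordinate descent.

Penalised coefficients are soft-thresholded Newton coordinate updates on the
Breslow partial likelihood; unpenalised covariates (age, sex, ...) are never
thresholded. The penalty parameter is chosen by K-fold cross-validated
partial likelihood (Verweij-van Houwelingen), and the selected variable set
is the support of the penalised coefficients at the chosen lambda.

Covariates are not standardised internally; the nine CpG beta-values share
the [0,1] scale, so a common lambda is meaningful across them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd

from .cox import _PartialLikelihood, _as_design


def _soft(z: float, lam: float) -> float:
    return np.sign(z) * max(abs(z) - lam, 0.0)


class _CDWorkspace:
    """Sorted-data workspace for coordinate updates (Breslow ties)."""

    def __init__(self, times, events, X):
        order = np.argsort(times, kind="stable")
        self.t = times[order]
        self.d = events[order]
        self.X = X[order]
        ev = self.d == 1
        self.event_times = np.unique(self.t[ev])
        self.starts = np.searchsorted(self.t, self.event_times, side="left")
        self.dj = np.array([((self.t == te) & ev).sum()
                            for te in self.event_times], dtype=float)
        self.x_event_sum = self.X[ev].sum(axis=0)

    def grad_hess_j(self, w: np.ndarray, j: int):
        xj = self.X[:, j]
        c0 = np.cumsum(w[::-1])[::-1][self.starts]
        c1 = np.cumsum((w * xj)[::-1])[::-1][self.starts]
        c2 = np.cumsum((w * xj * xj)[::-1])[::-1][self.starts]
        m = c1 / c0
        g = self.x_event_sum[j] - float(self.dj @ m)
        h = float(self.dj @ (c2 / c0 - m * m))
        return g, h

    def loglik(self, beta: np.ndarray) -> float:
        lp = np.clip(self.X @ beta, -500, 500)
        w = np.exp(lp)
        c0 = np.cumsum(w[::-1])[::-1][self.starts]
        return float(lp[self.d == 1].sum() - self.dj @ np.log(c0))


def _cd_fit(ws: _CDWorkspace, lam: float, penalized: np.ndarray,
            beta0: np.ndarray, tol: float = 1e-9, max_sweeps: int = 500):
    beta = beta0.copy()
    lp = np.clip(ws.X @ beta, -500, 500)
    for _ in range(max_sweeps):
        delta_max = 0.0
        for j in range(len(beta)):
            w = np.exp(lp)
            g, h = ws.grad_hess_j(w, j)
            if h <= 1e-12:
                continue
            z = h * beta[j] + g
            new = _soft(z, lam) / h if penalized[j] else z / h
            change = new - beta[j]
            if change != 0.0:
                lp = np.clip(lp + ws.X[:, j] * change, -500, 500)
                beta[j] = new
                delta_max = max(delta_max, abs(change))
        if delta_max < tol:
            break
    return beta


@dataclass
class PenalizedCoxPath:
    names: List[str]
    penalized: np.ndarray            # bool mask over columns
    lambdas: np.ndarray
    coefs: np.ndarray                # len(lambdas) x p
    cv_loglik: np.ndarray
    best_lambda: float
    selected: List[str]

    def n_nonzero(self) -> np.ndarray:
        return (np.abs(self.coefs[:, self.penalized]) > 0).sum(axis=1)


def default_lambda_grid(times, events, design, penalized_cols,
                        n_lambda: int = 25, ratio: float = 3e-3) -> np.ndarray:
    """Decreasing log-spaced grid from the smallest lambda that zeroes all
    penalised coefficients at beta=0."""
    X, names = _as_design(design)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    pl = _PartialLikelihood(times, events, X, "breslow")
    _, grad, _ = pl.evaluate(np.zeros(X.shape[1]), want_hess=False)
    pen = np.array([n in set(penalized_cols) for n in names])
    lam_max = float(np.abs(grad[pen]).max()) * 1.05
    return lam_max * np.logspace(0, np.log10(ratio), n_lambda)


def fit_penalized_cox(times, events, design, penalized_cols: Sequence[str],
                      lambdas=None, cv_folds: int = 5,
                      seed: int = 0) -> PenalizedCoxPath:
    """Fit the lasso path and select lambda by cross-validated partial likelihood."""
    X, names = _as_design(design)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    keep = np.isfinite(times) & np.isfinite(X).all(axis=1)
    times, events, X = times[keep], events[keep], X[keep]
    pen = np.array([n in set(penalized_cols) for n in names])
    if not pen.any():
        raise ValueError("no penalized columns")
    if lambdas is None:
        lambdas = default_lambda_grid(times, events,
                                      pd.DataFrame(X, columns=names), penalized_cols)
    lambdas = np.asarray(lambdas, dtype=float)
    if (lambdas < 0).any() or (np.diff(lambdas) >= 0).any():
        raise ValueError("lambda grid must be nonnegative and strictly decreasing")

    ws_full = _CDWorkspace(times, events, X)
    p = X.shape[1]

    # full-data path with warm starts
    coefs = np.zeros((len(lambdas), p))
    beta = np.zeros(p)
    for i, lam in enumerate(lambdas):
        beta = _cd_fit(ws_full, lam, pen, beta)
        coefs[i] = beta

    # cross-validated partial likelihood (Verweij-van Houwelingen)
    rng = np.random.default_rng(seed)
    fold = rng.permuted(np.arange(len(times)) % cv_folds)
    cvpl = np.zeros(len(lambdas))
    for kf in range(cv_folds):
        tr = fold != kf
        ws_tr = _CDWorkspace(times[tr], events[tr], X[tr])
        beta = np.zeros(p)
        for i, lam in enumerate(lambdas):
            beta = _cd_fit(ws_tr, lam, pen, beta)
            cvpl[i] += ws_full.loglik(beta) - ws_tr.loglik(beta)
    if not np.isfinite(cvpl).all():
        raise RuntimeError("cross-validated partial likelihood not finite")
    best = int(np.argmax(cvpl))
    selected = [names[j] for j in range(p)
                if pen[j] and abs(coefs[best, j]) > 0]
    return PenalizedCoxPath(names, pen, lambdas, coefs, cvpl,
                            float(lambdas[best]), selected)
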