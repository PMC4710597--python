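"""Restricted cubic spline basis (natural spline, truncated-power form).

For knots t1 < ... < tk the basis is the linear term x plus k-2 nonlinear
columns

    S_j(x) = [ (x-tj)+^3
               - (x-t_{k-1})+^3 (tk-tj)/(tk-t_{k-1})
               + (x-tk)+^3 (t_{k-1}-tj)/(tk-t_{k-1}) ] / (tk-t1)^2

which is cubic between the boundary knots and exactly linear outside them.
The (tk-t1)^2 scaling keeps the columns on the scale of x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SplineBasis:
    knots: np.ndarray
    basis: np.ndarray          # n x (k-1): linear column first
    column_names: list

    @property
    def k(self) -> int:
        return len(self.knots)


def default_knots(x, k: int = 4) -> np.ndarray:
    """Knots at equally-spaced tail quantiles of the exposed values.

    Four knots at the 5/35/65/95th percentiles by default (standard
    placement); the paper does not state its knot scheme.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if k == 3:
        probs = [0.10, 0.50, 0.90]
    elif k == 4:
        probs = [0.05, 0.35, 0.65, 0.95]
    elif k == 5:
        probs = [0.05, 0.275, 0.50, 0.725, 0.95]
    else:
        probs = np.linspace(0.05, 0.95, k)
    knots = np.quantile(x, probs)
    if len(np.unique(knots)) != len(knots):
        raise ValueError("degenerate exposure distribution: duplicate knots")
    return knots


def rcs_basis(x, knots) -> SplineBasis:
    x = np.asarray(x, dtype=float)
    knots = np.sort(np.asarray(knots, dtype=float))
    k = len(knots)
    if k < 3:
        raise ValueError("restricted cubic splines need at least 3 knots")
    if len(np.unique(knots)) != k:
        raise ValueError("duplicate knots")
    tk, tk1, t1 = knots[-1], knots[-2], knots[0]
    scale = (tk - t1) ** 2
    cols = [x]
    names = ["x"]
    pos3 = lambda v: np.clip(v, 0.0, None) ** 3
    for j in range(k - 2):
        tj = knots[j]
        col = (pos3(x - tj)
               - pos3(x - tk1) * (tk - tj) / (tk - tk1)
               + pos3(x - tk) * (tk1 - tj) / (tk - tk1)) / scale
        cols.append(col)
        names.append(f"x_s{j+1}")
    return SplineBasis(knots, np.column_stack(cols), names)
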