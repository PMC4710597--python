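"""Stratified summaries, group tests, inter-CpG correlations, incidence rates."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class StratifiedSummary:
    stratum: str
    n: int
    percent: float
    median: float
    q1: float
    q3: float
    n_missing: int


def stratified_medians(values: Sequence[float], strata: Sequence,
                       order: Sequence | None = None) -> pd.DataFrame:
    """Median (Q1-Q3) of ``values`` per stratum, missing values excluded.

    Percentages are of participants with a non-missing stratum label.
    Quantiles are type-7 (linear interpolation), used consistently package-wide.
    """
    vals = np.asarray(values, dtype=float)
    lab = pd.Series(strata, dtype=object)
    keep = lab.notna().to_numpy()
    vals, lab = vals[keep], lab[keep]
    levels = list(order) if order is not None else sorted(pd.unique(lab))
    total = len(lab)
    rows = []
    for lev in levels:
        in_s = (lab == lev).to_numpy()
        if not in_s.any():
            raise ValueError(f"empty stratum {lev!r}")
        v = vals[in_s]
        ok = np.isfinite(v)
        if not ok.any():
            raise ValueError(f"stratum {lev!r} has no non-missing values")
        q1, med, q3 = np.quantile(v[ok], [0.25, 0.5, 0.75])
        rows.append(StratifiedSummary(str(lev), int(in_s.sum()),
                                      100.0 * in_s.sum() / total,
                                      float(med), float(q1), float(q3),
                                      int((~ok).sum())))
    return pd.DataFrame([r.__dict__ for r in rows])


def kruskal_wallis(values: Sequence[float], strata: Sequence) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p across strata."""
    vals = np.asarray(values, dtype=float)
    lab = pd.Series(strata, dtype=object)
    keep = lab.notna().to_numpy() & np.isfinite(vals)
    vals, lab = vals[keep], lab[keep]
    groups = [vals[(lab == lev).to_numpy()] for lev in pd.unique(lab)]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >=2 nonempty groups")
    if all(np.array_equal(g, groups[0]) for g in groups[1:]) and all(
            np.ptp(g) == 0 for g in groups):
        # scipy raises on all-identical data; H is 0 by definition
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def kruskal_wallis_permutation_p(values, strata, n_perm: int = 10000,
                                 seed: int = 0) -> float:
    """Permutation reference p-value for the H statistic (test oracle)."""
    vals = np.asarray(values, dtype=float)
    lab = np.asarray(strata, dtype=object)
    h_obs, _ = kruskal_wallis(vals, lab)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        h, _ = kruskal_wallis(vals, rng.permutation(lab))
        if h >= h_obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def spearman_matrix(methylation: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Spearman correlations among the CpG columns."""
    cols = [c for c in methylation.columns if c != "participant_id"]
    sub = methylation[cols]
    if (sub.notna().sum() == 0).any():
        bad = [c for c in cols if sub[c].notna().sum() == 0]
        raise ValueError(f"all-missing CpG column(s): {bad}")
    mat = sub.corr(method="spearman", min_periods=3)
    return mat


@dataclass
class RateEstimate:
    cases: int
    person_years: float
    rate: float  # per 100 person-years

    def rounded(self, ndigits: int = 2) -> float:
        return round(self.rate, ndigits)


def incidence_rate(cases: int, person_years: float) -> RateEstimate:
    """Incidence rate per 100 person-years."""
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    if cases < 0:
        raise ValueError("cases must be nonnegative")
    return RateEstimate(int(cases), float(person_years),
                        100.0 * cases / person_years)


def rates_by_group(time, event, groups) -> pd.DataFrame:
    """Cases, person-years and IR per group label (missing labels dropped)."""
    df = pd.DataFrame({"time": np.asarray(time, float),
                       "event": np.asarray(event, int),
                       "g": pd.Series(groups, dtype=object)}).dropna(subset=["g"])
    rows = []
    for lev, sub in df.groupby("g", sort=True):
        r = incidence_rate(int(sub["event"].sum()), float(sub["time"].sum()))
        rows.append({"group": lev, "n": len(sub), "cases": r.cases,
                     "person_years": r.person_years, "rate_per_100py": r.rate})
    return pd.DataFrame(rows)
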