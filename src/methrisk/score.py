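"""Quartile flags and the two-CpG 0/1/2 methylation score.

The score counts how many of cg05575921 (AHRR) and cg06126421 (6p21.33)
fall in their lowest cohort quartile: 2 = both, 1 = one, 0 = neither.
It is rank-based, hence invariant to monotone transforms of a CpG column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SCORE_CPGS


@dataclass
class QuartileAssignment:
    """Per-participant quartile index (1-4) per CpG plus the cutoffs used.

    Quartile cutoffs are type-7 (linear-interpolation) quantiles of all
    non-missing values; membership in the lowest quartile uses the closed
    boundary rule beta <= Q1. Degenerate columns (all values equal) place
    everyone in quartile 1 and are flagged.
    """

    quartiles: pd.DataFrame          # participant_id + one int column per CpG (NaN-able)
    cutoffs: pd.DataFrame            # index CpG, columns Q1/Q2/Q3
    degenerate: tuple


def assign_quartiles(methylation: pd.DataFrame, cpgs=None) -> QuartileAssignment:
    cpgs = list(cpgs) if cpgs is not None else [
        c for c in methylation.columns if c != "participant_id"]
    out = pd.DataFrame({"participant_id": methylation["participant_id"].to_numpy()})
    cut_rows = {}
    degenerate = []
    for c in cpgs:
        vals = methylation[c].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        if ok.sum() < 4:
            raise ValueError(f"CpG {c}: need >=4 non-missing values to form quartiles")
        q1, q2, q3 = np.quantile(vals[ok], [0.25, 0.5, 0.75])
        cut_rows[c] = (q1, q2, q3)
        if vals[ok].min() == vals[ok].max():
            degenerate.append(c)
        idx = np.full(len(vals), np.nan)
        idx[ok] = 4.0
        idx[ok & (vals <= q3)] = 3.0
        idx[ok & (vals <= q2)] = 2.0
        idx[ok & (vals <= q1)] = 1.0
        out[c] = idx
    cutoffs = pd.DataFrame.from_dict(cut_rows, orient="index",
                                     columns=["Q1", "Q2", "Q3"])
    return QuartileAssignment(out, cutoffs, tuple(degenerate))


def build_score(assignment: QuartileAssignment) -> pd.DataFrame:
    """The 0/1/2 score; missing if either score CpG is missing.

    Returns columns participant_id, low_cg05575921, low_cg06126421, score.
    """
    q = assignment.quartiles
    for c in SCORE_CPGS:
        if c not in q.columns:
            raise ValueError(f"quartiles missing for score CpG {c}")
    out = pd.DataFrame({"participant_id": q["participant_id"].to_numpy()})
    flags = []
    for c in SCORE_CPGS:
        v = q[c].to_numpy(dtype=float)
        f = np.where(np.isfinite(v), (v == 1.0).astype(float), np.nan)
        out[f"low_{c}"] = f
        flags.append(f)
    out["score"] = flags[0] + flags[1]   # NaN propagates
    return out


def joint_sex_score_classes(score: pd.DataFrame, cohort: pd.DataFrame) -> pd.Series:
    """Six-level sex x score cross-classification, e.g. 'male-2'.

    Missing sex or score yields a missing class.
    """
    merged = score.merge(cohort[["participant_id", "sex"]], on="participant_id",
                         how="left", validate="one_to_one")
    cls = [
        f"{sx}-{int(sc)}" if isinstance(sx, str) and np.isfinite(sc) else np.nan
        for sx, sc in zip(merged["sex"], merged["score"].astype(float))
    ]
    return pd.Series(cls, index=score.index, name="sex_score_class", dtype=object)
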