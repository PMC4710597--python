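"""Cox model covariate sets for the mortality analyses.

Model 1: age, sex, batch. Model 2: + smoking status (+ methylation score
when smoking is the exposure of interest, and vice versa). Model 3: + BMI
category, physical activity, systolic blood pressure, total cholesterol,
prevalent CVD/diabetes/cancer.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dose_response import _CAT_REFS


def _dummies(series: pd.Series, ref, prefix: str) -> pd.DataFrame:
    out = {}
    for lev in sorted(x for x in series.dropna().unique() if x != ref):
        out[f"{prefix}[{lev}]"] = (series == lev).astype(float).where(series.notna())
    return pd.DataFrame(out)


def cox_design(cohort: pd.DataFrame, model: int = 1,
               score: Optional[pd.Series] = None,
               score_as: str = "categories",
               smoking: bool = False,
               include_batch: bool = True) -> pd.DataFrame:
    """Design matrix for mortality models 1-3.

    ``score`` is the per-participant 0/1/2 methylation score (aligned with
    ``cohort``); as 'categories' it enters as two dummies against score 0,
    as 'linear' as one numeric column. ``smoking`` adds never/former/current
    status dummies (reference: never).
    """
    parts = [pd.DataFrame({
        "age": cohort["age"].astype(float),
        "male": (cohort["sex"] == "male").astype(float).where(cohort["sex"].notna()),
    })]
    if include_batch:
        parts.append(_dummies(cohort["batch"], sorted(cohort["batch"].dropna().unique())[0],
                              "batch"))
    if model >= 2:
        if smoking:
            parts.append(_dummies(cohort["smoking_status"], "never", "smoking"))
        if score is not None:
            s = pd.Series(np.asarray(score, dtype=float), index=cohort.index)
            if score_as == "categories":
                parts.append(pd.DataFrame({
                    "score[1]": (s == 1).astype(float).where(s.notna()),
                    "score[2]": (s == 2).astype(float).where(s.notna()),
                }))
            else:
                parts.append(pd.DataFrame({"score": s}))
    if model >= 3:
        parts.append(_dummies(cohort["bmi_category"], _CAT_REFS["bmi_category"], "bmi"))
        parts.append(_dummies(cohort["physical_activity"],
                              _CAT_REFS["physical_activity"], "activity"))
        parts.append(pd.DataFrame({
            "systolic_bp": cohort["systolic_bp"].astype(float),
            "total_cholesterol": cohort["total_cholesterol"].astype(float),
            "prevalent_cvd": cohort["prevalent_cvd"].astype(float),
            "prevalent_diabetes": cohort["prevalent_diabetes"].astype(float),
            "prevalent_cancer": cohort["prevalent_cancer"].astype(float),
        }))
    return pd.concat([p.reset_index(drop=True) for p in parts], axis=1)


def cause_specific_events(survival: pd.DataFrame, cause: str = "all",
                          unknown_cause: str = "censor") -> np.ndarray:
    """Event indicator for a cause-specific analysis.

    Competing causes are censored at the death time. Deaths with unknown
    cause are censored by default ('censor') or kept as events of every
    cause ('event').
    """
    ev = survival["event"].to_numpy(int)
    if cause == "all":
        return ev
    known = survival["cause_known"].to_numpy(int) == 1
    is_cause = (survival["cause"] == cause).to_numpy()
    out = (ev == 1) & known & is_cause
    if unknown_cause == "event":
        out |= (ev == 1) & ~known
    return out.astype(int)
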