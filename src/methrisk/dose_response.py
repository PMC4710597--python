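"""Adjusted linear models of methylation on smoking, and spline dose-response.

Covariate adjustment mirrors the cohort analysis: batch, age, sex, BMI
category, physical activity and prevalent CVD/diabetes/cancer. Exposure
enters either as smoking-status / dose-category dummies (linear models) or
as a restricted cubic spline (dose-response curves with pointwise Wald
confidence limits, difference vs the zero-exposure reference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .splines import SplineBasis, default_knots, rcs_basis

_CAT_REFS = {
    "bmi_category": "normal",
    "physical_activity": "sufficient",
}


def covariate_design(cohort: pd.DataFrame, include_batch: bool = True) -> pd.DataFrame:
    """Adjustment covariates as a numeric design (no intercept column).

    Categorical variables are dummy-coded against a registered reference
    level; batch enters as chip-level dummies. Rows with missing values keep
    NaN so callers can do complete-case selection.
    """
    parts = {
        "age": cohort["age"].astype(float),
        "male": (cohort["sex"] == "male").astype(float).where(cohort["sex"].notna()),
        "prevalent_cvd": cohort["prevalent_cvd"].astype(float),
        "prevalent_diabetes": cohort["prevalent_diabetes"].astype(float),
        "prevalent_cancer": cohort["prevalent_cancer"].astype(float),
    }
    df = pd.DataFrame(parts)
    for col, ref in _CAT_REFS.items():
        s = cohort[col]
        for lev in sorted(x for x in s.dropna().unique() if x != ref):
            df[f"{col}[{lev}]"] = (s == lev).astype(float).where(s.notna())
    if include_batch:
        b = cohort["batch"]
        levels = sorted(b.dropna().unique())
        for lev in levels[1:]:
            df[f"batch[{lev}]"] = (b == lev).astype(float).where(b.notna())
    return df


@dataclass
class EffectEstimate:
    term: str
    coefficient: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float


def fit_adjusted_ols(outcome, exposure_design: pd.DataFrame,
                     covariate_design_: pd.DataFrame):
    """OLS of ``outcome`` on exposure + covariates, complete cases.

    Returns (estimates DataFrame restricted to the exposure terms,
    statsmodels results, n_dropped).
    """
    y = pd.Series(np.asarray(outcome, dtype=float), name="y").reset_index(drop=True)
    X = pd.concat([exposure_design.reset_index(drop=True),
                   covariate_design_.reset_index(drop=True)], axis=1)
    keep = y.notna() & X.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    Xc = sm.add_constant(X[keep], has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise ValueError("rank-deficient design after complete-case selection")
    if keep.sum() <= Xc.shape[1]:
        raise ValueError("zero residual degrees of freedom")
    res = sm.OLS(y[keep], Xc).fit()
    rows = []
    for term in exposure_design.columns:
        ci = res.conf_int().loc[term]
        rows.append(EffectEstimate(term, float(res.params[term]),
                                   float(res.bse[term]), float(ci[0]),
                                   float(ci[1]), float(res.pvalues[term])))
    return pd.DataFrame([r.__dict__ for r in rows]), res, n_dropped


def smoking_exposure(cohort: pd.DataFrame, kind: str):
    """Exposure vector with the reference group coded 0, plus inclusion mask.

    'intensity':  current cigarettes/day; never and former smokers are the
                  reference at 0.
    'packyears':  cumulative pack-years; never smokers reference at 0.
    'cessation':  years since quitting among former smokers; current smokers
                  reference at 0 (never smokers excluded).
    """
    st = cohort["smoking_status"]
    if kind == "intensity":
        x = cohort["cigarettes_per_day"].astype(float).copy()
        x[st.isin(["never", "former"])] = 0.0
        include = st.notna()
        ref = st.isin(["never", "former"])
    elif kind == "packyears":
        x = cohort["pack_years"].astype(float).copy()
        x[st == "never"] = 0.0
        include = st.notna()
        ref = st == "never"
    elif kind == "cessation":
        x = cohort["years_since_cessation"].astype(float).copy()
        x[st == "current"] = 0.0
        include = st.isin(["former", "current"])
        ref = st == "current"
    else:
        raise ValueError(f"unknown exposure kind {kind!r}")
    if not (ref & include).any():
        raise ValueError(f"reference group empty for exposure {kind!r}")
    return x.to_numpy(dtype=float), include.to_numpy()


def dose_response_curve(outcome, exposure, covariate_design_: pd.DataFrame,
                        knots=None, grid=None):
    """Fitted spline curve of outcome vs exposure, as difference from x=0.

    Returns (curve DataFrame [x, estimate, lower, upper], SplineBasis,
    statsmodels results). The confidence band is pointwise Wald (1.96 SE)
    from the delta contrast against the reference exposure 0.
    """
    x = np.asarray(exposure, dtype=float)
    if np.nanmin(x) < 0:
        raise ValueError("exposure must be nonnegative")
    if knots is None:
        exposed = x[np.isfinite(x) & (x > 0)]
        knots = default_knots(exposed, k=4)
    sb: SplineBasis = rcs_basis(np.where(np.isfinite(x), x, 0.0), knots)
    spline_df = pd.DataFrame(sb.basis, columns=sb.column_names)
    spline_df[~np.isfinite(x)] = np.nan
    est, res, _ = fit_adjusted_ols(outcome, spline_df, covariate_design_)
    if grid is None:
        hi = np.nanquantile(x[x > 0], 0.98) if (x > 0).any() else 1.0
        grid = np.linspace(0.0, float(hi), 60)
    gb = rcs_basis(np.asarray(grid, float), knots).basis
    rb = rcs_basis(np.zeros(1), knots).basis
    contrast = gb - rb                       # difference vs reference x=0
    beta = res.params[sb.column_names].to_numpy()
    cov = res.cov_params().loc[sb.column_names, sb.column_names].to_numpy()
    fit_diff = contrast @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", contrast, cov, contrast))
    curve = pd.DataFrame({
        "x": np.asarray(grid, float),
        "estimate": fit_diff,
        "lower": fit_diff - 1.96 * se,
        "upper": fit_diff + 1.96 * se,
    })
    return curve, sb, res
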