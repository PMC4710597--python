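"""Synthetic cohort generator.

Emulates the joint structure the downstream analyses assume: smoking
behaviour with realistic intensity/pack-year/cessation distributions,
blood methylation beta-values at nine CpG sites whose means decline with
smoking exposure in a saturating fashion and recover after cessation,
copula-coupled inter-CpG correlation, and cause-specific mortality from a
Weibull proportional-hazards model driven by the two-CpG methylation score,
age and sex, with administrative censoring and a short recruitment stagger.

The generator is the ground truth for every recovery test: the hazard it
uses is known exactly, so Cox fits, selection procedures and evaluation
metrics can be checked against it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import CPG_SITES, SCORE_CPGS, CpGProfile, SimConfig

_REF_INTENSITY = 20.0   # cigarettes/day defining the "reference current smoker"
_REF_PACKYEARS = 30.0


def _sat(x: np.ndarray, half: float) -> np.ndarray:
    """Saturating dose curve in [0,1): half its plateau at ``half``."""
    return 1.0 - np.exp2(-np.asarray(x, dtype=float) / half)


def _recovery(ysc: np.ndarray, tau: float, permanent: float) -> np.ndarray:
    """Fraction of the smoking deficit remaining after ``ysc`` years abstinent."""
    return permanent + (1.0 - permanent) * np.exp(-np.asarray(ysc, dtype=float) / tau)


def _draw_exposures(rng: np.random.Generator, status: np.ndarray, age: np.ndarray):
    """Cigarettes/day, pack-years and years-since-cessation given status."""
    n = len(status)
    cpd = np.zeros(n)
    pack_years = np.zeros(n)
    ysc = np.full(n, np.nan)
    start_age = rng.uniform(15.0, 20.0, n)

    cur = status == "current"
    cpd_cur = np.clip(np.round(rng.gamma(4.0, 5.0, cur.sum())), 1, 60)
    cpd[cur] = cpd_cur
    dur_cur = np.maximum(age[cur] - start_age[cur], 1.0)
    pack_years[cur] = cpd_cur / 20.0 * dur_cur * rng.uniform(0.6, 1.0, cur.sum())

    fmr = status == "former"
    max_ysc = np.maximum(age[fmr] - start_age[fmr] - 2.0, 2.0)
    ysc_f = rng.uniform(1.0, np.minimum(35.0, max_ysc))
    ysc[fmr] = ysc_f
    cpd_hist = np.clip(np.round(rng.gamma(4.0, 5.0, fmr.sum())), 1, 60)
    dur_f = np.maximum(age[fmr] - start_age[fmr] - ysc_f, 1.0)
    pack_years[fmr] = cpd_hist / 20.0 * dur_f * rng.uniform(0.6, 1.0, fmr.sum())
    return cpd, pack_years, ysc


def _modulation_current(cpd, pack_years, dr) -> np.ndarray:
    s_int = _sat(cpd, dr.half_sat_intensity) / _sat(_REF_INTENSITY, dr.half_sat_intensity)
    s_py = _sat(pack_years, dr.half_sat_packyears) / _sat(_REF_PACKYEARS, dr.half_sat_packyears)
    return dr.intensity_weight * s_int + (1.0 - dr.intensity_weight) * s_py


def _modulation_former(pack_years, ysc, dr) -> np.ndarray:
    s_py = _sat(pack_years, dr.half_sat_packyears) / _sat(_REF_PACKYEARS, dr.half_sat_packyears)
    return s_py * _recovery(ysc, dr.recovery_tau, dr.permanent_fraction)


def _modulation_norms(config: SimConfig) -> Tuple[float, float]:
    """Mean exposure modulation among current / former smokers.

    Computed from a fixed internal quasi-sample of the generator's own
    exposure model so that a profile's ``current_offset`` equals the mean
    beta shift of the simulated current-smoker population (and likewise for
    former smokers), independent of the user seed.
    """
    rng = np.random.default_rng(987654321)
    m = 20000
    lo, hi = config.age_range
    age = rng.uniform(lo, hi, m)
    dr = config.dose_response_params
    status_c = np.full(m, "current")
    cpd, py, _ = _draw_exposures(rng, status_c, age)
    norm_cur = float(np.mean(_modulation_current(cpd, py, dr)))
    status_f = np.full(m, "former")
    _, py_f, ysc_f = _draw_exposures(rng, status_f, age)
    norm_frm = float(np.mean(_modulation_former(py_f, ysc_f, dr)))
    return norm_cur, norm_frm


def mean_beta(config: SimConfig, cpg: str, status: str,
              cigarettes_per_day: float = 0.0, pack_years: float = 0.0,
              years_since_cessation: float = 0.0) -> float:
    """The generator's mean beta-value curve for one CpG at a given exposure.

    This is the noiseless dose-response truth used by curve-shape oracles.
    """
    prof = config.cpg_profiles[cpg]
    dr = config.dose_response_params
    norm_cur, norm_frm = _modulation_norms(config)
    if status == "never":
        eff = 0.0
    elif status == "current":
        eff = prof.current_offset * float(
            _modulation_current(np.array([cigarettes_per_day]),
                                np.array([pack_years]), dr)[0]) / norm_cur
    elif status == "former":
        eff = prof.former_offset * float(
            _modulation_former(np.array([pack_years]),
                               np.array([years_since_cessation]), dr)[0]) / norm_frm
    else:
        raise ValueError(f"unknown smoking status {status!r}")
    return float(np.clip(prof.never_mean + eff, 0.02, 0.98))


@dataclass
class SimulatedCohort:
    """The three linked tables plus the generator's hidden truth."""

    cohort: pd.DataFrame
    methylation: pd.DataFrame
    survival: pd.DataFrame
    truth: pd.DataFrame  # participant_id, true_score, linear_predictor

    def __iter__(self):
        return iter((self.cohort, self.methylation, self.survival))


def generate_cohort(config: SimConfig) -> SimulatedCohort:
    """Draw a full synthetic cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    pid = np.array([f"P{i+1:05d}" for i in range(n)])

    # --- demographics and smoking -------------------------------------
    lo, hi = config.age_range
    age = rng.uniform(lo, hi, n)
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    status = rng.choice(["never", "former", "current"], size=n,
                        p=np.asarray(config.smoking_prevalence, dtype=float))
    cpd, pack_years, ysc = _draw_exposures(rng, status, age)

    # --- clinical covariates (marginals only) --------------------------
    bmi = rng.choice(["under", "normal", "over", "obese"], size=n,
                     p=[0.008, 0.244, 0.485, 0.263])
    activity = rng.choice(["inactive", "insufficient", "sufficient"], size=n,
                          p=[0.2032, 0.4384, 0.3584])
    sbp = rng.normal(140.0, 18.0, n) + 8.0 * (age - 62.0) / 10.0
    chol = rng.normal(220.0, 38.0, n)
    prev_cvd = (rng.random(n) < 0.216).astype(int)
    prev_dia = (rng.random(n) < 0.162).astype(int)
    prev_can = (rng.random(n) < 0.066).astype(int)
    batch = np.array([f"B{b+1:02d}" for b in rng.integers(0, config.batch_count, n)])

    # --- methylation: copula-coupled logit-normal ----------------------
    dr = config.dose_response_params
    norm_cur, norm_frm = _modulation_norms(config)
    corr = config.inter_cpg_correlation
    # eigen square root tolerates PSD-but-singular matrices
    w, v = np.linalg.eigh(corr)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((n, len(CPG_SITES))) @ root.T

    cur, fmr = status == "current", status == "former"
    m_cur = _modulation_current(cpd[cur], pack_years[cur], dr) / norm_cur
    m_frm = _modulation_former(pack_years[fmr], ysc[fmr], dr) / norm_frm
    beta = np.empty((n, len(CPG_SITES)))
    for j, cpg in enumerate(CPG_SITES):
        prof: CpGProfile = config.cpg_profiles[cpg]
        mu = np.full(n, prof.never_mean)
        mu[cur] += prof.current_offset * m_cur
        mu[fmr] += prof.former_offset * m_frm
        mu = np.clip(mu, 0.02, 0.98)
        beta[:, j] = expit(logit(mu) + prof.dispersion * z[:, j])
    beta = np.clip(beta, 0.0, 1.0)
    meth = pd.DataFrame(beta, columns=list(CPG_SITES))
    meth.insert(0, "participant_id", pid)

    # --- two-CpG score from the complete (pre-missingness) matrix ------
    if n >= 4:
        from .score import assign_quartiles, build_score
        qa = assign_quartiles(meth)
        score = build_score(qa)["score"].to_numpy(dtype=float)
    else:
        score = np.zeros(n)

    # --- survival: Weibull PH ------------------------------------------
    hz = config.hazard_params
    lp = (hz.log_hr_score * score
          + hz.log_hr_age10 * (age - 62.0) / 10.0
          + hz.log_hr_male * (sex == "male"))
    e = rng.exponential(1.0, n)
    t_event = hz.scale * (e / np.exp(lp)) ** (1.0 / hz.shape)
    censor = config.admin_censor_years - rng.uniform(0.0, config.entry_stagger_years, n)
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)

    cause = np.full(n, "none", dtype=object)
    mix = np.asarray(config.cause_mix, dtype=float)
    idx_event = np.flatnonzero(event == 1)
    if idx_event.size:
        logits = np.log(np.maximum(mix, 1e-12))[None, :].repeat(idx_event.size, 0)
        logits[:, 0] += 0.25 * score[idx_event]           # CVD tilted by score
        logits[:, 1] += 0.15 * (status[idx_event] == "current")  # cancer by smoking
        p = np.exp(logits - logits.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        u = rng.random(idx_event.size)
        pick = (u[:, None] > np.cumsum(p, axis=1)).sum(axis=1)
        cause[idx_event] = np.array(["CVD", "cancer", "other"])[pick]
    cause_known = np.ones(n, dtype=int)
    cause_known[idx_event] = (rng.random(idx_event.size) < config.cause_known_prob)

    cohort = pd.DataFrame({
        "participant_id": pid,
        "sex": sex,
        "age": age,
        "smoking_status": status.astype(object),
        "cigarettes_per_day": cpd,
        "pack_years": pack_years,
        "years_since_cessation": ysc,
        "bmi_category": bmi.astype(object),
        "physical_activity": activity.astype(object),
        "systolic_bp": sbp,
        "total_cholesterol": chol,
        "prevalent_cvd": prev_cvd,
        "prevalent_diabetes": prev_dia,
        "prevalent_cancer": prev_can,
        "batch": batch,
    })
    survival = pd.DataFrame({
        "participant_id": pid,
        "time": time,
        "event": event,
        "cause": cause,
        "cause_known": cause_known,
    })
    truth = pd.DataFrame({
        "participant_id": pid,
        "true_score": score,
        "linear_predictor": lp,
    })

    # --- MCAR missingness ----------------------------------------------
    rates = config.missing_rates or {}
    smoking_fields = ("smoking_status", "cigarettes_per_day",
                      "pack_years", "years_since_cessation")
    for field_name, rate in rates.items():
        if rate <= 0:
            continue
        mask = rng.random(n) < rate
        if field_name == "smoking_status":
            for f in smoking_fields:
                cohort.loc[mask, f] = np.nan
        elif field_name in cohort.columns:
            cohort.loc[mask, field_name] = np.nan
        elif field_name in meth.columns:
            meth.loc[mask, field_name] = np.nan

    # nullable ints so missingness survives the CSV round-trip unchanged
    for col in ("prevalent_cvd", "prevalent_diabetes", "prevalent_cancer"):
        cohort[col] = cohort[col].astype("Int64")

    return SimulatedCohort(cohort, meth, survival, truth)


# ----------------------------------------------------------------------
# CSV round-trip
# ----------------------------------------------------------------------

_COHORT_DTYPES = {
    "participant_id": str, "sex": str, "smoking_status": str,
    "bmi_category": str, "physical_activity": str, "batch": str,
    "age": float, "cigarettes_per_day": float, "pack_years": float,
    "years_since_cessation": float, "systolic_bp": float,
    "total_cholesterol": float,
    "prevalent_cvd": "Int64", "prevalent_diabetes": "Int64",
    "prevalent_cancer": "Int64",
}
_SURVIVAL_DTYPES = {
    "participant_id": str, "time": float, "event": "int64",
    "cause": str, "cause_known": "int64",
}


def write_cohort(tables: SimulatedCohort | Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame],
                 path) -> Dict[str, Path]:
    """Write cohort.csv / methylation.csv / survival.csv under ``path``."""
    cohort, meth, surv = tuple(tables)[:3]
    ids = set(cohort["participant_id"])
    for name, df in (("methylation", meth), ("survival", surv)):
        if set(df["participant_id"]) != ids:
            raise ValueError(f"participant_id mismatch between cohort and {name}")
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, df in (("cohort", cohort), ("methylation", meth), ("survival", surv)):
        f = out / f"{name}.csv"
        df.to_csv(f, index=False, na_rep="")
        files[name] = f
    return files


def read_cohort(path) -> SimulatedCohort:
    """Read and validate the three CSVs; inverse of :func:`write_cohort`."""
    p = Path(path)
    cohort = pd.read_csv(p / "cohort.csv", dtype=_COHORT_DTYPES,
                         keep_default_na=True)
    meth = pd.read_csv(p / "methylation.csv",
                       dtype={"participant_id": str})
    surv = pd.read_csv(p / "survival.csv", dtype=_SURVIVAL_DTYPES)

    ids = set(cohort["participant_id"])
    if set(meth["participant_id"]) != ids or set(surv["participant_id"]) != ids:
        raise ValueError("participant_id keys differ across tables")
    vals = meth[[c for c in meth.columns if c != "participant_id"]].to_numpy(float)
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
        raise ValueError("beta-values outside [0,1] in methylation.csv")
    if len(surv) and (surv["time"].to_numpy() <= 0).any():
        raise ValueError("nonpositive follow-up time in survival.csv")
    bad = (surv["event"] == 0) & (surv["cause"] != "none")
    if bad.any():
        raise ValueError("censored records must have cause 'none'")
    truth = pd.DataFrame({"participant_id": cohort["participant_id"]})
    return SimulatedCohort(cohort, meth, surv, truth)
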