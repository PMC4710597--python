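"""End-to-end pipeline: simulate -> describe -> dose-response -> cox ->
score -> evaluate, with a hashed output manifest and a stage-timed log."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import CPG_SITES, SCORE_CPGS, SimConfig
from .cox import fit_cox
from .descriptives import rates_by_group, spearman_matrix, stratified_medians, kruskal_wallis
from .dose_response import covariate_design, dose_response_curve, fit_adjusted_ols, smoking_exposure
from .evaluate import (absolute_risk, aic, calibration_gb, categorize_risk,
                       collinearity, harrell_c, idi, model_compare, nri,
                       optimism_corrected_c, score_model_design)
from .km import kaplan_meier, logrank
from .models import cause_specific_events, cox_design
from .score import assign_quartiles, build_score
from .simulate import generate_cohort, read_cohort, write_cohort


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    input_dir: Optional[str] = None      # load instead of simulating
    out_dir: str = "results"
    horizon: float = 10.0
    bootstrap_reps: int = 200
    ties: str = "breslow"
    sensitivity_exclude_cvd: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        sim = SimConfig.from_dict(d.pop("sim", {}))
        return cls(sim=sim, **d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the output manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = []
    t_start = time.time()

    def log(msg):
        log_lines.append(f"[{time.time() - t_start:8.2f}s] {msg}")

    # -- stage: data ----------------------------------------------------
    if config.input_dir:
        data = read_cohort(config.input_dir)
        log(f"loaded cohort from {config.input_dir} (n={len(data.cohort)})")
    else:
        data = generate_cohort(config.sim)
        write_cohort(data, out / "data")
        log(f"simulated cohort n={len(data.cohort)} seed={config.sim.seed}")
    cohort, meth, surv = data.cohort, data.methylation, data.survival
    if config.sensitivity_exclude_cvd:
        keep = cohort["prevalent_cvd"].fillna(0).astype(int) == 0
        cohort = cohort[keep.to_numpy()].reset_index(drop=True)
        meth = meth[keep.to_numpy()].reset_index(drop=True)
        surv = surv[keep.to_numpy()].reset_index(drop=True)
        log(f"sensitivity mode: excluded prevalent CVD, n={len(cohort)}")

    files = {}

    def emit(name: str, df: pd.DataFrame):
        f = out / name
        df.to_csv(f, index=False)
        files[name] = f

    # -- stage: describe ------------------------------------------------
    rows = []
    for cpg in SCORE_CPGS:
        for var in ("smoking_status", "sex", "bmi_category"):
            summ = stratified_medians(meth[cpg], cohort[var])
            h, p = kruskal_wallis(meth[cpg], cohort[var])
            summ.insert(0, "cpg", cpg)
            summ.insert(1, "variable", var)
            summ["kw_p"] = p
            rows.append(summ)
    emit("table1_stratified.csv", pd.concat(rows, ignore_index=True))
    emit("tableS2_spearman.csv", spearman_matrix(meth).reset_index(names="cpg"))
    log("descriptives written")

    # -- stage: score ---------------------------------------------------
    qa = assign_quartiles(meth)
    score_df = build_score(qa)
    emit("scores.csv", score_df)
    score = score_df["score"]
    log(f"score distribution 0/1/2 = "
        f"{[int((score == k).sum()) for k in (0, 1, 2)]}")

    # -- stage: incidence rates ----------------------------------------
    ir = rates_by_group(surv["time"], surv["event"], score)
    ir.insert(0, "stratum", "score")
    ir2 = rates_by_group(surv["time"], surv["event"], cohort["smoking_status"])
    ir2.insert(0, "stratum", "smoking")
    emit("table3_incidence.csv", pd.concat([ir, ir2], ignore_index=True))

    # -- stage: dose-response ------------------------------------------
    cov = covariate_design(cohort)
    dr_rows = []
    for cpg in SCORE_CPGS:
        st = cohort["smoking_status"]
        expo = pd.DataFrame({
            "former": (st == "former").astype(float).where(st.notna()),
            "current": (st == "current").astype(float).where(st.notna()),
        })
        est, _, n_drop = fit_adjusted_ols(meth[cpg], expo, cov)
        est.insert(0, "cpg", cpg)
        dr_rows.append(est)
        log(f"dose-response OLS {cpg}: dropped {n_drop} incomplete rows")
        for kind in ("intensity", "packyears", "cessation"):
            x, include = smoking_exposure(cohort, kind)
            curve, _, _ = dose_response_curve(
                meth[cpg][include], x[include],
                cov[include].reset_index(drop=True))
            emit(f"fig1_{kind}_{cpg}.csv", curve)
    emit("table2_regression.csv", pd.concat(dr_rows, ignore_index=True))

    # -- stage: survival ------------------------------------------------
    times = surv["time"].to_numpy(float)
    q_first = qa.quartiles[SCORE_CPGS[0]]
    km = kaplan_meier(times, surv["event"], q_first)
    km_rows = []
    for lev, curve in km.items():
        km_rows.append(pd.DataFrame({
            "quartile": lev, "time": curve.event_times,
            "survival": curve.survival, "greenwood_var": curve.greenwood_var}))
    emit("figS2_km_quartiles.csv", pd.concat(km_rows, ignore_index=True))
    chi2, df_lr, p_lr = logrank(times, surv["event"], q_first)
    log(f"log-rank across quartiles of {SCORE_CPGS[0]}: chi2={chi2:.2f} p={p_lr:.3g}")

    hr_rows = []
    for cause in ("all", "CVD", "cancer", "other"):
        ev = cause_specific_events(surv, cause)
        for model in (1, 2, 3):
            design = cox_design(cohort, model=model, score=score,
                                smoking=(model >= 2))
            fit = fit_cox(times, ev, design, ties=config.ties)
            summ = fit.summary().loc[["score[1]", "score[2]"]] if model >= 2 \
                else fit.summary()
            summ = summ.reset_index(names="term")
            summ.insert(0, "cause", cause)
            summ.insert(1, "model", model)
            hr_rows.append(summ)
            log(f"cox cause={cause} model={model}: n={fit.n} events={fit.n_events} "
                f"dropped={fit.n_dropped} converged={fit.converged}")
    emit("table3_cox.csv", pd.concat(hr_rows, ignore_index=True))

    # -- stage: evaluate (fatal-CVD prediction) -------------------------
    ev_cvd = cause_specific_events(surv, "CVD")
    base_design = score_model_design(cohort)
    aug_design = score_model_design(cohort, meth, add_cpgs=list(SCORE_CPGS))
    complete = base_design.notna().all(1) & aug_design.notna().all(1)
    bd = base_design[complete].reset_index(drop=True)
    ad = aug_design[complete].reset_index(drop=True)
    t_c = times[complete.to_numpy()]
    e_c = ev_cvd[complete.to_numpy()]
    log(f"evaluation complete-case n={len(bd)} ({int((~complete).sum())} dropped)")

    base_fit = fit_cox(t_c, e_c, bd, ties=config.ties)
    aug_fit = fit_cox(t_c, e_c, ad, ties=config.ties)
    cmp_ = model_compare(base_fit, aug_fit)
    risk_base, _ = absolute_risk(base_fit, config.horizon)
    risk_aug, _ = absolute_risk(aug_fit, config.horizon)
    tab, nri_pct, nri_p = nri(categorize_risk(risk_base), categorize_risk(risk_aug),
                              e_c.astype(bool))
    idi_pct, idi_p = idi(risk_base, risk_aug, e_c.astype(bool))
    c_base = harrell_c(t_c, e_c, base_fit.linear_predictor)
    c_aug = harrell_c(t_c, e_c, aug_fit.linear_predictor)
    opt_base = optimism_corrected_c(t_c, e_c, bd, B=config.bootstrap_reps,
                                    seed=config.sim.seed + 1)
    opt_aug = optimism_corrected_c(t_c, e_c, ad, B=config.bootstrap_reps,
                                   seed=config.sim.seed + 2)
    calib, gb_chi2, gb_p = calibration_gb(aug_fit)
    vif = collinearity(ad, list(SCORE_CPGS))
    mv = tab.movements()
    report = {
        "n": int(len(bd)), "n_cases": int(e_c.sum()),
        "neg2loglik": {"score": base_fit.neg2_loglik, "augmented": aug_fit.neg2_loglik},
        "df": {"score": len(base_fit.coef), "augmented": len(aug_fit.coef)},
        "aic": {"score": aic(base_fit), "augmented": aic(aug_fit)},
        "lr_p": cmp_["p"],
        "harrell_c": {"score": c_base, "augmented": c_aug},
        "optimism_corrected_c": {"score": opt_base["corrected"],
                                 "augmented": opt_aug["corrected"],
                                 "score_ci": [opt_base["ci_low"], opt_base["ci_high"]],
                                 "augmented_ci": [opt_aug["ci_low"], opt_aug["ci_high"]]},
        "reclassification": mv,
        "nri_pct": nri_pct, "nri_p": nri_p,
        "idi_pct": idi_pct, "idi_p": idi_p,
        "calibration": {"per_group": calib.to_dict(orient="records"),
                        "chi2": gb_chi2, "p": gb_p},
        "vif": vif.to_dict(orient="records"),
    }
    with open(out / "table4_evaluation.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    files["table4_evaluation.json"] = out / "table4_evaluation.json"
    emit("table4_calibration.csv", calib)
    log(f"evaluation: C {c_base['c']:.3f} -> {c_aug['c']:.3f}, "
        f"corrected {opt_base['corrected']:.3f} -> {opt_aug['corrected']:.3f}, "
        f"NRI {nri_pct:.2f}% IDI {idi_pct:.2f}%")

    # -- manifest -------------------------------------------------------
    manifest = {
        "seed": config.sim.seed,
        "n_participants": int(len(cohort)),
        "horizon_years": config.horizon,
        "bootstrap_reps": config.bootstrap_reps,
        "sensitivity_exclude_cvd": config.sensitivity_exclude_cvd,
        "outputs": {name: _sha256(Path(f)) for name, f in files.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return manifest
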