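# methrisk

Smoking leaves a durable, dose-dependent imprint on blood DNA methylation.
Nine CpG sites — in *AHRR* (cg05575921, cg21161138, cg23576855), *F2RL3*
(cg03636183), *2q37.1* (cg21566642, cg01940273, cg05951221, cg06644428) and
*6p21.33* (cg06126421) — are the strongest such markers on the Illumina 450K
array. `methrisk` implements, end to end, the analysis that links these
markers to smoking exposure and to mortality in a prospective older-adult
cohort, and asks whether the two strongest CpGs improve fatal-cardiovascular
risk prediction over the conventional SCORE risk factors (age, sex, systolic
blood pressure, current smoking, total cholesterol).

It is written for biostatisticians and epidemiologists who want a tested,
reproducible implementation of this pipeline — including a synthetic cohort
generator with known ground truth, so every estimator can be validated by
parameter recovery without access to the original cohort data.

## What is inside

- **`methrisk.simulate`** — synthetic cohorts: smoking behaviour, logit-normal
  beta-values with copula-coupled inter-CpG correlation and saturating
  dose–response in intensity, pack-years and time since cessation, and
  Weibull proportional-hazards mortality driven by the methylation score,
  age and sex (`S(t | x) = exp(-(t/λ)^k e^{β'x})`).
- **`methrisk.descriptives`** — stratified medians (Q1–Q3), Kruskal–Wallis
  tests, pairwise-complete Spearman matrices, incidence rates per 100
  person-years.
- **`methrisk.dose_response`** — covariate-adjusted linear models and
  restricted cubic splines (truncated-power natural splines, linear beyond
  the boundary knots) with pointwise Wald bands against the zero-exposure
  reference.
- **`methrisk.cox` / `km` / `penalized` / `diagnostics`** — from-scratch
  censored-survival machinery: Kaplan–Meier with Greenwood variance,
  log-rank, Newton–Raphson maximisation of the Cox partial likelihood
  (Breslow and Efron ties), Breslow baseline cumulative hazard, per-SD
  hazard ratios, L1-penalised Cox by coordinate descent with
  cross-validated penalty choice, and a cumulative martingale-residual
  (score-process) check of proportional hazards.
- **`methrisk.score`** — the two-CpG methylation score: 2/1/0 for lowest
  cohort quartile at both / one / neither of cg05575921 and cg06126421.
- **`methrisk.evaluate`** — absolute 10-year risks `1 − exp(−H₀(t)e^{β'x})`,
  Harrell's C, .632-bootstrap optimism correction
  (`C_corr = 0.368·C_app + 0.632·C_oob`), guideline risk categories
  (0–5, >5–10, >10–20, >20%), category NRI, IDI, the May–Hosmer form of the
  Gronnesby–Borgan calibration test, AIC/likelihood-ratio comparison, VIF.
- **`analysis/01–05`** — numbered drivers running the whole sequence on the
  reference synthetic cohort; **`methrisk`** CLI with `simulate`,
  `describe`, `dose-response`, `cox`, `score` and `run` subcommands.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/04_survival_models.py
```

prints, for the reference cohort (n=1000, seed 1):

```
cohort n=1000; smoking prevalence: {'never': 0.506, 'former': 0.311, 'current': 0.183}
deaths: 146 (14.6%), median follow-up 10.3 y
...
model-3 HRs for methylation score 2 vs 0:
     all: HR 2.99 (1.63, 5.49)
     CVD: HR 5.54 (2.16, 14.25)
  cancer: HR 1.71 (0.53, 5.55)
   other: HR 1.90 (0.54, 6.61)
```

Reading this: participants in the lowest methylation quartile at both score
CpGs have about a three-fold all-cause and five-to-six-fold cardiovascular
mortality hazard relative to score 0, after adjustment for age, sex, batch,
smoking status and the clinical covariates — the score carries the
smoking-associated mortality signal. `analysis/05_prediction_eval.py` then
evaluates whether adding the two CpG beta-values to the SCORE variables
improves fatal-CVD discrimination, printing apparent and optimism-corrected
C-statistics, NRI/IDI and the calibration test for both models.

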