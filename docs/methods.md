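# Methods

## The scientific setting

Blood DNA methylation at a small set of CpG sites responds to cigarette
smoke in a dose-dependent and slowly reversible way, making beta-values at
these sites candidate biomarkers of cumulative smoking exposure and of
smoking-related mortality risk. The pipeline models three questions on a
prospective cohort of older adults (ages 50–75, ~10 years of mortality
follow-up): (i) how methylation at nine 450K CpGs varies with smoking
status, current intensity, pack-years and time since cessation; (ii) how
individual CpGs and a two-CpG score relate to all-cause and cause-specific
mortality; (iii) whether the two strongest CpGs add predictive value for
fatal cardiovascular disease beyond the SCORE risk factors.

## Synthetic cohort generator

Because no individual-level cohort data are distributable, the package
ships a generator whose *defaults are the study conditions*: n = 1,000,
equal sexes, ages uniform on [50, 75], smoking prevalence 48/33/19%
never/former/current, administrative censoring at 10.45 years minus a
0.3-year recruitment stagger (giving a median follow-up of ~10.3 years),
and a Weibull baseline calibrated to ~14% deaths over follow-up.

**Methylation model.** Each CpG has a logit-normal marginal: with
smoking-dependent mean `μ` and dispersion `σ` (logit scale),
`β = expit(logit(μ) + σ z)`, where the `z` across CpGs are multivariate
normal with a configurable correlation matrix (a Gaussian copula). This
gives support on [0, 1] and tractable rank correlations. The mean follows

```
μ = m₀ + Δ · s(exposure) / E[s]
```

where `m₀` is the never-smoker median, `Δ` the configured current- or
former-smoker offset, and `s` a saturating exposure modulation:
`1 − 2^(−x/h)` in cigarettes/day (half-saturation h = 6) and pack-years
(h = 15), mixed 60/40 for current smokers; for former smokers the
pack-year term is multiplied by a recovery factor
`ρ + (1 − ρ)·exp(−ysc/τ)` with τ = 9 years and permanent fraction
ρ = 0.35, so methylation recovers over ~20–25 years but not fully.
Normalising by the mean modulation of the simulated exposure distribution
makes `Δ` equal the realised mean shift of that smoking group, so the
configured offsets are directly recoverable by the adjusted regression
(−0.25 for cg05575921 reproduces the 0.88 → 0.63 never→current median
drop). Half-saturation at 6 cigarettes/day places the steep part of the
fitted spline below ~15 cigarettes/day, with flattening beyond 20.

For the two score CpGs the never-smoker medians and offsets are calibrated
to the published stratified medians; the seven remaining CpGs carry
plausible values consistent with the reported ranges (their supplementary
stratified values were not available) and are therefore synthetic choices,
as is the exchangeable 0.65/0.30 default correlation structure (reported
pairwise rank correlations span 0.46–0.93, weaker for cg06644428).

**Mortality model.** Event times are Weibull proportional hazards,
`H(t|x) = (t/λ)^k · exp(β'x)` with shape k = 1.4, scale λ = 70 and linear
predictor `0.62·score + 0.70·(age−62)/10 + 0.45·male`, where `score` is
the 0/1/2 two-CpG lowest-quartile count computed from the generated
(pre-missingness) beta-values. The score log-HR 0.62 matches the published
per-category hazard-ratio gradient (~1.9× per score unit, model 1).
Censoring is administrative only. Causes of death are multinomial
(CVD/cancer/other ≈ 0.37/0.36/0.27 among deaths) with logits tilted by the
score (CVD) and current smoking (cancer), and 94.4% of deaths have a known
cause. Missingness is MCAR with per-field rates matching the footnoted
counts (22/1000 smoking status, 3/1/1 per-CpG, etc.).

**What the generator does not emulate.** Real covariate *joint*
distributions (only marginals are matched); leukocyte-composition
confounding; measurement error in self-reported smoking (the generator's
smoking variables predict methylation more cleanly than real self-report,
which inflates smoking–methylation collinearity relative to the published
VIF of 1.46 — the collinearity checks therefore use a configuration with
the published 0.56 inter-CpG correlation and no smoking effect); direct
effects of blood pressure or cholesterol on the simulated hazard (the
SCORE variables other than age/sex are noise here, so absolute C-statistics
run lower than the published 0.75–0.82, while *differences* — optimism
gaps, NRI/IDI nulls, selection behaviour — are meaningful). Passing tests
therefore validate the estimators and the pipeline logic, not the
epidemiology of any real cohort.

## Estimators

**Descriptives.** Quantiles are type-7 (linear interpolation) throughout —
stratified summaries, quartile cutoffs and score boundaries. Kruskal–Wallis
uses the tie-corrected H with a chi-square reference (a permutation oracle
backs the tests); Spearman matrices are pairwise-complete.

**Restricted cubic splines.** Truncated-power natural-spline basis: linear
term plus, for knots t₁<…<t_k, columns
`[(x−t_j)₊³ − (x−t_{k−1})₊³(t_k−t_j)/(t_k−t_{k−1}) + (x−t_k)₊³(t_{k−1}−t_j)/(t_k−t_{k−1})]/(t_k−t₁)²`,
giving linearity beyond the boundary knots. Default four knots at the
5/35/65/95th percentiles of the exposed participants (the source analysis
does not state its knot scheme). Dose–response curves are reported as
differences from exposure 0 with pointwise 1.96·SE Wald bands; reference
groups (never+former at intensity 0; never at 0 pack-years; current at 0
years since cessation) enter with all spline columns zero.

**Cox fitting.** Newton–Raphson on the log partial likelihood with
step-halving; Breslow ties by default (mirroring the PHREG default of the
original analysis), Efron available. Convergence at max |score| < 1e-8 or
relative log-likelihood change < 1e-10; runaway coefficients (monotone
likelihood/separation) are flagged as non-converged rather than raised.
Covariance is the inverse observed information. Zero-variance columns are
tolerated via pseudo-inverse Newton steps (coefficient 0); genuinely
collinear designs raise. The Breslow baseline cumulative hazard
`H₀(t) = Σ_{t_j≤t} d_j / Σ_{risk} e^{lp}` supports absolute risks
`1 − exp(−H₀(t)e^{lp})`, with an extrapolation flag beyond the last
observed time. Complete-case analysis per model; no imputation.
Cause-specific analyses censor competing causes at the death time;
unknown-cause deaths are censored (configurable).

**Penalised Cox.** Cyclic coordinate descent with soft-thresholded Newton
coordinate updates on the Breslow partial likelihood; unpenalised
covariates are never thresholded; covariates are not standardised
internally (the nine beta-values share the [0,1] scale). The penalty grid
is log-spaced from the smallest all-zero lambda; lambda is chosen by
5-fold cross-validated partial likelihood (Verweij–van Houwelingen),
seeded. At lambda → 0 the path reproduces the unpenalised fit (tested to
1e-4); at large lambda all penalised coefficients are exactly zero.

**Proportional-hazards diagnostics.** The primary check is the cumulative
martingale-residual (score-process) supremum test: the observed score
process over event times is compared against realisations obtained by
multiplying per-subject martingale increments with standard-normal
weights, including the correction for estimating beta; the p-value is the
exceedance fraction of resampled suprema (default 1,000 draws, seeded). A
scaled-Schoenfeld rank-correlation test is provided as a cheap
alternative.

**Evaluation.** Harrell's C counts pairs usable under censoring (earlier
time is an event; tied times event-vs-censored), credits 0.5 for risk
ties, and reports a leave-one-subject-out jackknife 95% CI. Optimism
correction is the plain .632 bootstrap: refit on each resample, score the
out-of-bag records, `C_corr = 0.368·C_app + 0.632·mean(C_oob)`, percentile
CI over per-replicate corrected values; resamples without events are
skipped and counted, and a degenerate resample with no out-of-bag records
contributes its resample C. Risk categories use half-open intervals with
boundaries in the lower category (5.0% is "0–5%"). Category NRI follows
`[(cases up − cases down)/cases] − [(controls up − controls down)/controls]`
with the standard binomial-difference z-test; IDI is the difference in
discrimination slopes with a paired z-test. Cases are fatal-CVD deaths
during follow-up; controls are everyone else including other deaths
(configurable). Calibration follows the May–Hosmer simplification of the
Gronnesby–Borgan test: five groups by quintiles of the ranks of estimated
risk, per-group `z = (O−E)/√E` with martingale-based expected counts, and
an overall score test for adding the group indicators (chi-square,
groups−1 df). VIF/tolerance come from regressing each added column on the
rest of the design.

## Numerical and design choices

- All randomness flows from explicit integer seeds; the pipeline derives
  per-stage seeds from one root seed, and manifests record content hashes,
  so a fixed configuration is bit-reproducible.
- Linear predictors are clipped at ±500 before exponentiation to keep the
  partial-likelihood evaluation finite under separation.
- Lowest-quartile membership uses the closed boundary `β ≤ Q1`; an
  all-constant CpG column puts everyone in quartile 1 and is flagged
  degenerate. Score cutoffs are computed on the full analysis cohort.
- The NRI check against the published 21.92% uses the printed movement
  counts (18/11 cases, 82/151 controls) with complete-case denominators of
  50 cases and 871 controls, which reproduce the printed value exactly;
  the original denominators are not printed.
- Null/power simulation scenarios: the calibration test's mis-specification
  scenario omits a strong quadratic term of the included covariate, because
  omitting an *orthogonal* covariate leaves rank-based risk groups
  internally calibrated (a known insensitivity of group-based calibration
  tests); the optimism-correction "pure-noise" scenario uses eight noise
  predictors at n = 200 so that overfitting optimism (the phenomenon the
  .632 correction removes) dominates sampling noise, comparable to a
  10-coefficient model on ~50 events. With a single noise predictor the
  correction still shrinks |C − 0.5| on average, which is tested as an
  aggregate contrast.

## Problem sizes

Recovery and null-distribution suites run at the sizes that make their
guarantees sharp while keeping the default test run quick: 50 replicates
of n = 2,000 for log-HR recovery and CI coverage; 20 replicates of
n = 2,000 for penalised selection (the two hazard-carrying CpGs are
recovered in ≥70%; at n = 1,000 selection among nine correlated CpGs is
visibly less stable, as the demo driver shows); 200 replicates for the
calibration type-I error; 100 replicates for the IDI/NRI noise nulls;
bootstrap B = 100–200 in tests and drivers versus the conventional 1,000
of a production analysis (the default of `optimism_corrected_c` remains
B = 1,000).

## Known limitations

Single-imputation-free complete-case handling only; no time-varying
covariates, frailty, or subdistribution (Fine–Gray) hazards; no
continuous NRI; spline knot schemes beyond 3–5 quantile-based knots are
not implemented. The generator's limitations are listed above; in
particular, absolute discrimination levels and smoking–methylation
collinearity should not be read as estimates of any real cohort's values.
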