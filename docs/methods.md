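# Methods

`t2dsim` is a discrete-time, individual-level simulation of type 2 diabetes
progression after second-line treatment intensification. Time advances in
90-day quarters over a maximum horizon of 31 quarters (about 7.6 years).
Each simulated person carries nine continuous risk factors — HbA1c (%), BMI
(kg/m²), systolic and diastolic blood pressure (mm Hg), HDL, LDL, total
cholesterol and non-fasting triglycerides (mg/dL), and eGFR
(mL/min/1.73 m²) — and nine complication processes: hypoglycaemia, MI,
unstable angina, stroke, heart-failure hospitalisation, lower-extremity
amputation, end-stage kidney disease, diabetic eye disease, and all-cause
death. The pipeline has four stages: cohort synthesis, pathway simulation,
engine calibration, and counterfactual contrast.

## Cohort synthesis

Real linked primary/secondary-care records of the population this package
emulates cannot be redistributed, so the cohort is synthetic by design. Each
continuous variable is drawn from a family solved from a published
median/IQR summary:

* **normal** — location = median, scale = IQR width / (2·z₀.₇₅); used for
  age, blood pressures, lipids and eGFR;
* **log-normal** — log-location = ln(median), log-scale =
  ln(Q3/Q1)/(2·z₀.₇₅); used where the median sits visibly off-centre in the
  IQR (HbA1c, BMI, triglycerides);
* **quantile-knots** — a piecewise-linear quantile function through
  (0, lo), (0.25, Q1), (0.5, median), (0.75, Q3), (1, hi); used for diabetes
  duration, whose printed quartiles (2.5, 4.9, 5.0 years) are left-skewed
  inside the IQR beyond what either parametric family can represent. The
  tails are linear to configurable endpoints (0 and 15 years by default).

The nine risk factors are coupled by a Gaussian copula targeting Spearman
rank correlations (latent Pearson r = 2·sin(πρ/6)); the default matrix is a
weak, clinically plausible structure (BMI–blood pressure, LDL–total
cholesterol, triglycerides–HDL, …) because the emulated summary table prints
no correlations; it is fully user-overridable and must be positive
semi-definite. Categorical descriptors (sex, ethnicity, deprivation
quintile including an explicit "missing" level, second-line drug class) are
drawn independently at the printed frequencies.

Comorbidity history flags cannot be independent: the printed per-condition
prevalences (angina 3.3%, MI 6.1%, stroke 4.2%, heart failure 4.7%) imply a
17.1% composite under independence, against a printed 13.8% "any CVD". The
four cardiovascular flags therefore share one latent Gaussian factor; its
loading is solved by Gauss–Hermite quadrature and bisection so the
composite hits its target exactly in expectation while marginals are
preserved (solved loading ≈ 0.68). Sampled vectors violating sbp > dbp or
total cholesterol ≥ HDL (a few per 62,640 draws) are repaired and counted.

HbA1c is stored on the % (NGSP) scale; conversion to mmol/mol uses the IFCC
master equation mmol/mol = 10.929·(% − 2.15), rounded only for display.
The emulated table labels its lipid rows mmol/L while printing mg/dL-scale
magnitudes; the package stores mg/dL throughout (the convention of its risk
equations) and treats the table labels as a likely erratum.

## Treatment pathways

Regimens are categorical drug-class combinations: no therapy; seven
monotherapies; nine named dual therapies; and a single pooled
"triple-or-other" category. Each individual starts on the metformin dual
matching their assigned second-line class and evolves by a first-order
Markov chain over six category-level states (own dual, metformin
monotherapy, other monotherapy, other dual, triple-or-other, no therapy).
Leaving the own dual is governed by a per-quarter hazard and a destination
distribution, both banded by time (year 1 / years 2–3 / year 4+); the own
dual is never re-entered, which makes "time to second-line cessation" well
defined, while revisits among all other categories are allowed. On entry
into "other mono/dual" a concrete regimen code is sampled (excluding the
individual's own dual, renormalised) and held while the category persists.
Statin and blood-pressure-therapy flags are independent per-quarter
Bernoulli draws at configured prevalences (defaults 0.75 and 0.65).

Administrative censoring is drawn independently of regimen and arm, with a
constant hazard within each follow-up year derived exactly from published
yearly available-follow-up counts; this yields 84% cumulative censoring by
year 7. Death is not simulated separately at this stage — the censoring
schedule stands in for all loss to follow-up.

Because censoring is independent of state, the chain's exact marginal
distribution equals the regimen mix among those still followed. Default
calibration exploits this: the marginals are iterated deterministically and
five free parameters (two leave hazards, the year-1 destination masses to
metformin-mono and triple, the later destination mass to triple) are solved
by root-finding against the published pathway statistics — own-dual
persistence 73.5% among those followed at one year (equivalently 33/28/7%
of the whole cohort on metformin-SU/-DPP4i/-SGLT2i), metformin monotherapy
12% and triple therapy 7% of the cohort at one year, and 31% triple among
those followed at the end of the horizon. No stochastic fitting is
involved, so the calibration is reproducible to machine precision. The
leave hazards are common to the three arms, making cessation times
exchangeable across arms, consistent with the emulated study's finding of
no between-arm cessation differences.

## Treatment effects

Every drug class carries, versus no therapy: an additive shift per risk
factor (the indirect pathway) and a log hazard-ratio per complication (the
direct pathway). A regimen's effect is the **sum** of its components'
effects on the transformed scale; the pooled triple category is resolved
through a configurable representative composition (default
metformin + SU + DPP4i, the most prevalent classes). Additivity is a
declared contract — no interaction structure is claimed — and can be
replaced by a user combination hook.

The shipped default values are deliberately labelled illustrative: their
signs follow the meta-analytic literature (SGLT2i lower HbA1c, weight,
blood pressure, and heart-failure and kidney-event hazards, and preserve
eGFR; sulphonylureas and insulin raise hypoglycaemia hazard and weight;
TZDs raise heart-failure hazard), but the magnitudes are round numbers, not
estimates. Risk-factor entries are stored as per-quarter increments
(1 − lag1)·steady-state-shift, so with the default AR lag of 0.9 the
on-treatment trajectory settles at the cited steady-state displacement
(e.g. −0.9% HbA1c for SGLT2i, −1.9% for metformin + SGLT2i).

## Risk-factor engine

Each factor follows a linear AR(1) update per quarter:

    x[t+1] = a + b·x[t] + Σ β_k·covariate_k + c·t + regimen effect
             + offset[t] (+ ε, stochastic mode)

Defaults: lag b = 0.9 for all factors; intercept a = (1 − b)·(published
median), making the no-therapy process stationary at the baseline median; a
deterministic eGFR time term c = −0.025 per quarter, giving an asymptotic
decline of ≈1 mL/min/1.73 m² per year to feed the kidney-disease pathway;
all covariate coefficients zero (they are config slots, not claims).
Updates are clipped at documented physiologic floors (HbA1c 3%, BMI 12,
SBP 60, DBP 30, HDL 10, LDL 10, total cholesterol 50, triglycerides 20,
eGFR 1); clip events are counted on the equation set. Expected mode draws
no randomness; stochastic mode adds Gaussian innovations with per-factor
residual SDs.

## Event engine

Each complication has a logistic model on the quarterly probability scale:
p = expit(intercept + risk-factor terms + baseline-covariate terms + time
term + prior-event term + direct regimen log-HR). At small quarterly
probabilities the logistic link approximates proportional hazards for the
direct effect. Acute events (hypoglycaemia, MI, unstable angina, stroke)
are recurrent: the linear predictor loads on the count of prior events (in
expected mode, on the *expected* cumulative count — a declared convention).
ESKD and death are absorbing; eye disease and amputation are modelled as
first occurrences.

Default intercepts are anchored so that an average individual under no
therapy has a plausible baseline quarterly probability (naive 5-year
cumulative incidences ≈ 23% eye disease, 3.5% ESKD, 2.5% heart failure,
well under 1% MI/amputation), with coefficient signs and rough magnitudes
from clinical reasoning (ESKD loads negatively on eGFR, eye disease on
HbA1c, vascular events on age, blood pressure, LDL and prior CVD). Anchoring
uses the closed-form means of the default cohort spec.

Summary quantities: cumulative incidence over a horizon is the naive
complement product 1 − Π(1 − p_t) conditional on follow-up — *not* a
cause-specific competing-risk CIF; expected recurrent-event counts are
Σ p_t. In stochastic mode events are drawn, death truncates the individual,
and no probabilities or events are recorded after death.

## Simulation loop and counterfactuals

The quarter loop order is fixed and documented: read the quarter's regimen,
compute event probabilities from the *current* state, then advance the risk
factors. Counterfactual runs create three identical copies of each
individual — same baseline, same second-line duration, same downstream
regimens, same censoring — relabelling only the second-line quarters to
each arm's metformin dual. In stochastic mode the three copies share random
numbers (one generator seed, draws aligned by individual index and
quarter), so between-arm differences carry no simulation noise. With
identical effect entries for the three classes the three runs are
bit-identical and every contrast is exactly zero.

A horizon-h summary averages over individuals with follow-up ≥ h
(mirroring declining available-follow-up denominators), with normal-based
95% CIs (mean ± 1.96·SD/√n). Contrasts are paired within-individual
differences — the three copies are the same people — aggregated the same
way, overall and stratified by baseline CVD (the composite flag, fixed at
baseline).

## Calibration and recalibration

Predicted per-quarter means (with across-individual SDs) are compared to
observed hold-out means; agreement means the observed mean lies within
pred_mean ± 1.96·pred_sd/√n_obs. The flagging rule is any-quarter by
default, with a fraction-of-quarters alternative. For a correctly specified
system this band attains ≈95% per-quarter coverage (verified by simulation
in the tests; the predictive band must come from a stochastic run so it
carries the model's full spread).

Recalibration estimates an additive per-quarter offset schedule for each
flagged risk factor: level discrepancies D_t = observed − predicted are
optionally smoothed by a Savitzky–Golay filter (order ≤ 2, preserving
linear/quadratic trends including at the boundaries), then inverted through
the AR recursion, δ_t = D_{t+1} − lag1·D_t. Since each quarter has a free
offset this is the least-squares solution, and re-running with the schedule
attached reproduces the observed means exactly up to smoothing. Only
risk-factor outcomes are recalibratable. Validation is by parameter
recovery: a known drift of 0.05·t kg/m² per quarter injected into the BMI
update is recovered with RMSE well under 20% of the drift magnitude at
hold-out n = 10,000, and the error shrinks with hold-out size.

## What the synthetic data do and do not show

The generator reproduces *marginal* summaries, arm frequencies, a composite
comorbidity prevalence, pathway mix at two time points and the censoring
profile. It does not reproduce: the joint dependence of real risk factors
beyond the assumed copula structure; regimen-dependent censoring or
informative loss to follow-up; seasonal or calendar-time effects;
measurement error and irregular observation times; or the real
effect-modification structure across subgroups. Passing tests therefore
demonstrate that the machinery is correct and internally calibrated, not
that its default coefficients are clinically accurate: coefficient and
effect configs are inputs, and substantive conclusions require externally
estimated values.

## Problem sizes and numerical choices

Full-size cohort generation and pathway simulation run at n = 62,640
(seconds on one core). Counterfactual direction checks use n = 10,000;
copula convergence checks n = 50,000; the incidence formulas are checked
against a 10⁶-replicate Monte-Carlo oracle; AR(1) convergence is checked to
10⁻⁶ at quarter 200. Quantiles are type-7 (linear interpolation)
throughout. Root-finding uses bisection/`brentq` at 10⁻¹²–10⁻¹⁰ tolerances.
All randomness flows through `numpy` `SeedSequence`s keyed by a user seed
plus a fixed per-stage tag, and the order of RNG consumption is part of the
reproducibility contract: identical (spec, seed) inputs give bit-identical
outputs.

## Known limitations

* Quarterly probabilities are treated as independent across events within a
  quarter; no within-quarter event ordering or competing-risk adjustment is
  applied to the headline cumulative incidences.
* Expected mode propagates mean states through nonlinear (logistic) event
  models, so event probabilities are evaluated at expected states rather
  than averaged over state distributions (a Jensen gap, small at these
  spreads).
* The default coefficients, effects and transition structure are
  illustrative stand-ins calibrated to printed summary statistics, not
  estimates from individual-level data.
* GLP1-RA appears only as a downstream pathway class, not as a second-line
  comparator; costs and QALYs are out of scope.
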