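# t2dsim

Individual-level microsimulation of type 2 diabetes progression under
alternative second-line glucose-lowering treatments.

When metformin alone no longer controls blood glucose, a second drug class
is added — most commonly a sulphonylurea (SU), a DPP4 inhibitor (DPP4i) or
an SGLT2 inhibitor (SGLT2i). Randomised trials compare these classes in
selected populations over limited horizons and rarely cover every
complication patients care about. `t2dsim` addresses the question the way
health-outcomes modellers do: simulate each individual's risk factors and
complications forward in 90-day quarters under each *counterfactual*
second-line choice, holding everything else about that person fixed, and
contrast the predicted outcomes.

The package is aimed at epidemiologists and health-economic modellers who
want a tested, fully config-driven scaffold for this class of model:
synthetic cohort generation, treatment-pathway simulation, quarterly
risk-factor/complication engines, recalibration against held-out
trajectories, and paired counterfactual contrasts.

## The model

For individual *i* with risk-factor vector **x** (HbA1c %, BMI kg/m²,
SBP/DBP mm Hg, HDL/LDL/total cholesterol/triglycerides mg/dL, eGFR
mL/min/1.73 m²), each factor follows a linear AR(1) update per quarter *t*:

    x_{t+1} = a + b·x_t + β'z_i + c·t + Δ(r_t) + δ_t  (+ ε_t)

where z_i are baseline covariates, r_t the quarter's regimen, Δ(r) the sum
of the component drug classes' additive shifts versus no therapy, and δ_t a
recalibration offset. Each complication has a per-quarter logistic model

    p_t = expit( α + γ'x_t + η'z_i + κ·N_t^prior + λ(r_t) )

with λ(r) the regimen's direct log hazard-ratio and N^prior the prior-event
count for recurrent (acute) events. Cumulative incidence by horizon h is
1 − Π_{t<h}(1 − p_t); recurrent events report expected counts Σ p_t.
Counterfactual contrasts are paired within-individual differences of these
quantities across arms, with normal-based 95% CIs (mean ± 1.96·SD/√n),
overall and by baseline cardiovascular-disease status. See
`docs/methods.md` for the full account, including the Gaussian-copula
cohort generator, the moment-matched pathway Markov chain, and the
AR-inversion recalibration estimator.

## Worked example

The numbered scripts under `analysis/` run the full study pipeline;
`analysis/04_counterfactuals.py` is the headline stage:

```sh
python analysis/04_counterfactuals.py --n 10000 --seed 4
```

prints (abridged):

```
counterfactual run: n = 10000, horizons 1/3/5 y (seed 4)
absolute 5-year predicted probabilities (%):
  eskd              SU 4.22  DPP4i 4.27  SGLT2i 3.08
  hf_hospitalisation SU 3.05  DPP4i 3.02  SGLT2i 2.32
  eye_disease       SU 17.29  DPP4i 17.70  SGLT2i 16.88
5-year mean differences, percentage points (95% CI), overall:
  SGLT2i-SU      eskd               -1.14 (-1.18, -1.11)  n=3594
  SGLT2i-SU      hf_hospitalisation -0.73 (-0.76, -0.71)  n=3594
  SGLT2i-DPP4i   eskd               -1.19 (-1.23, -1.15)  n=3594
  SGLT2i-DPP4i   eye_disease        -0.82 (-0.83, -0.80)  n=3594
```

Reading: among 10,000 simulated individuals (3,594 with at least five years
of follow-up), choosing SGLT2i over SU at second line lowers the predicted
5-year probability of end-stage kidney disease by 1.14 percentage points
under the default, deliberately illustrative effects registry — the signs
follow the meta-analytic literature; the magnitudes are config inputs, not
estimates. Hypoglycaemia excess under SU concentrates in year 1, while the
individual is still on the sulphonylurea, and stops growing once most have
moved on — the simulation reproduces that qualitative pattern.

The other drivers: `01_build_cohort.py` synthesises the 62,640-person
baseline cohort (median age 60.0 y, 39.4% female, median HbA1c
63 mmol/mol, 13.8% with CVD, second-line split 49/41/10%);
`02_simulate_pathways.py` simulates regimen pathways (73% still on their
second-line dual at one year among those followed; 31% on triple therapy
at the end; 84% censored by year 7); `03_calibration_check.py` injects a
known drift into the BMI equation and recovers it (RMSE 0.5% of the drift
magnitude at hold-out n = 10,000); `05_report_pathway_flows.py` writes the
regimen-flow (Sankey) tables. The same stages are available as a CLI:

```sh
t2dsim all --n 10000 --seed 1 --out results/
```

## Layout

```
src/t2dsim/          library: cohort, pathways, effects, risk, events,
                     simulate, calibrate, reporting, pipeline, cli, io
analysis/            numbered narrative drivers (01..05)
scripts/acceptance.py  headline-statistics reproduction
tests/               pytest suite (unit, property, end-to-end)
docs/methods.md      model documentation
```
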