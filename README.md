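# bayesdose

A randomised Bayesian model-based phase I dose-escalation design with a
standard-of-care control arm, for settings where background symptom rates
are uncertain and treatment toxicity must be judged as *additional* risk
over control — as in early-pandemic COVID-19 therapeutic trials.

The package implements the complete design workflow: the control-anchored
two-parameter logistic dose-toxicity model with overdose control and
target-interval dose recommendation, a fast trial simulator for operating
characteristics, grid-search calibration of the operational prior, the
non-parametric optimal benchmark, and safety-review reporting (posterior
summary tables, what-if next-cohort tables, partial-dosing sensitivity
analyses).

## The model

The risk of a dose-limiting toxicity (DLT) at dose *d<sub>j</sub>* is

> p<sub>j</sub> = exp(θ₁ + θ₂·d<sub>j</sub>) / (1 + exp(θ₁ + θ₂·d<sub>j</sub>)),  j = 0, 1, …, m

with standardised dose levels d₁ < … < d<sub>m</sub> and d₀ = 0 for the
control arm, so that θ₁ = logit(p₀) is the control risk and θ₂ ≥ 0 the
steepness of the curve. The prior is (θ₁, log θ₂) ~ N(μ, Σ) with zero
covariance; the standardised levels are solved from the prior point
estimates of DLT risk (the *skeleton* p<sub>j</sub>⁽⁰⁾ = p₀⁽⁰⁾ + ν·j) at
the prior parameter locations.

Escalation proceeds in cohorts (six patients, randomised 2:1 to the
current dose and control). After each cohort the posterior of (θ₁, θ₂) is
updated and, writing ARDLT<sub>j</sub> = p<sub>j</sub> − p₀ for the
additional risk of DLT:

* a dose is **safe** iff P(ARDLT<sub>j</sub> ≥ γ_toxic) < c_overdose
  (defaults 30% and 0.25);
* the next cohort receives the safe dose maximising
  P(ARDLT<sub>j</sub> ∈ [γ−δ, γ+δ]) (default target 20% ± 5%), subject to
  no more than doubling the current actual dose;
* the trial stops when all doses are unsafe, or ends at N = 30 patients
  with the analogous final recommendation.

Posterior inference is deterministic by default (an equal-probability
product grid over (θ₁, log θ₂), reweighted by the binomial likelihood),
with an MCMC backend (emcee) for cross-validation.

## Worked example

The calibrated four-dose design (300/400/600/800 mg bd) after five clean
cohorts — escalation through all four doses with no DLT observed on
treatment or control:

```python
import bayesdose as bd

design = bd.default_design()
data = bd.TrialData(n_patients=[8, 4, 4, 4, 4], n_dlt=[0, 0, 0, 0, 0])
report = bd.build_report(design, data)
print(report.table.round(4).to_string(index=False))
print("recommendation:", report.decision.action, "->", report.recommended_arm)
```

```
      arm  n_patients  n_dlt  mean_dlt_risk  ci_low  ci_high  ardlt_mean  prob_overdose  prob_target
  control           8      0         0.0305  0.0056   0.0867      0.0000         0.0000       0.0000
300 mg bd           4      0         0.0454  0.0088   0.1210      0.0149         0.0000       0.0000
400 mg bd           4      0         0.0606  0.0115   0.1599      0.0301         0.0000       0.0016
600 mg bd           4      0         0.0770  0.0140   0.2068      0.0465         0.0004       0.0204
800 mg bd           4      0         0.0953  0.0163   0.2642      0.0647         0.0047       0.0614
recommendation: stay -> 4
```

The highest dose has the largest probability of lying in the 15–25%
additional-risk band and a very low probability (0.5%) of exceeding the
30% bound, so the model recommends dosing the next cohort at 800 mg bd. A
what-if table for that hypothetical cohort shows the recommendation is
robust: only the extreme outcome — all four treated participants with a
DLT and clean controls — would flip it to de-escalation:

```python
wi = bd.what_if(design, data, hypothetical_arm=4)
print(wi.rows[["dlt_treat", "prob_overdose", "recommended_arm", "action"]])
```

```
 dlt_treat  prob_overdose  recommended_arm      action
         0         0.0009                4        stay
         1         0.0064                4        stay
         2         0.0296                4        stay
         3         0.0956                4        stay
         4         0.2293                3 de-escalate
```

Operating characteristics under a true dose-toxicity scenario (control
10%, doses 15/30/45/60% — target at dose 2):

```python
sc = bd.default_scenarios()[1]
oc = bd.operating_characteristics(sc, design, n_sims=2000, seed=11)
print(oc.selection_prop)   # [0.162 0.558 0.242 0.038] — 55.8% correct selection
print(oc.stop_prop)        # 0.001
```

A command-line interface mirrors the library:

```bash
bayesdose simulate --scenario scenario_2 --n-sims 2000 --seed 1
bayesdose benchmark --scenario scenario_1 --n 30 --reps 100000 --seed 3
bayesdose calibrate --n-sims 500 --seed 7 --subset mu2=-0.05
bayesdose update --data trial.csv --out report.json
bayesdose whatif --data trial.csv --arm 4
bayesdose sensitivity --data trial.csv --arm 2
```

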