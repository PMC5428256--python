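# uroflow

Bladder-filling rate modelling and adaptive ultrasound scan scheduling for
radiotherapy preparation.

## The problem

Pelvic radiotherapy (e.g. for cervical cancer) is delivered with a full
bladder to push the small bowel out of the high-dose region, and the bladder
volume (BV) at each treatment fraction should match the volume at the
planning CT to within ±15%.  In practice patients cannot reproduce their
bladder filling reliably, so technicians re-scan with a portable ultrasound
every 10 minutes until the volume is right — costing scans, waiting time and
patient discomfort.

Bladder volume grows linearly with time after voiding, so each patient has a
well-defined **mean urinary inflow rate** `v_tot` (ml/min).  `uroflow`
implements the full analysis around a parameterized population model of that
rate,

```
v_tot = v0 + k_age * P_age + k_wat * P_wat + k_bmi * P_bmi
```

where `v0` is the net urinary inflow rate (ml/min), `P_age` is age (yr),
`P_wat` the pre-session water intake (ml) and `P_bmi` the body-mass index
(kg/m²; its effect is negligible and dropped in the two-covariate model).
The package provides:

- **`uroflow.cohort`** — a seeded synthetic-cohort generator: covariates over
  clinical ranges, latent rates from the linear model plus patient scatter,
  linear BV growth, multiplicative measurement noise, bounded scan-time
  jitter and post-void residual urine;
- **`uroflow.inflow`** — per-patient slope estimation by weighted least
  squares, with and without scan-time uncertainty (effective-variance fit),
  and chi-square goodness-of-fit probabilities;
- **`uroflow.population`** — the population model, statsmodels-style:
  `InflowRateModel(records).fit(method=...)` returns an `InflowModel` results
  object.  Methods: multivariable OLS (`regression2`/`regression3`) and an
  `iterative` alternating fit that decomposes the rate covariate by covariate;
- **`uroflow.validation`** — measured-vs-predicted relative deviations,
  consistency classification at a tolerance (default 0.42) and the tolerance
  derivation rule;
- **`uroflow.scheduler`** — simulation of the model-guided pre-treatment
  workflow: predicted first scan time, correction factor on inconsistent
  scans, void/wait/treat decisions, scan-count and waiting-time summaries;
- **`uroflow.pipeline` / CLI** — a reproducible end-to-end pipeline
  (`uroflow run-all --seed 2 --out bundle/`).

## Worked example

```python
import numpy as np, uroflow

cfg = uroflow.CohortConfig(n_patients=25, seed=7)          # default noise settings
cohort = uroflow.generate_cohort(cfg)
rng = np.random.default_rng(11)
trajs = uroflow.simulate_cohort_trajectories(cohort, range(0, 70, 10), cfg, rng)

fit = uroflow.fit_inflow_plain(trajs[0])                   # one patient's slope
records = uroflow.estimate_cohort_rates(cohort, trajs)     # all 25 slopes
model = uroflow.InflowRateModel(records).fit(method="regression2")
print(model.summary())
```

prints

```
patient P001: v_tot = 2.009 +/- 0.073 ml/min (chi2/ndf = 2.31/5, prob = 0.805)
Population inflow-rate model
  method: regression2    n = 25
    coef     estimate    std err    p-value
      v0       3.1359     0.7195     0.0003
   k_age      -0.0471     0.0120     0.0008
   k_wat       0.0069     0.0009     0.0000
```

The fitted coefficients recover the generating truth (3.115, −0.047, 0.007)
within their standard errors: older patients fill more slowly, drinking more
fills faster.  The model then predicts a new patient's rate and drives the
scan schedule:

```python
model.predict(55, 300)        # -> 2.626 ml/min for a 55-yr-old drinking 300 ml
out = uroflow.run_session(cohort[0], model, uroflow.ScheduleConfig(),
                          np.random.default_rng(1), noise_cv=0.05)
# -> 2 scan(s), wait 38.0 min, success: True
```

i.e. the first scan (taken at the predicted fill time) was out of the ±15%
band, the scan-implied rate corrected the model, and the second scan landed
in tolerance.

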