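# mpapk — population pharmacokinetics of mycophenolic acid in renal transplantation

Mycophenolic acid (MPA, dosed as its prodrug mycophenolate mofetil, MMF) is a
first-line immunosuppressant after kidney transplantation.  Its exposure
target is an area under the concentration–time curve over one 12-hour dosing
interval at steady state (AUC_ss,12h) of 30–60 mg·h/L, but apparent clearance
roughly halves between the first post-transplant week ("early" stage) and the
stable period years later — so the dose that is right early on overexposes a
stable patient.

`mpapk` implements the complete model-based workflow around this problem for
pharmacometricians and clinical-pharmacology researchers:

* a **two-compartment oral-absorption model** with lag time, solved in closed
  form: central concentration after a dose D,

  `C(t) = (ka·D/V) · [A·e^{−α(t−Tlag)} + B·e^{−β(t−Tlag)} + C·e^{−ka(t−Tlag)}]`,

  parameterised by CL/F, V/F, Q/F, V2/F, ka, Tlag, with hybrid exponents
  α, β from k10 = CL/V, k12 = Q/V, k21 = Q/V2;
* a **nonlinear mixed-effects (FOCE with interaction) estimator** with
  lognormal inter-individual variability (`p_i = p_typ·e^{η}`, diagonal Ω),
  proportional residual error (`C_obs = C_pred·(1+ε)`), stepwise covariate
  selection (forward ΔOFV > 6.63, backward ΔOFV > 10.83) and a nonparametric
  bootstrap;
* **non-compartmental analysis** (linear trapezoid, terminal slope, CL/F,
  dose-normalised AUC);
* **Monte Carlo dose simulation**: probability of target attainment (PTA) for
  0.25–1.5 g bid regimens in both stages;
* **limited sampling strategies**: AUC from 3–4 timed samples by Bayesian
  (MAP) estimation or stepwise regression, scored by r, PE% and RMSE;
* a **synthetic-cohort generator** reproducing the study design (51 early +
  48 stable subjects, 10 samples over the day-4 dosing interval), so the
  whole pipeline is testable without any clinical data;
* model diagnostics: CWRES tables and the prediction-corrected visual
  predictive check (pc-VPC).

The default `PopulationModel.renal_transplant()` carries the published final
estimates (CL/F 23.36 L/h, V/F 78.07 L, V2/F 554.52 L, Q/F 29.53 L/h,
ka 1.36 h⁻¹, Tlag 0.23 h; stage coefficients −0.82 on CL and −2.54 on V;
proportional error sd 0.37).

## Worked example

```python
from mpapk import PopulationModel
from mpapk.dosing_sim import regimen_table

model = PopulationModel.renal_transplant()
table = regimen_table(model, n=1000, seed=1)
print(table[["stage", "dose_mg", "median", "pta_percent", "optimal"]])
```

prints (seed 1):

```
 stage  dose_mg  median  pta_percent  optimal
     0   1000.0    35.7         54.3    False
     0   1250.0    45.2         60.4     True
     1    500.0    33.2         50.2     True
     1    750.0    51.2         48.3    False
     ...
early: best regimen 1.25 g bid (PTA 60.4%)
stable: best regimen 0.50 g bid (PTA 50.2%)
```

`median` is the median simulated day-4 AUC_ss,12h in mg·h/L and
`pta_percent` the share of 1,000 virtual patients inside 30–60 mg·h/L: early
patients need 1.0–1.5 g twice daily, stable patients 0.5–0.75 g — the
two-fold clearance difference translated into dosing guidance.

Each script in `examples/` demonstrates one capability end to end
(cohort simulation + NCA, model fitting, dose selection, limited sampling,
diagnostics) and prints a short interpretation with its numbers.

A thin CLI mirrors the pipeline stages:

```bash
mpapk generate --out cohort.csv --seed 1
mpapk nca --data cohort.csv --out nca.csv
mpapk simulate --n 1000 --seed 1
```

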