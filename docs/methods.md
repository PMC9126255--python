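# Methods

## Structural model

MPA disposition is a two-compartment model with first-order absorption from a
depot, an absorption lag time, and linear elimination from the central
compartment.  All volumes and clearances are apparent (bioavailability-scaled,
"/F"); doses are milligrams of MMF as administered, with no prodrug-to-MPA
molar conversion — bioavailability and the conversion factor are absorbed
into /F, so none of the parameters may be read as blood-flow-limited
physiological quantities.

The model is parameterised clinically — CL/F, V/F, Q/F, V2/F, ka, Tlag —
rather than by micro rate constants.  The closed-form solution superposes,
over doses, three exponentials in the hybrid rates α and β (the roots of
s² − (k10+k12+k21)s + k10·k21, with k10 = CL/V, k12 = Q/V, k21 = Q/V2).  The
implementation is verified against stiff ODE integration of the
depot/central/peripheral system to < 10⁻⁶ relative error.  The removable
singularity at ka = α or β is handled by a 10⁻⁷ relative nudge of ka, which
changes concentrations far below measurement resolution.

Default parameter values (the published final estimates):

| parameter | value | units | role |
|---|---|---|---|
| ka | 1.36 | 1/h | absorption rate |
| V/F | 78.07 | L | central volume |
| V2/F | 554.52 | L | peripheral volume |
| CL/F | 23.36 | L/h | clearance (early stage) |
| Q/F | 29.53 | L/h | intercompartmental clearance |
| Tlag | 0.23 | h | absorption lag |
| dVdStage | −2.54 | — | stage effect on V (log scale) |
| dCLdStage | −0.82 | — | stage effect on CL (log scale) |
| ω² (V, CL, ka, V2, Q, Tlag) | 1.03, 0.20, 0.34, 1.72, 0.98, 0.74 | — | IIV variances |
| σ (proportional) | 0.37 | — | residual error sd |

Inter-individual variability is lognormal, `p_i = p_typ·exp(η)`, η ~ N(0, Ω)
with diagonal Ω; the categorical post-transplant stage (0 = first week,
1 = ≥5 years) acts multiplicatively, `p_typ·exp(coeff·stage)`; continuous
covariates, when tested, enter as powers of the median-normalised value.
Residual error is proportional, `C_obs = C_pred·(1+ε)`.

A reporting inconsistency in the source estimates is worth noting: the
early-stage V/F (78.07 L) combined with the stage coefficient −2.54 gives a
stable-stage typical V/F of 6.2 L, while the accompanying text reports
16.24 L; no standard covariate form reconciles the two.  The package follows
the tabulated coefficient form throughout (the clearance pair, 23.36 →
10.29 ≈ 10.25 L/h, is exactly consistent and is the normative example).

Several printed parameters also differ qualitatively from most published MPA
models in that the variabilities are very large (ω² up to 1.7, i.e. >130%
CV); the estimation-related consequences are discussed below.

## Estimation (FOCE with interaction)

The marginal likelihood is approximated per subject: the joint density of
data and random effects is maximised over η (damped Newton with a
Gauss–Newton Hessian, the exact gradient of the η-dependent proportional
variance term, per-subject Levenberg damping, and an analytic model Jacobian
chained through the hybrid rates); the model is then linearised at the mode
and the Gaussian integral evaluated through the 6×6 Woodbury complement.
With Ω → 0 the objective reduces exactly to the weighted least-squares
deviance; on one-random-effect problems it agrees with adaptive
Gauss–Hermite quadrature to < 0.5 of a −2LL unit.

Two numerical choices deserve explanation:

* **Onset smoothing.**  A subject's individual lag time can sit exactly on a
  sampling time, where the exact model's Jacobian is discontinuous and the
  conditional mode jumps.  Inside the likelihood kernels only, the
  absorption-onset indicator is replaced by a C¹ smoothstep of width
  0.005 h (~18 s); predictions differ from the exact model only within that
  window.  Simulation, NCA and exposure integrals always use the exact
  model.

* **Outer optimiser.**  Even smoothed, the conditional-mode surface is only
  piecewise smooth: with the very large ω² of this model, subjects' modes
  hop between local optima of their joint density as the population
  parameters move, leaving jumps of a few tenths of an OFV unit that defeat
  line-search quasi-Newton methods.  The outer minimisation therefore uses
  a sign-based resilient-propagation scheme (iRprop−) with per-coordinate
  adaptive steps, run in log rate-constant coordinates
  (log k10, k12, k21 instead of log CL, Q, V2 — the data pin the rates, so
  this decorrelates the steepest valley), with the mode search re-anchored
  at every accepted step so it follows a continuous path.  Starting values
  come from non-compartmental results (stage-median dose/AUC for clearance,
  the terminal volume for the volumes, and the log clearance ratio for the
  stage coefficients).

Standard errors come from the central-difference Hessian of the objective
(step 10⁻⁴ on the log scale; covariance 2H⁻¹), CV% = 100·SE/estimate, and
η-shrinkage is 100·(1 − sd(η̂)/ω).

**Covariate selection** is classical greedy forward inclusion / backward
elimination against χ² thresholds (defaults 6.63 at p = 0.01 and 10.83 at
p = 0.001, 1 df).  Because the piecewise-smooth objective leaves residual
optimiser drift between independently minimised fits, the improvement
attributed to a term is measured as a *paired* statistic: the fitted model
and the same model with that coefficient zeroed are evaluated by one
objective call from shared mode anchors, so drift cancels.  Candidate
coefficients start from the empirical-Bayes-eta regression on the covariate
(the classical screening estimate) — with large ω² the etas absorb an
unmodelled covariate almost completely and a zero start sits in a locally
flat region.

**Known limitation — recovery bias at the published variabilities.**  With
ω² of 1.0–1.7 on the volumes and flows and a 10-sample design, the
likelihood surface carries a long ridge: parameter sets with V/F tens of
percent from the generating values fit the data essentially as well (an
importance-sampling evaluation of the exact marginal likelihood rates such
points as statistically tied), and the FOCE linearisation error (~2% of
−2LL here) systematically prefers a shifted region of that ridge.
Simulate-and-refit at the study's own design therefore recovers the
clearance stage coefficient, ω²CL and σ well, but several structural
typicals (V, V2, CL, ka) show biases beyond 15%, and stepwise selection can
occasionally attribute the whole stage shift to one of CL or V rather than
both — a property of conditional-linearisation estimation in this regime,
reproduced faithfully rather than patched; the acceptance suite measures
and reports it.  Under moderate variability (ω² ≈ 0.05) the same machinery
recovers all parameters within a few percent.

## Synthetic cohorts

The generator emulates the clinical design: 51 early + 48 stable subjects;
twice-daily dosing with per-dose amounts drawn from stage-specific truncated
normals on the daily dose (1.69 ± 0.44 g/day early, 1.09 ± 0.29 g/day
stable), halved and rounded to the 250 mg menu (500–1500 mg early,
250–750 mg stable per administration); 7 doses administered, with the 7th
(72 h, "day 4") opening the sampled interval; samples at 0, 0.5, 1, 1.5, 2,
3, 4, 6, 8 and 12 h post-dose; lognormal η on all six parameters and
proportional noise on every observation; values below the 0.04 mg/L
quantification floor flagged (discarded by default at estimation; LLOQ/2
imputation available).  Demographics (age, weight, albumin, creatinine
clearance, serum creatinine) are drawn from stage-specific normals matching
the study cohort but have no effect on the kinetics — they exist so
covariate selection can be null-tested.

What the generator does **not** emulate: enterohepatic-recirculation
secondary peaks, delayed-absorption subpopulations, sampling-time jitter
(optional flag, off by default), per-subject missing/extra samples, or any
real demographic–PK correlation.  Passing recovery tests therefore
demonstrate internal consistency of the estimator under the stated model,
not robustness to those real-data features.

## Exposure metrics and simulation conventions

NCA uses the linear trapezoid with linear interpolation of interior missing
values; λz is a log-linear fit of the last 3 monotone-decreasing positive
observations (configurable); Cmin is the pre-dose (trough) observation;
CL/F = dose/AUC_ss,12h; Vd/F = CL_F/λz; dose-normalised AUC is per gram of
MMF.  Tmax is reported both per interval and as absolute time since the
first dose (the day-4 interval makes absolute Tmax ≈ 74 h).

Model-based interval AUCs use the composite trapezoid at 0.01 h steps
(error ≪ 0.1% at these time constants).  Monte Carlo dose assessment draws
all six etas, applies the stage covariates, simulates bid dosing from t = 0
and integrates each *noise-free* individual curve over the 72–84 h interval
(residual error is measurement noise, not exposure; an option includes it
for sensitivity).  A closed-form configuration, AUC = dose/CL_i, is kept as
a cross-check oracle — it is the exact steady-state value, whereas at day 4
accumulation is only ~91% (early typicals) and ~76% (stable typicals)
complete, because the terminal half-lives are ~31 h and ~51 h.  That gap is
why the day-4 stable-stage PTA at 0.5 g bid computes to ~49% while the
steady-state configuration gives ~54%; the exact recipe behind the
published percentages is not fully specified, and both configurations are
exposed.

## Limited sampling

The Bayesian route estimates MAP etas from the scheme's samples only,
reconstructs the profile at the full 10-point design and integrates by
trapezoid; the regression route is stepwise-forward OLS (entry p < 0.05) of
observed AUC on the scheme concentrations, fitted per stage, in-sample by
default with a leave-one-out option.  PE% = (AUCpred − AUCobs)·100/AUCobs
and RMSE is the root mean square of the PE% values (the conventional
definition).  The observed reference AUC is the trapezoid over the full
observed (noisy) profile.  Note the all-points regression is exact by
construction: the trapezoid AUC is a fixed linear combination of the design
concentrations.

## Problem sizes used by the test suite

Unit tests run on reduced cohorts (12–24 subjects).  The acceptance suite
uses: 20 simulate-and-refit replicates at the full 99-subject design with
capped optimiser budgets (≤120 outer iterations per fit, shorter for warm
nested fits); 100 permuted-null covariate tests (5 per cohort); 1,000
virtual subjects per simulated regimen arm; 50 one-eta quadrature
comparisons; and one 99-subject cohort for the limited-sampling table.  The
bootstrap is exercised at small replicate counts in the unit tests; the
production default remains n = 1000.
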