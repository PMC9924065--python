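# Methods

This note documents the models, numerical methods, synthetic-data
assumptions and design choices behind `cpg2mtx`.

## Structural models

**CPG2 (glucarpidase).** Plasma CPG2 follows one-compartment intravenous
infusion kinetics with first-order elimination (clearance `CL`, volume `V`,
`ke = CL/V`). The concentration–time course is the closed-form superposition
of zero-order infusion responses; the `CL → 0` limit is handled with a
stable `expm1` formulation. Concentrations are in mg/L; doses in enzyme
units (U) are converted to mass by a potency constant (below).

**MTX (methotrexate).** Plasma MTX follows two-compartment kinetics with
first-order renal elimination and an enzymatic decomposition flux catalysed
by circulating CPG2:

    dXc/dt = -(Kr + Knr + K12)·Xc + K21·Xp - α·[CPG2]·[Xc]/(Km + [Xc])
    dXp/dt =  K12·Xc - K21·Xp

with amounts `Xc`, `Xp` in µmol, `[Xc] = Xc/Vc` in µmol/L, and micro
constants tied to the physiological parameters by `CLr = Kr·Vc` and
`Q = K12·Vc = K21·Vp`. The decomposition flux is Michaelis–Menten in the
MTX concentration with maximum rate `Vmax = α·[CPG2]`; `α` is the
conversion constant between catalyst concentration and maximum rate. The
general first-order non-renal constant `Knr` is retained as an option but
is zero in the final model, where all non-renal elimination is carried by
the catalyst term. Cumulative renal and degraded amounts are integrated as
extra states so that mass balance is checkable at every output time.

**Final covariate model** (typical values; body weight standardised at
60 kg, so the /60 divisors are part of the formulas):

    CLr = 3.248 · BW/Scr/60   (L/h)       Vc = 0.386 · BW/BSA   (L)
    Vp  = 3.052 · BW/60       (L)         α  = 6.545e5          (model units)
    Q   = 0.0778 L/h (fixed)              Km = 86 µmol/L (fixed)

Inter-individual variability is lognormal per parameter,
`θ_i = tvθ·exp(η_i)`, `η ~ N(0, ω²)`, with ω² diagonal. CV values are
converted by `CV = sqrt(exp(ω²) − 1)` (the plain `sqrt(ω²)` reading differs
by <2% at these magnitudes). Residual error is additive in mg/L for CPG2
and proportional for MTX.

### Units and the potency constant

`Km` is published in µmol/L, so MTX state is kept in µmol and µmol/L. CPG2
assay limits are mass-based, so CPG2 concentrations are mg/L. `α` therefore
carries units (µmol/h)/(mg/L) internally; its published magnitude is kept
as a model-unit constant because its printed unit derivation does not
dimension-check, and which catalyst unit the original software used
internally is not recoverable. The U→mg conversion
(`cpg2_units_per_mg`, default 1000 U/mg) is **only** used by the simulator
to turn U doses into mass; estimation from concentration data never needs
it, and any absolute statement that depends on simulated CPG2
concentrations (e.g. how deep the MTX crash goes) is conditional on it.

### Numerical integration

The MTX system is integrated piecewise between dose-event boundaries.
Segments that end before the first CPG2 dose are constant-coefficient
linear and advanced exactly by an augmented matrix exponential; from the
first CPG2 dose onward the stiff-capable adaptive LSODA integrator is used
with an analytic Jacobian (the catalyst term makes the system stiff: with
typical parameters the effective elimination rate immediately after dosing
is ~10²–10³ h⁻¹ against distribution rates of ~10⁻² h⁻¹). Simulation
tolerances are rtol 1e-8 / atol 1e-10; the estimation path relaxes to
rtol 1e-6 / atol 1e-6 (µmol), which changes the objective by well under
0.1 units while roughly halving cost. A bolus at time t takes effect for
times strictly after t, so an observation recorded at a dose instant reads
the pre-dose state (the 48-h sample is drawn before the second CPG2 dose).
An independent matrix-exponential solver for the catalyst-free linear
system serves as the oracle for the `α = 0` limit and for back-scaling
infusion amounts in the generator.

## Synthetic cohorts

The generator emulates the two study designs so the full pipeline runs
without external data.

*Phase 1*: 16 healthy adult volunteers, two CPG2 arms (20 and 50 U/kg,
8 each), 5-min infusions at 0 and 48 h; sampling pre-dose, 5 min, 15 min,
2, 8, 12, 24, 48 h after the first dose and 5 min, 8, 12, 24, 48 h after
the second. The pre-dose draw has true concentration zero and is emitted
flagged below the limit of quantification, leaving 12 quantifiable samples
per subject. Covariates are drawn uniformly on the published demographic
ranges (height 162.6–184.8 cm, weight 54.3–66.9 kg, age 20–40 y).

*Phase 2*: patients with delayed MTX excretion. Weight, age, serum
creatinine and dose intensity are drawn log-uniformly on the published
ranges (10.7–78.1 kg, 1–75 y, 0.23–3.47 mg/dl, 2.9–14.3 g/m²); height is
tied to weight through a weight-dependent body-mass index so children stay
child-sized. The delayed-excretion phenotype is produced by drawing the
target pre-CPG2 MTX concentration log-uniformly on 1.02–692.32 µmol/L and
scaling a 6-h HD-MTX infusion (ending `hours_post_mtx − 6` before CPG2)
so the linear pre-CPG2 model hits that concentration exactly at the CPG2
start. Hours-post-MTX and the acute-renal-failure flag are chosen so every
subject satisfies one row of the selection table by construction, and the
generator asserts this. A second 50 U/kg CPG2 dose is appended at 48 h
when the true MTX concentration exceeds 1 µmol/L at the 46-h check, which
also extends the MTX sampling schedule to 72 and 96 h. Window samples
(5–8 h shared between assays, 12–20 h for CPG2) are recorded at their
realised times. Residual error is applied per the analyte's error model;
negative draws are floored at zero and flagged; assay censoring applies
the published limits (MTX 0.5 ng/ml via the molar mass 454.44 g/mol, CPG2
1 ng/ml), values above the upper limit are assumed diluted into range.

What the generator does **not** emulate: assay cross-reactivity with
metabolites, leucovorin rescue, urine data, correlated covariates beyond
the height–weight tie, informative dropout, or any real-data error
structure beyond the stated models — so passing recovery tests shows
internal consistency of simulator and estimator under the published
conditions, not performance on clinical data.

A consequence worth stating plainly: the published MTX residual SD (1.414,
proportional) implies that roughly a quarter of error-perturbed draws are
negative, floored to zero, censored, and dropped by the M1 rule. The
retained errors are then left-truncated with positive mean, which an
uncorrected likelihood absorbs as upward bias in some typical values (most
visibly renal clearance, ~+30% at n = 30). The recovery harness reports
this honestly; with a moderate residual SD (0.3) the same harness recovers
typical values to within sampling error, isolating the truncation effect.

## Estimation

The marginal likelihood is approximated in the FOCE/Laplace family. Per
subject, the conditional mode of η minimises the penalised deviance
`h(η) = ½Σ[r²/g² + log 2πg²] + ½η'Ω⁻¹η` by damped Gauss–Newton with line
search, a trust cap of 3 log units per step, warm starts across outer
iterations, and a reset to the prior mode whenever a stale warm start is
worse than η = 0 (the inner problem can be multimodal). The subject's
−2 log-likelihood is the Laplace expression at the mode. For closed-form
models the log-determinant uses an exact central-difference Hessian of
`h`; for the ODE model it uses the Gauss–Newton (FOCE-with-interaction)
form `Ω⁻¹ + J'WJ`, whose cost is one Jacobian instead of ~13 extra ODE
solves. The proportional-error SD is floored via `g² = σ²(f² + 1e-12)` so
a transiently zero prediction cannot produce an infinite weight. Validated
against adaptive Gauss–Hermite quadrature on a one-random-effect toy
(agreement within 0.1 OFV units across a parameter grid; the discrepancy
grows with deliberate model misspecification, as expected of a Laplace
approximation).

The outer problem maximises over log-transformed typical values, ω² and σ²
(covariate exponents untransformed). Two optimisers are used, chosen by
whether the model's objective is smooth to machine precision:

* closed-form CPG2 models: bounded quasi-Newton (L-BFGS-B), convergence at
  relative OFV change < 1e-9;
* the ODE-based MTX model: a derivative-free quadratic response-surface
  trust-region search (axial + pairwise stencil, least-squares quadratic
  fit, constrained model step; radius 0.25 shrinking by 0.4 over three
  rounds). Adaptive integration leaves ~0.03 units of evaluation noise on
  the objective, which stalls finite-difference quasi-Newton methods,
  while the stencil fit averages over it.

Standard errors come from a central-difference Hessian of the approximate
−2LL in the transformed space, delta-transformed back; the sandwich
estimator is out of scope. Q and Km are structural constants of the MTX
model and never enter the parameter vector. The coupled analysis is
sequential: the CPG2 population fit supplies per-subject empirical-Bayes
CPG2 parameters, which become the fixed catalyst forcing of the MTX fit —
so the MTX random effect is four-dimensional. Below-LLOQ records are
dropped (M1). Empirical-Bayes (MAP/post-hoc) estimation fixes the
population parameters and reuses the inner solver; with no observations it
returns the covariate-model typical values, flagged.

Covariate screening adds one power term at a time to CL or V and compares
the OFV drop to χ²(1); forward–backward stepwise selection includes at
p < 0.001 (ΔOFV > 10.828), eliminates at the same threshold, and breaks
equal-drop ties by AIC. Candidate fits run from three starts (exponent 0,
exponent 1, and exponent 1 with deflated IIV) because the single-start
fit reliably lands in a local optimum where inflated IIV absorbs the
covariate signal.

## Diagnostics

Goodness-of-fit tables report PRED (η = 0), IPRED (empirical-Bayes mode)
and CWRES — the FOCE conditional weighted residual obtained by linearising
about the mode: `y ~ N(f(η̂) − Jη̂, JΩJ' + diag g²)`, whitened by the
Cholesky factor. The bootstrap resamples subjects with replacement,
refits, and reports medians with 2.5/97.5 percentile intervals and the
convergence fraction; replicate seeds derive from the master seed. The VPC
simulates the original design (same covariates, doses and observation
times), bins by nominal schedule label (window draws bin by their window),
and overlays observed 5/50/95th percentiles on 95% envelopes of the same
statistics across replicates; per-subject random streams are keyed by
subject id so the result is invariant to subject ordering. Prediction-
corrected VPC and npde are out of scope.

## Limited-sampling forecasting

For each non-empty subset of {pre-dose, 20 min, 2 h, 5–8 h, 24 h} (31
subsets), the 48-h MTX concentration is forecast by MAP estimation
restricted to the subset's observations followed by forward simulation.
Scores are ME/MAE/RMSE in the plain `pred − obs` convention and the hit
ratio — the fraction of subjects classified on the same side of
1.0 µmol/L, the redosing threshold. Exactly 1.0 counts as "over" (≥),
consistent with the second-dose trigger; note the clinical wording mixes
">" and "over or under". On synthetic cohorts the reference 48-h value is
the error-free simulated concentration by default; a flag switches to the
recorded observation to mirror a clinical comparison. The 5–8 h point is
represented by its realised sampled time.

## Problem sizes used by the test suite

Parameter-recovery runs use 10 replicate CPG2 fits at n = 50 and 3
replicate coupled-model fits at n = 30 with variance components held at
their generating values (the typical values are the quantities under
test); the limited-sampling sweep uses a 10-subject cohort; the bootstrap
and VPC unit tests use 4–16 subjects and 1–50 replicates. These sizes were
chosen to exercise every code path at meaningful signal-to-noise on a
single CPU; the estimators themselves accept arbitrary sizes.

## Known limitations

* The Laplace/FOCE objective is an approximation; its error grows with
  sparse data, strong nonlinearity and gross misspecification.
* The M1 treatment of censored records is the classic, biased choice; a
  censoring-aware likelihood (M3) is not implemented.
* Ω is diagonal; parameter correlations are not estimable here.
* The sequential CPG2→MTX coupling ignores CPG2-parameter uncertainty in
  the MTX stage.
* Absolute simulated CPG2 concentrations (hence the depth of the MTX
  crash) scale with the potency constant, which is a configuration value,
  not a measured quantity.
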