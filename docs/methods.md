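# Methods

## Model

For subject i = 1..n, outcome k ∈ {RR, PR, OX} and time t (hours since
admission), the longitudinal sub-model is a multivariate linear mixed
model on the visit scale v = t/6 (measurements are scheduled 6-hourly):

    y_ik(t) = x_ik'β_k + β_k,visit · v + b_ik0 + b_ik1 · v + ε_ik(t),
    b_i = (b_i,RR0, b_i,RR1, b_i,PR0, b_i,PR1, b_i,OX0, b_i,OX1) ~ N(0, D),
    ε_ik(t) ~ N(0, σ_k²), independent across rows given b_i.

x_ik collects baseline covariates (one-hot expanded against declared
reference levels). D is an unstructured 6×6 covariance, so baseline
levels and slopes of the three vitals are all mutually correlated. A
per-visit slope is six times the per-hour slope.

The survival sub-model is a proportional-hazards model for the recovery
time with a piecewise-constant baseline on knots s_0 < … < s_B (zero
hazard before s_0, last height extended beyond s_B):

    h_i(t) = λ_b(t) · exp( ζ'x_i + Σ_k γ_k m_ik(t) ),

where m_ik(t) = x_ik'β_k + β_k,visit·v + b_ik0 + b_ik1·v is the
current (error-free) value of outcome k. Because each m_ik is linear in
t, the subject-specific cumulative hazard is a closed-form sum of
(e^{Cu} − e^{Cl})/C terms over the baseline intervals; the same closed
form is used by the likelihood and, inverted analytically, by the
simulator, so generator and estimator share one hazard definition. A
`random-effects` association variant (w_i(t) = Σ_k γ_k(b_ik0 + b_ik1 v))
is available via `JointModel(association=...)`; the current-value form is
the default because γ is interpreted as linking the longitudinal
measures themselves to recovery.

The event is recovery: γ_k > 0 means higher current values of outcome k
shorten the stay. This inverts the usual mortality intuition and is
stated on every summary table.

## Estimation

* **Cox (separate)**: Newton–Raphson with step-halving on the Breslow
  partial likelihood; convergence at gradient max-norm < 1e-8; SEs from
  the inverse observed information; Wald 95 % CIs on the log scale.
  Ties use the Breslow approximation (simulated times are continuous, so
  ties are measure-zero). Coefficients beyond ±15 are reported as
  monotone-likelihood failures (perfect separation).
* **MLMM**: exact ML. The fixed effects are profiled out by generalized
  least squares; quasi-Newton (L-BFGS) maximizes over the log-Cholesky
  factor of D and log σ with an analytic profile gradient (envelope
  theorem). The marginal covariance V_i = Z_i D Z_i' + diag(σ²) is
  factored directly (never through D⁻¹), so boundary estimates with
  singular D — which genuinely occur here — stay numerically stable.
  SEs come from the inverse numeric observed information of the full
  likelihood. ML (not REML) is used so log-likelihoods are comparable
  with the joint model.
* **Joint model**: full ML over (β, log-chol D, log σ, ζ, γ, log λ).
  The 6-dimensional random-effect integral uses adaptive Gauss–Hermite
  quadrature, 3 nodes per dimension (729 tensor nodes, pruned below
  relative weight 1e-8), centered and scaled at each subject's posterior
  mode found by a damped Newton iteration with analytic gradient and
  Hessian (the complete-data log-density is strictly concave in b). An
  antithetic Monte-Carlo importance sampler around the same mode is
  retained purely as a cross-check; tests require the two integrators to
  agree within 1e-3 relative.

### Optimization of the joint likelihood

The raw parameterization is badly conditioned: γ multiplies current
values of magnitude ~50–150, so curvatures span about six orders of
magnitude, and γ trades off against the baseline heights along a narrow
curved valley. Three measures make the fit reliable:

1. **Centering.** Inside the fit the association uses
   m_ik(t) − m̄_k with m̄_k the sample mean of outcome k; the shift is
   absorbed by log λ and removed again before parameters are reported.
2. **Preconditioned, restarted L-BFGS.** A diagonal preconditioner from
   finite-difference curvatures rescales every direction to unit
   curvature; L-BFGS runs with an analytic score obtained from the
   Fisher identity (posterior-weighted complete-data score on the
   quadrature nodes) and is restarted, with the preconditioner
   recomputed, until the log-likelihood stabilizes.
3. **Two-phase fitting.** Under strong association the likelihood is
   multimodal in γ, with a spurious mode near the attenuated two-stage
   estimate. The fit therefore starts from a Cox fit on BLUP-predicted
   current values, maximizes the survival block (ζ, γ, log λ) with the
   longitudinal block frozen at the MLMM estimates, and only then
   releases all parameters. The γ = 0 initializer
   (`initialize_from_separate`) is retained as the documented two-stage
   start and as the fallback when the auxiliary Cox fit fails.

Convergence is declared at relative log-likelihood change below 1e-8
(stricter than the 1e-6 the reporting requires). SEs come from the
numeric observed information evaluated by central differences of the
objective in preconditioned coordinates (step = 5 % of each direction's
curvature length-scale); raw fixed-step differences are unusable at this
curvature spread. Boundary variance components can make single diagonal
entries of the inverse information negative; those SEs are reported as
missing rather than silently clipped.

## The synthetic generator

`default_true_params()` encodes a published-cohort-like truth: intercepts
(47.266, 146.743, 87.297), per-visit slopes (−0.195, −0.160, +0.901),
severity effects, residual SDs (8.07, 10.74, 5.21), association
γ = (−0.297, −0.121, 0.5452), and a 6×6 random-effect covariance taken
from the printed table after symmetrization and eigenvalue clipping at
1e-6 (`nearest_psd`) — the printed matrix is not positive semidefinite,
e.g. its PR intercept–slope covariance exceeds the bound implied by the
variances. The "sigma2_k" residual lines are read as standard deviations,
not variances; their magnitudes match the descriptive outcome SDs, which
variances would not.

Baseline hazard: knots {18, 48, 72, 96} h with zero hazard before 18 h
(the earliest observed recovery) and relative heights (1, 1, 120). The
tall final interval reflects the discharge-review dynamics needed to
reproduce the published profile: with the strong association
(Var(γ'm) ≈ 20 on the log-hazard scale) a flat baseline cannot produce
both a 72 h median and ~89 % recovery by 96 h. `calibrate_baseline`
scales all heights by one factor, found by monotone root-finding with
common random numbers at n = 5000, so the simulated Kaplan–Meier median
hits 72 h (±2 h); with the shipped height shape the recovered fraction
then lands at 0.891. Covariate generators: age uniform on 2–59 months,
binary covariates at stated prevalences, severity with three levels
(non-severe/mild-severe/severe at 0.25/0.40/0.35); only the severity
effects enter the default fixed effects and ζ — the remaining covariates
are drawn so that realistic covariate tables and Cox fits are available,
without inflating the default association variance.

Event times solve Λ_i(T) = −log u analytically per interval; the
plug-back identity |Λ_i(T) + log u| < 1e-10 is enforced by tests.

What the generator does *not* emulate: missed visits or irregular
measurement times, measurement error in baseline covariates,
informative censoring other than the administrative 96 h cut-off, serial
(autoregressive) within-subject correlation, and any misspecification of
the linear trajectory shape. Passing recovery tests therefore
demonstrate correctness of the estimator under the model's own
assumptions, not robustness of the model on real hospital data.

## Numerical choices and degenerate inputs

* Time unit is hours; the visit index t/6 is the longitudinal time
  covariate.
* CSV round-trips use Python's shortest-repr float rendering, so
  write → load is bit-exact.
* Kaplan–Meier median: smallest t with S(t) ≤ 0.5, missing if never
  reached; Greenwood variance.
* Piecewise-hazard terms (e^{Cu} − e^{Cl})/C switch to a series expansion
  below |C|·u ≈ 1e-8 and are assembled in log space inside the joint
  likelihood, so drifts of either sign and any magnitude are safe.
* A cohort subject with no longitudinal rows is invalid as data (the
  container requires both tables to cover the same subjects), but the
  BLUP and conditional-likelihood code paths handle the empty case
  (prior mean/covariance) explicitly.
* p-values below 1e-300 are printed as "<1e-300" in human-readable
  tables; machine-readable files carry full precision.
* No multiple-testing adjustment is applied anywhere.

## Problem sizes used by the test suite

The suite exercises the estimators at reduced scale chosen for a
single-CPU run: γ-recovery on three cohorts of n = 75, MLMM fixed-effect
recovery at n = 300, calibration checks at n = 5000 (simulation only),
integrator cross-checks on 5-subject cohorts, and one full pipeline run
at the study size n = 101.

## Known limitations

* The γ-likelihood is multimodal under strong association; the two-phase
  multi-start fit finds the dominant mode on the cohorts tested, but no
  global guarantee exists. `loglik_init_` and `loglik_` let users verify
  the improvement, and fits can be re-run from user-supplied starts.
* Standard errors for variance components at the boundary are reported
  as missing.
* The piecewise-constant baseline is a modelling choice; hazard shapes
  that vary quickly inside an interval are absorbed into the
  time-drift term only through the association.
* No left truncation, competing risks, cure fractions, stratified
  baselines, or time-varying association.
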