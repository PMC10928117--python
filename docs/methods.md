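# Methods

`hwle` estimates healthy working life expectancy (HWLE) — the expected
years from age 50 spent simultaneously healthy and in paid work — from
panel-observed multi-state data with registry-linked exact death ages.
This note documents the model, the numerical machinery, the synthetic
cohort generator, and the design decisions taken where more than one
reasonable choice existed.

## The multi-state model

States form a labelled space with one absorbing death state.  The default
3-state topology is healthy-and-working (HW), not-healthy-and/or-not-
working (nHW) and dead, with HW ↔ nHW movement in both directions and
death reachable from both alive states.  A 5-state variant distinguishes
all four health × work combinations.

Each permitted transition r → s has a Gompertz-type log-linear intensity

    q_rs(a, x) = exp( α_rs + γ_rs (a − 50) + Σ_k β_rsk x_k ),

where `a` is age (the only time scale), `exp(α_rs)` is the baseline
intensity per year at age 50, `exp(γ_rs)` is the per-year-of-age hazard
rate ratio, and `exp(β_rsk)` the HRR of binary covariate k.  Any (transition,
effect) pair can be constrained to HRR = 1 — e.g. workplace factors on
transitions out of the non-working state, where they are undefined.  Age is
included on every transition by default; constraining it off yields the
time-homogeneous models used by the closed-form test oracles.

### Likelihood

States are interval-censored at interviews; death ages are exact but the
state immediately before death is unknown.  Contributions per consecutive
observation pair:

* alive r at t0, alive s at t1:  `log P_rs(t0, t1)`;
* alive r at t0, exact death at td:  `log Σ_{s alive} P_rs(t0, td) · q_{s,dead}(td)`.

Covariates enter at their value at the start of each observation interval
(piecewise-constant between interviews).  P over an interval is computed by
splitting it into sub-intervals of at most `step_years` (default 0.5 y),
freezing the generator at each sub-interval **midpoint**, and composing the
matrix exponentials in order.  The midpoint rule is second-order in the
step; with the default step the residual discretization bias in fitted age
slopes is far below one standard error at cohort sizes of a few thousand
(an earlier left-endpoint variant produced a visible O(step) bias in
integrated expectancies).  An observed transition that is impossible under
the allowed mask yields −∞ (flagged, not raised) in the per-subject
likelihood; `fit` refuses such data with an explicit error.

### Fitting

The log-likelihood gradient is exact: each piece's contribution is a
Fréchet derivative of a matrix exponential in a rank-one direction,
evaluated via scaled Taylor ladders with a doubling recursion (see
`hwle._linalg`; the batched kernels are numba-compiled when numba is
available, with an equivalent numpy path otherwise, both cross-checked
against `scipy.linalg.expm_frechet`).

Optimization is quasi-Newton (scipy BFGS) on an internally *centered*
parameterization: baseline log-intensities are re-anchored at the
person-time-weighted mean observation age and covariate means, which
near-orthogonalizes baselines and slopes and roughly halves the iteration
count; results are mapped back to the age-50 anchoring.  The gradient
tolerance is 1e-5 on the centered problem.  When no stationary point
exists — typically zero observed events on a transition, driving a
baseline to −∞ — a box-bounded L-BFGS-B polish (baselines ≥ e⁻²⁵/y) gives
the boundary MLE a meaningful projected-gradient convergence criterion.
Starting values are crude rates, observed transition counts divided by
person-time at risk.

The covariance of the MLE is the inverse observed information, with the
Hessian from central finite differences of the analytic gradient.  A
singular information matrix (boundary estimates) is inverted after
flipping its spectrum up to a small floor, so flat directions report very
large — not infinite — variances; `covariance_ok_` records whether this
was needed.  Wald CIs use z = 1.96 on the log scale; constrained effects
are reported as "1.00 (fixed)".

## Expectancies

State occupancy from age 50 is propagated over an age grid (default step
h = 0.25 y) to a hard truncation at age 120, with the generator frozen at
each cell midpoint and covariates held fixed over age.  A state expectancy
is the trapezoidal integral of its occupancy; HWLE is the expectancy of
the HW state and life expectancy (LE) the sum over alive states, so the
decomposition HWLE + non-HW years = LE holds to machine precision by
construction.  Halving h moves expectancies by well under 0.005 years at
the defaults.  Occupancy mass remaining at 120 contributes no further
years.

Marginal ("population overall") expectancies weight the conditional-on-
starting-state expectancies by a logistic regression (multinomial for the
5-state space) of baseline state on baseline age, evaluated at age 50.  A
degenerate baseline (one state only) falls back to the empirical shares
with a warning.

Uncertainty is parametric: `n_draws` (default 1000) parameter vectors are
drawn from N(MLE, covariance) — the covariance repaired to PSD by
eigenvalue clipping if needed — expectancies recomputed per draw
(vectorized across draws), and 2.5/97.5 percentiles reported.  Extreme
draws from near-singular covariances are handled by capping intensities at
1e8/y during occupancy propagation (numerically "instantaneous").
Intervals are deterministic given the seed.  Initial-state-model and
grid-truncation uncertainty are not propagated.

## Multiple imputation

Missing interview cells (state or covariate; never death records) are
imputed by predictive mean matching across all waves simultaneously.  The
panel is pivoted to one row per subject with one column per (variable,
wave) plus baseline age and user-chosen auxiliary columns.  Chained
equations run 10 cycles in least-missing-first order; each incomplete
column is regressed (ridge-stabilised OLS with a proper Bayesian draw of
coefficients and residual variance) on all other columns among its
observed cases, and each missing cell receives the observed value of a
donor drawn uniformly from the 5 nearest cases by predicted value (type-1
matching: donors ranked by the posterior-mean prediction, targets by the
drawn-coefficient prediction).  Donor values only — binaries stay binary.
Cells that are structurally absent (waves after death or censoring) are
treated as latent during chaining but never written back.  M = 20
completed panels by default, each from an independent child stream of one
seed.

Per-imputation fits are warm-started from the first converged fit, and a
completed panel identical to the first (e.g. when nothing was missing)
reuses its fit outright; failures are flagged and excluded from pooling
(all-fail is an error).
Scalars pool by Rubin's rules — point = mean, total variance = within +
(1 + 1/m)·between — with a t reference on Barnard–Rubin degrees of
freedom, taking the complete-data df as large (the adjusted df then
reduces to the classical (m−1)/λ²).  HRRs pool on the log scale;
expectancies pool on the year scale with each imputation's Monte-Carlo
variance as the within-imputation variance.

## The synthetic cohort generator

The generator emulates the structure of an English ageing-cohort panel
with mortality linkage: baseline ages 50+ drawn from the band mix
(30/32/25/12/1% across 50–60 … 90–100), ~2-yearly interview waves (default
5) with ±0.2 y uniform jitter, exact death ages within the observation
window (deaths after the last scheduled wave are unobserved, mirroring a
registry that closes with the final wave), binary covariates at realistic
baseline prevalences (osteoarthritis 0.24, mental health problems 0.25,
obesity 0.24, pain interference 0.28, physical inactivity 0.37) evolving
by first-order per-wave flip probabilities, and per-covariate auxiliary
columns (noisy copies, 90% agreement) as imputation predictors.

Trajectories are drawn exactly for a monthly piecewise-constant
approximation of the age-inhomogeneous intensities: a unit-exponential
deviate is inverted against the cumulative hazard accumulated over the
monthly grid, and the destination state is drawn proportionally to the
intensities at the event age.  The initial state follows a logistic law in
age whose intercept (−0.42 at age 50, slope −0.035/y) was calibrated once
so the baseline cross-section is ~27% healthy-and-working under the band
mix.  Generating intensities at 50 (HW→nHW 0.08, HW→dead 0.001, nHW→HW
0.35, nHW→dead 0.0035 per year; age HRRs 1.07/1.06/0.86/1.10) put the
implied age-only HWLE near 9 years and LE near 31.6 years from age 50 —
the regime reported for the English population — and are pinned in the
versioned scenario files `scenarios/elsa_like.yaml` (three covariates with
their published single-covariate HRR profiles) and `scenarios/recovery.yaml`
(one covariate, HRR 1.5 on the HW exit, time-fixed; used for the recovery
and imputation studies).

Missingness injection supports MCAR and MAR on interview cells, never on
death records.  MAR probabilities are logistic in fully observed
quantities — age band (70+), an auxiliary column and, for covariate cells,
the co-observed state — with the intercept calibrated by bisection so the
average rate matches the requested rate, and the truth mask is returned
for recovery scoring.

What the generator does **not** emulate: calendar-period effects, survey
weights, household clustering, covariate correlation at baseline,
measurement error in states, or the real cohort's non-response process.
Passing tests therefore demonstrate internal statistical correctness of
the estimator pipeline under a known generating process, not agreement
with estimates from the restricted-access survey data.

## Simulation studies and problem sizes

The test suite's studies use sizes chosen to give adequate power at
desk scale: parameter recovery and CI coverage use 50 replicates of the
recovery scenario at n = 2000 subjects and 5 waves (coverage for every
free parameter checked against the 88–99% band; marginal HWLE compared to
the generating model's integrated truth within 4 Monte-Carlo standard
errors, floored at 0.03 y for residual discretization); the
imputation-versus-complete-case study uses 20 replicates at n = 600 with
M = 20 imputations and 30% MAR missingness in one covariate.  The MAR
selection there depends strongly on the co-observed state: record-wise
complete-case deletion then conditions on interval outcomes and is
materially biased, which is the failure mode imputation is meant to
repair; a selection that depends only on covariates would leave the
conditional likelihood ignorable and nothing for imputation to fix.

## Known limitations

* Covariates are piecewise-constant between interviews and held fixed over
  age in expectancies (time-independence assumption); both follow from the
  panel design rather than belief about the underlying processes.
* No misclassification/hidden-state layer, no random effects, no survey
  weighting, and no left-truncation adjustment beyond conditioning on the
  first observed state.
* Wald intervals on the log scale can be poor for transitions with very
  few events (boundary MLEs report essentially unbounded upper CI limits).
* The imputation model is linear in the wide predictor matrix; strongly
  non-monotone missingness patterns or continuous covariates would need a
  richer chained model than the binary/state cells handled here.
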