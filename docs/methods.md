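# Methods

This note documents the models, algorithms, numerical choices and
limitations of `hemopk`. Units throughout: concentrations IU/L internally
(clinical thresholds quoted in IU/mL are converted ×1000 at the API
boundary), amounts IU, times hours, clearances L/h, volumes L.

## Dataset dialect

Each subject's record block follows the NONMEM-style layout used in factor
concentrate modeling: a pre-dose record at the time origin carrying PREDOSE
and BASELINE, a dose record whose TIMEH is the infusion duration with
RATE = AMT/TIMEH, then observation rows. TIMEH is truncated — not rounded —
to 4 decimal places (a 10-minute administration is 0.1666 h), so
RATE·TIMEH = AMT holds to truncation error. An unmeasured baseline is
imputed as 0.005 IU/mL (0.5% of normal activity, the conventional upper
bound for severe hemophilia); −1 encodes "absent" for PREDOSE/BASELINE.
Concentrations below the limit of quantification (LOQ, default 0.01 IU/mL =
10 IU/L) become BLQ rows with EVID = 3, MDV3 = 0 (they enter the censored
likelihood) and MDV5 = 1 (they are excluded from residual diagnostics).
The pre-dose record is encoded EVID = 0 with MDV5 = MDV3 = 1 (the
"ignored observation" convention); EVID is restricted to {0, 1, 3}.

Dataset screening flags rising post-infusion concentrations, missing
required values, out-of-range continuous covariates, unexpected categorical
codes, and duplicate records. The rising check compares consecutive valid
observations within one occasion after the end of infusion; its default
tolerance is zero (any rise is flagged, appropriate for data expected to
decline monotonically). Data with appreciable assay noise legitimately
produce chance rises between closely spaced samples, so the check accepts a
relative tolerance; the pipeline, which knows its simulated cohorts carry
~10% CV, screens at tolerance 1.0 (only a more-than-doubled value, about
7σ of pairwise noise, is flagged — a gross-error screen). Every flag must be
resolved as corrected or excluded before analysis; exclusions that leave a
subject without observations drop the subject, and all changes land in an
audit log.

## Structural models

Linear mammillary 1-, 2- and 3-compartment disposition with constant-rate
IV infusion, in the clearance parameterizations (CL, V), (CL, V1, Q, V2)
and (CL, V1, Q2, V2, Q3, V3). The unit-bolus central concentration is
written as Σᵢ wᵢ·exp(λᵢt): for one compartment analytically, for two via
the stable quadratic eigenvalue formulas, for three by eigendecomposition
of the micro-constant matrix (numerically tied eigenvalues are perturbed by
1e−12 relative). An infusion of rate R contributes
R·Σᵢ (wᵢ/λᵢ)(e^{λᵢτ} − e^{λᵢ(τ−T)}) after its end and the expm1 analogue
during; multiple doses superpose. The endogenous baseline is additive and
constant (not a compartment) — standard for factor levels and consistent
with reporting thresholds near baseline. A measured pre-dose level above
baseline is represented as an initial central amount (PREDOSE − BASELINE)·V
decaying per the model; this "decay the residual" reading is the simplest
mechanistic one, and the alternative (constant subtraction) was deliberately
not implemented to keep one documented behavior.

`time_to_level` searches only after the end of the last infusion (clinical
threshold times are elimination-phase quantities), brackets on a 512-point
grid over the search window and refines with Brent's method to < 0.01 h.
A level at or below baseline is reported as never reached; a level above
the end-of-infusion concentration returns the end-of-infusion time.

## Hierarchical model

Individual parameters are log-normal around covariate-adjusted typical
values: θ_ij = TV(θ_i | covariates)·exp(η_ij), η ~ N(0, Ω), with Ω diagonal
or unstructured. Covariate effects come in linear, power, exponential and
categorical-fraction forms, centered at a constant frozen into the model
object (the dataset median by default) so forecasting never re-derives
centering from new data; multiple effects on one parameter compose
multiplicatively, which preserves positivity for the power and exponential
forms. Residual error is additive, proportional, exponential (implemented
as additive error on log concentration, with the LOQ bound transformed
accordingly) or combined additive-proportional,
g = √(f²σ_prop² + σ_add²) — the last is the default, as the most common
choice in PK practice. Inter-occasion (within-subject) variability is not
modeled: for factor concentrates it is small relative to between-subject
variability.

## Estimation

The subject-level joint −2 log-likelihood is

    q_i(η) = Σ_obs [ log 2πg² + ((y − f)/g)² ]
             − 2 Σ_BLQ log Φ((LOQ − f)/g)
             + η'Ω⁻¹η + log|2πΩ|,

with f and g evaluated at the subject's covariates and η — the
η-dependence of g carries the FOCEI-style "interaction". Censored (BLQ)
rows contribute the normal CDF term (the M3 approach) through
`scipy.special.log_ndtr` for stability. The population objective is the
Laplace approximation to −2 log marginal likelihood,
OFV = Σᵢ [q_i(η̂ᵢ) + log det Hᵢ − d·log 4π], where η̂ᵢ is the conditional
mode and Hᵢ the Hessian of q_i there.

Numerics. The inner mode search is a damped Newton iteration run for **all
subjects simultaneously** on padded arrays; each iteration evaluates its
entire finite-difference stencil (step 1e−4) in one stacked call, and the
line search is tolerant of floating-point noise near the mode (Armijo with
an absolute slack of 1e−10·|q|, convergence on gradient < 1e−6 or Newton
decrement below noise). The inner iteration warm-starts from the modes of
the previous outer evaluation (cold start η = 0 on the first); the mode is
still located to tolerance regardless of start, so the objective remains a
well-defined function of the outer parameters while the iteration count
drops by an order of magnitude. The outer optimizer is L-BFGS-B on a fully
unconstrained vector: log typical values, raw covariate coefficients,
log-Cholesky factor of Ω (guaranteeing positive semi-definiteness), log σ.
Standard errors come from the numerical Hessian of OFV/2 at the optimum
with delta-method back-transformation; its eigenvalue ratio is the reported
condition number. Exact 21×21 adaptive Gauss–Hermite evaluation of the
marginal agrees with the Laplace OFV to well under 0.1 units on
one-random-effect problems, and the residual small-sample bias of the
maximum-likelihood estimates on very sparse designs (≈ +1% on clearance for
3-sample subjects) is a property of the exact likelihood, not of the
approximation.

Model comparison uses the objective-function drop against the 95%
chi-squared quantile at the printed two-decimal precision — 3.84 for one
added parameter, with equality counting as superior; for df > 1 the
rounded quantile generalizes the rule. Stepwise covariate selection is
forward-only at that criterion, with the precision requirement
operationalized as the 95% Wald interval of the covariate coefficient
excluding zero; an optional stricter backward pass (6.63, α = 0.01) is off
by default and labeled an extension. The η-vs-covariate screen reports
Pearson correlations (continuous) or one-way ANOVA F (categorical), ranked
by p-value, with constant covariates reported as undefined. The
model-variant registry resolves which brand model serves a request given
the covariates supplied; age and weight are always available (they are
mandatory on every request) and registries must include an age/weight-only
fallback.

## Evaluation

CWRES uses the first-order-conditional construction: linearizing f in η
about η̂, E[y] ≈ f(η̂) − Gη̂ and Cov[y] ≈ GΩG' + diag(g²) with G = ∂f/∂η
(numerical), CWRES = Cov^{−1/2}(y − E[y]). Shrinkages are the SD-based
variants: η-shrinkage_k = (1 − SD(η̂_k)/ω_k)·100,
ε-shrinkage = (1 − SD(IWRES))·100. Bootstrap resamples subjects with
replacement (same n, seeded, bit-reproducible), refits, and reports
2.5/50/97.5 percentiles of converged resamples; success below 50% flags
instability. Cross-validation partitions subjects (holdout 20% or k-fold,
k = 5 default; both left open deliberately and configurable), predicts
held-out subjects at the population level (η = 0 — held-out subjects
contribute no data to inform η), and reports ME = mean(pred − obs) and MSE
on the concentration scale (a log-scale switch is provided; the scale
choice was genuinely open and concentration scale is the default because
the clinical quantities are absolute levels). Sparse-subset validation
re-estimates each subject by MAP from a 3–4 point subset of their full
profile and compares derived quantities (terminal half-life, times to
50/20/10 IU/L) as relative differences.

## Bayesian forecasting

A validated fit is frozen as a `PriorSet` (typical values, covariate
effects, Ω, σ; Ω must be positive definite). MAP estimation is the same
conditional-mode machinery under those priors, honoring PREDOSE/BASELINE/
BLQ exactly as in estimation; with zero observations the forecast is the
covariate-adjusted typical curve. Posterior uncertainty is propagated by
importance sampling: a Gaussian proposal at the MAP with covariance
1.5 × the Laplace posterior covariance, importance re-weighting by the
exact joint, then systematic resampling to equal weights; with no data this
reduces exactly to prior sampling, and a degenerate curvature falls back to
the prior with a warning. Pointwise 2.5/50/97.5 percentiles of the
propagated curves form the band. The default band describes the underlying
factor level (no residual error): the reported thresholds concern the
patient's true level, not a hypothetical re-assay — `predictive=True`
adds assay noise for an inclusive band.

The reporting grid spans 0 to max(96 h, 5 terminal half-lives) at 0.1 h,
auto-extended (cap 400 h) to cover the MAP curve's descent below the lowest
clinical threshold with a 2× margin so the band's crossings lie on the
grid. Threshold times are the first grid-bracketed crossing of the *lower*
bound after the end of infusion, refined by linear inversion (well under
the 0.1 h reporting precision); "never falls below" (baseline at or above
threshold) and "beyond horizon" are explicit statuses rather than
extrapolations. The dose–interval–trough solver works at steady state by
geometric summation of the infusion response (trough = level at the end of
the dosing interval); dose↔trough is linear above baseline, the interval is
found by Brent bracketing, a target at or below baseline is reported as
"achieved without dosing", and a target unreachable at the given dose as
infeasible.

## Synthetic cohorts

The simulator emulates the data this engine is built for: weight-based
dosing (default 50 IU/kg over 10 minutes), the classical 11-sample design
(4 samples in the first hour, 7 through 48 h), hemophilia-like covariates
(age uniform on 12–65 y; weight from a two-segment rule — linear growth to
18 y, then a 75 ± 14 kg adult distribution, clipped to 42–130 kg — a crude
but documented stand-in for pediatric-to-adult cohorts), log-normal BSV,
combined residual error (σ_prop = 0.10, σ_add = 2 IU/L), a known baseline
of 5 IU/L (severe hemophilia), and censoring at LOQ = 10 IU/L. The default
truth — 1 compartment, V = 3 L, CL chosen for a 12 h terminal half-life,
ω² = 0.09 on CL and V — is an implementation default that is
factor-VIII-*like*; it does not reproduce any commercial product's values.
All randomness flows from a mandatory seed through one `default_rng`
stream, making datasets bit-reproducible. `sparsify` reduces rich profiles
to the 3–4 sample clinical scenario; `inject_errors` plants rising,
duplicate, outlier and missing-value defects with a ledger for
recovery testing.

What simulated data do not exercise: real assay-family differences
(one-stage vs chromogenic), inter-occasion variability, time-varying
covariates, model misspecification of the compartment count, and informative
dropout. Passing tests therefore demonstrate correctness of the machinery
and calibration under the stated generating model, not clinical validity
for any product.

## Study-condition choices in the acceptance experiments

- Parameter recovery uses 40 subjects × 11 samples with proportional error
  σ = 0.1 and ω² = 0.09 (typical of rich brand datasets); the fitted typical
  values land within a few percent of truth.
- The M3-vs-exclusion comparison uses a sparse elimination-phase design
  (8, 60, 120 h; 80 subjects per replicate; ~25% of samples below LOQ), the
  regime where censoring is informative: dropping BLQ rows biases clearance
  downward by several percent while the censored likelihood stays near the
  exact-ML value. Under rich designs with a known baseline both handlings
  are nearly unbiased and the comparison is uninformative — that null result
  is itself documented in the test suite's development history.
- Type-I error calibration of the 3.84 criterion uses 200 null replicates of
  16-subject cohorts; the rejection rate sits inside the binomial 95% band
  around 5%.
- Problem sizes in the acceptance script (replicate counts, cohort sizes,
  draw counts) are chosen so the full run completes in a few minutes on one
  CPU while keeping Monte-Carlo error well below each decision margin.

## Known limitations

- Estimation is Laplace-class only (no SAEM or importance-sampling EM); the
  approximation is validated against numerical integration rather than any
  external tool's output.
- Covariate centering constants and variance structures are frozen at fit
  time; re-centering requires refitting.
- Multi-occasion records are supported by superposition but the simulator
  and most tests exercise single-occasion data.
- The forecast importance sampler assumes a unimodal posterior (true for
  the implemented structural models with log-normal BSV); multimodal
  posteriors would need the MCMC alternative, which is not included.
- Nesting for likelihood-ratio tests is enforced structurally (same dataset
  fingerprint, parameter-set inclusion), not semantically.
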