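# hemopk

Population pharmacokinetics and Bayesian individual forecasting for
clotting-factor concentrates (hemophilia A/B replacement therapy).

Hemophilia prophylaxis aims to keep plasma factor VIII/IX activity above a
protective threshold (conventionally 0.01–0.05 IU/mL, where 1 IU/mL = 100%
of normal). Classical individual PK assessment needs an 11-sample profile
per patient, which is impractical in the clinic — especially for children.
The population-PK (PopPK) alternative fits a hierarchical nonlinear
mixed-effects model to dense multi-subject data once, then uses the
population estimates as informative priors so that an individual patient's
kinetics can be forecast from as few as 3–4 factor levels.

`hemopk` is a self-contained engine for that workflow, aimed at
pharmacometricians and methods researchers:

- **dataset** — read/write/assemble/validate concentration–time datasets in
  the NONMEM-style CSV dialect used for factor concentrates (CID, OCC,
  TIMEH, AMT, RATE, DV, EVID, DOSE, PREDOSE, MDV5, BASELINE, BLQ, MDV3 plus
  optional covariates), with systematic error flagging and documented
  correction/exclusion.
- **structural** — closed-form 1/2/3-compartment linear disposition for
  constant-rate IV infusion (CL/V, CL/V1/Q/V2, CL/V1/Q2/V2/Q3/V3
  parameterizations), dose superposition, endogenous baseline, residual
  pre-dose factor, terminal half-life and time-to-level inversion.
- **population** — typical values with covariate effects (linear, power,
  exponential, categorical), log-normal between-subject variability
  `θ_ij = TV(θ_i)·exp(η_ij)`, `η ~ N(0, Ω)`, and additive / proportional /
  exponential / combined residual error.
- **estimation** — maximum likelihood via a Laplace-with-interaction
  approximation of the marginal likelihood, with the M3 censored-normal
  likelihood `Φ((LOQ − f)/g)` for below-LOQ (BLQ) records; naïve-pooled
  initialization; likelihood-ratio model comparison at the 3.84 OFV
  criterion (df = 1); Ω-structure testing; stepwise covariate selection; a
  model-variant registry keyed on available covariates.
- **evaluation** — CWRES/IWRES diagnostics, η- and ε-shrinkage, condition
  number and VIFs, subject-level bootstrap, holdout/k-fold cross-validation
  (mean error, mean squared error), sparse-subset validation.
- **forecast** — MAP individual estimation under frozen population priors,
  95% credibility bands by importance sampling from a Laplace proposal,
  times at which the *lower* band bound reaches 0.05/0.02/0.01 IU/mL,
  concentrations at 24/48/72 h, and a steady-state dose ↔ interval ↔ trough
  solver.
- **simulate** — a fully seeded synthetic-cohort generator (the test bed for
  everything above) with hemophilia-like covariates, the classical 11-sample
  design, LOQ censoring at 0.01 IU/mL, and planted-error injection.

## Worked example

Simulate a 20-subject rich cohort from a factor-VIII-like truth (1
compartment, CL = 0.1733 L/h, V = 3 L, terminal half-life 12 h, ω² = 0.09 on
CL and V, combined error), fit it, freeze the fit as priors and forecast one
subject from a 3-sample sparse profile:

```python
from hemopk.simulate import default_fviii_spec, simulate_cohort, sparsify
from hemopk.estimation import fit_population, naive_pooled_fit
from hemopk.forecast import PriorSet, posterior_band, report_thresholds
from hemopk.structural import ONE_COMPARTMENT

spec = default_fviii_spec(n_subjects=20, seed=42)
ds, truth = simulate_cohort(spec)

pooled = naive_pooled_fit(ds, ONE_COMPARTMENT, spec.truth.error)
fit = fit_population(ds, spec.truth.with_updates(theta=pooled["params"]))
print(fit.pop.theta, fit.se, fit.ofv)

priors = PriorSet(fit.pop, provenance="readme example")
sparse = sparsify(ds, [3.0, 24.0, 48.0])
fc = posterior_band(sparse.subjects[0], priors, n_draws=1000, seed=1)
print(report_thresholds(fc))
```

Output (seed 42):

```
fit    CL=0.1600 (SE 0.0089)  V=2.873 (SE 0.132)        # truth: 0.1733, 3.0
omega2 CL=0.060 V=0.041  sigma_prop=0.101 sigma_add=2.07  OFV=2621.47

subject 1, sparse observations (3, 24, 48 h): 1084.5, 580.2, 225.1 IU/L
  t(0.05 IU/mL) = 83.2 h    t(0.02 IU/mL) = 109.9 h    t(0.01 IU/mL) = 136.4 h
  C(24 h) = 529.3 [479.3, 582.7] IU/L
  C(48 h) = 228.4 [193.6, 275.9] IU/L
  C(72 h) = 100.4 [ 76.1, 137.8] IU/L
```

The typical values are recovered within ~8% on 20 subjects; the reported
threshold times are where the lower 95% credibility bound first reaches each
clinical level (a deliberately conservative convention), and the bracketed
intervals are the band at fixed times. For this subject — a slow eliminator
(true individual CL 0.105 vs typical 0.16 L/h) — three samples are enough to
pull the MAP clearance to 0.106 L/h.

The same pipeline runs from the shell:

```bash
hemopk run --out-dir runs/demo --n 20 --seed 42
hemopk forecast subject.csv --priors runs/demo/priors.yaml --seed 1 --out report.json
```

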