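"""Nonlinear mixed-effects estimation with censored (BLQ) likelihood.

The marginal likelihood of each subject's data is approximated by the
Laplace method with interaction: the subject-level joint -2 log-likelihood

    q_i(eta) = sum_obs [ log 2*pi*g^2 + ((y - f)/g)^2 ]
             - 2 * sum_BLQ log Phi((LOQ - f)/g)
             + eta' Omega^-1 eta + log |2*pi*Omega|

is minimized over eta (the conditional mode), and the population objective
function value (OFV, -2 log approximate marginal likelihood) is

    OFV = sum_i [ q_i(eta_hat_i) + log det H_i - d*log(4*pi) ]

with H_i the Hessian of q_i at the mode.  Censored observations enter
through the normal CDF (the M3 approach); the error magnitude g is evaluated
at the eta-dependent prediction, which carries the "interaction" of
FOCEI-class estimators.

The inner eta problem is solved for all subjects simultaneously with a
damped Newton iteration on vectorized arrays, which keeps replicate-heavy
simulation studies affordable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .dataset import PKDataset, SubjectData
from .population import (
    CovariateEffect,
    ErrorModel,
    OmegaMatrix,
    PopulationModel,
    typical_value_matrix,
)
from .structural import ONE_COMPARTMENT, StructuralModel, exp_coefficients

__all__ = [
    "FitResult",
    "ModelComparison",
    "ModelVariant",
    "individual_joint_neg2ll",
    "conditional_eta_mode",
    "fit_population",
    "naive_pooled_fit",
    "compare_models",
    "lrt_threshold",
    "test_omega_structure",
    "stepwise_covariates",
    "screen_eta_covariates",
    "select_model_variant",
    "build_variant_registry",
]

_LOG_2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# data packing
# ---------------------------------------------------------------------------

class PackedData:
    """Per-subject event data flattened into padded numpy arrays."""

    def __init__(self, subjects: Sequence[SubjectData]):
        self.subjects = list(subjects)
        n = len(subjects)
        m = max((len(s.observations()) for s in subjects), default=0)
        m = max(m, 1)
        k = max((len(s.regimen().infusions) for s in subjects), default=1)
        k = max(k, 1)
        self.n, self.m = n, m
        self.times = np.ones((n, m))
        self.y = np.zeros((n, m))
        self.obs_mask = np.zeros((n, m), dtype=bool)
        self.blq_mask = np.zeros((n, m), dtype=bool)
        self.loq = np.full((n, m), np.nan)
        self.dose_start = np.zeros((n, k))
        self.dose_dur = np.ones((n, k))
        self.dose_rate = np.zeros((n, k))
        self.baseline = np.zeros(n)
        self.residual = np.zeros(n)
        cov_names = sorted({name for s in subjects for name in s.covariates()})
        self.covariates = {
            name: np.array([s.covariates().get(name, np.nan) for s in subjects], dtype=float)
            for name in cov_names
        }
        for i, s in enumerate(subjects):
            obs = s.observations()
            for j, r in enumerate(obs):
                self.times[i, j] = r.timeh
                if r.is_blq:
                    self.blq_mask[i, j] = True
                    self.loq[i, j] = r.blq
                else:
                    self.obs_mask[i, j] = True
                    self.y[i, j] = r.dv
            for j, inf in enumerate(s.regimen().infusions):
                self.dose_start[i, j] = inf.start_h
                self.dose_dur[i, j] = inf.duration_h
                self.dose_rate[i, j] = inf.rate
            self.baseline[i] = s.baseline_iul
            self.residual[i] = s.residual_iul

    @classmethod
    def from_dataset(cls, ds: PKDataset) -> "PackedData":
        return cls(ds.subjects)


def _batched_concentration(model: StructuralModel, params: np.ndarray, packed: PackedData) -> np.ndarray:
    """Central concentration at the packed observation times.

    ``params`` has shape ``(..., n, p)``; extra leading axes (used to stack
    finite-difference evaluations) broadcast through.  Returns ``(..., n, m)``.
    """
    lam, w = exp_coefficients(model, params)        # (..., n, d)
    t = packed.times                                 # (n, m)
    v_c = params[..., :, 1]                          # V or V1 is always second
    resid_amt = packed.residual * v_c                # (..., n)
    f = packed.baseline[:, None] + resid_amt[..., :, None] * np.sum(
        w[..., :, None, :] * np.exp(lam[..., :, None, :] * t[:, :, None]), axis=-1
    )
    tau = t[:, :, None, None] - packed.dose_start[:, None, :, None]     # (n,m,k,1)
    lam_ = lam[..., :, None, None, :]                # (...,n,1,1,d)
    dur = packed.dose_dur[:, None, :, None]
    tpos = np.maximum(tau, 0.0)
    during = np.expm1(lam_ * tpos) / lam_
    after = (np.exp(lam_ * tpos) - np.exp(lam_ * np.maximum(tau - dur, 0.0))) / lam_
    resp = np.where(tau <= dur, during, after)
    resp = np.where(tau <= 0, 0.0, resp)
    f = f + np.sum(
        packed.dose_rate[:, None, :, None] * w[..., :, None, None, :] * resp,
        axis=(-2, -1),
    )
    return f


class JointContext:
    """Precomputed quantities for repeated joint -2LL evaluations."""

    def __init__(self, packed: PackedData, pop: PopulationModel):
        self.packed = packed
        self.pop = pop
        self.param_names = pop.structural.param_names
        self.eta_idx = np.array(
            [self.param_names.index(p) for p in pop.eta_params], dtype=int
        )
        self.tv = typical_value_matrix(pop, packed.covariates)  # (n, p)
        om = pop.omega.matrix
        self.d = om.shape[0]
        sign, logdet = np.linalg.slogdet(2.0 * np.pi * om)
        if sign <= 0:
            raise np.linalg.LinAlgError("omega matrix is singular")
        self.omega_inv = np.linalg.inv(om)
        self.omega_logdet2pi = logdet
        self.em = pop.error

    def individual_params(self, eta: np.ndarray) -> np.ndarray:
        """(..., n, d) eta -> (..., n, p) parameter array."""
        params = np.broadcast_to(self.tv, eta.shape[:-1] + self.tv.shape[-1:]).copy()
        with np.errstate(over="ignore"):
            params[..., self.eta_idx] = params[..., self.eta_idx] * np.exp(
                np.clip(eta, -60.0, 60.0)
            )
        return params

    def predictions(self, eta: np.ndarray) -> np.ndarray:
        return _batched_concentration(self.pop.structural, self.individual_params(eta), self.packed)

    def joint(self, eta: np.ndarray) -> np.ndarray:
        """q_i(eta_i) for all subjects; eta (..., n, d) -> (..., n)."""
        p = self.packed
        f = self.predictions(eta)
        em = self.em
        out = np.zeros(eta.shape[:-1])
        if em.form == "exponential":
            g = em.sigma_prop
            with np.errstate(divide="ignore", invalid="ignore"):
                logf = np.log(np.maximum(f, 1e-300))
            z = (np.log(np.maximum(p.y, 1e-300)) - logf) / g
            term_obs = _LOG_2PI + 2.0 * math.log(g) + z * z
            zc = (np.log(p.loq) - logf) / g
        else:
            g = f * em.sigma_prop if em.form == "proportional" else (
                np.full_like(f, em.sigma_add) if em.form == "additive"
                else np.sqrt(f * f * em.sigma_prop**2 + em.sigma_add**2)
            )
            if np.any((g <= 0) & (p.obs_mask | p.blq_mask)):
                raise ValueError("residual sd is zero at a contributing observation")
            gsafe = np.where(p.obs_mask | p.blq_mask, g, 1.0)
            z = (p.y - f) / gsafe
            term_obs = _LOG_2PI + 2.0 * np.log(gsafe) + z * z
            zc = (p.loq - f) / gsafe
        out = out + np.sum(np.where(p.obs_mask, term_obs, 0.0), axis=-1)
        if p.blq_mask.any():
            logcdf = special.log_ndtr(np.where(p.blq_mask, zc, 0.0))
            out = out + -2.0 * np.sum(np.where(p.blq_mask, logcdf, 0.0), axis=-1)
        quad = np.einsum("...nd,de,...ne->...n", eta, self.omega_inv, eta)
        return out + quad + self.omega_logdet2pi


def _batched_eta_mode(
    ctx: JointContext,
    gtol: float = 1e-6,
    max_iter: int = 80,
    eta0: np.ndarray | None = None,
):
    """Damped Newton minimization of q_i over eta, all subjects at once.

    All finite-difference points of one iteration are evaluated in a single
    stacked call to the joint likelihood.  Returns
    (eta_hat, q_at_mode, hessians (n,d,d), converged mask).
    """
    n, d = ctx.packed.n, ctx.d
    eta = np.zeros((n, d)) if eta0 is None else np.array(eta0, dtype=float)
    h = 1e-4
    eye = np.eye(d)
    pairs = [(j, k) for j in range(d) for k in range(j + 1, d)]
    # FD stencil offsets: center, +/- each axis, +/- each axis pair
    offsets = [np.zeros(d)]
    for j in range(d):
        offsets += [h * eye[j], -h * eye[j]]
    for j, k in pairs:
        offsets += [h * (eye[j] + eye[k]), -h * (eye[j] + eye[k])]
    offsets = np.asarray(offsets)  # (r, d)

    def grad_hess(e):
        Q = ctx.joint(e[None, :, :] + offsets[:, None, :])  # (r, n)
        q0 = Q[0]
        g = np.empty((n, d))
        H = np.empty((n, d, d))
        for j in range(d):
            qp, qm = Q[1 + 2 * j], Q[2 + 2 * j]
            g[:, j] = (qp - qm) / (2 * h)
            H[:, j, j] = (qp - 2 * q0 + qm) / h**2
        base = 1 + 2 * d
        for idx, (j, k) in enumerate(pairs):
            qpp, qmm = Q[base + 2 * idx], Q[base + 2 * idx + 1]
            off = (qpp + qmm - Q[1 + 2 * j] - Q[2 + 2 * j]
                   - Q[1 + 2 * k] - Q[2 + 2 * k] + 2 * q0) / (2 * h**2)
            H[:, j, k] = H[:, k, j] = off
        return q0, g, H

    q0, g, H = grad_hess(eta)
    active = np.ones(n, dtype=bool)
    for _ in range(max_iter):
        # regularize non-PD Hessians per subject
        Hreg = H.copy()
        for i in np.nonzero(active)[0]:
            ev = np.linalg.eigvalsh(H[i])
            if ev[0] < 1e-8:
                Hreg[i] += (1e-8 - ev[0] + 0.1 * np.abs(ev).max()) * eye
        step = np.zeros_like(eta)
        step[active] = -np.linalg.solve(Hreg[active], g[active][..., None])[..., 0]
        slope = np.sum(g * step, axis=1)
        gnorm = np.max(np.abs(g), axis=1)
        # converged: small gradient, or Newton decrement at floating-point noise
        active = (gnorm > gtol) & (-slope > 1e-11 * (np.abs(q0) + 1.0))
        if not active.any():
            break
        step[~active] = 0.0
        # backtracking line search, per subject, tolerant of FP noise in q
        scale = np.where(active, 1.0, 0.0)
        noise = 1e-10 * (np.abs(q0) + 1.0)
        for _ in range(12):
            trial = eta + scale[:, None] * step
            q1 = ctx.joint(trial)
            bad = active & ~(q1 <= q0 + 1e-4 * scale * slope + noise)
            if not bad.any():
                break
            scale[bad] *= 0.5
        eta = eta + scale[:, None] * step
        q0, g, H = grad_hess(eta)
    gnorm = np.max(np.abs(g), axis=1)
    dec = np.abs(np.einsum("nd,nd->n", g, np.linalg.solve(
        H + 1e-8 * eye, g[..., None])[..., 0]))
    converged = (gnorm <= max(gtol, 1e-3)) | (dec <= 1e-9 * (np.abs(q0) + 1.0))
    return eta, q0, H, converged


def _laplace_ofv_terms(q_mode: np.ndarray, H: np.ndarray, d: int) -> np.ndarray:
    sign, logdet = np.linalg.slogdet(H)
    logdet = np.where(sign > 0, logdet, np.inf)
    return q_mode + logdet - d * math.log(4.0 * math.pi)


# ---------------------------------------------------------------------------
# public single-subject operations
# ---------------------------------------------------------------------------

def individual_joint_neg2ll(subject: SubjectData, pop: PopulationModel, eta) -> float:
    """Joint -2 log-likelihood of one subject's data and eta under the model."""
    ctx = JointContext(PackedData([subject]), pop)
    return float(ctx.joint(np.atleast_2d(np.asarray(eta, dtype=float)))[0])


def conditional_eta_mode(subject: SubjectData, pop: PopulationModel, gtol: float = 1e-6):
    """Posterior mode of eta for one subject (empirical-Bayes estimate)."""
    ctx = JointContext(PackedData([subject]), pop)
    eta, q, H, conv = _batched_eta_mode(ctx, gtol=gtol)
    if not conv[0]:
        raise RuntimeError(f"eta mode search did not converge for subject {subject.cid}")
    return eta[0], q[0], H[0]


# ---------------------------------------------------------------------------
# population fit
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    pop: PopulationModel
    ofv: float
    converged: bool
    message: str
    n_subjects: int
    eta: np.ndarray                      # (n, d) conditional modes
    predictions: pd.DataFrame            # per-observation table
    se: dict[str, float] = field(default_factory=dict)
    covariance: np.ndarray | None = None
    se_names: tuple[str, ...] = ()
    condition_number: float = np.nan
    grad_norm: float = np.nan
    n_obs: int = 0
    dataset_fingerprint: str = ""

    @property
    def theta(self) -> dict[str, float]:
        return self.pop.theta


def _dataset_fingerprint(subjects: Sequence[SubjectData]) -> str:
    import hashlib

    hsh = hashlib.sha256()
    for s in subjects:
        for r in s.records:
            hsh.update(repr((r.cid, r.timeh, r.amt, r.dv, r.evid)).encode())
    return hsh.hexdigest()[:16]


class _ParamTransform:
    """Maps a PopulationModel's free parameters to an unconstrained vector.

    Typical values and sigmas are log-transformed, Omega is parameterized by
    its log-Cholesky factor (diagonal structure: log standard deviations
    only), covariate coefficients are untransformed.
    """

    def __init__(self, pop: PopulationModel, fit_covariates: bool = True,
                 fit_omega: bool = True):
        self.template = pop
        self.fit_covariates = fit_covariates
        self.fit_omega = fit_omega
        self.names: list[str] = [f"TV_{p}" for p in pop.structural.param_names]
        if fit_covariates:
            self.names += [
                f"theta_{e.covariate}_{e.parameter}" for e in pop.covariate_effects
            ]
        d = pop.omega.dim
        self.d = d
        if not fit_omega:
            self.omega_slots = []
        elif pop.omega.structure == "diagonal":
            self.omega_slots = [(i, i) for i in range(d)]
        else:
            self.omega_slots = [(i, j) for i in range(d) for j in range(i + 1)]
        self.names += [f"omega_L_{i}{j}" for i, j in self.omega_slots]
        self.names += [f"log_{s}" for s in pop.error.sigma_names]
        self.n_free = len(self.names)

    def pack(self, pop: PopulationModel) -> np.ndarray:
        x = [math.log(pop.theta[p]) for p in pop.structural.param_names]
        if self.fit_covariates:
            x += [e.theta for e in pop.covariate_effects]
        L = np.linalg.cholesky(pop.omega.matrix + 1e-12 * np.eye(self.d))
        for i, j in self.omega_slots:
            x.append(math.log(L[i, i]) if i == j else L[i, j])
        for s in pop.error.sigma_names:
            x.append(math.log(max(getattr(pop.error, s), 1e-8)))
        return np.asarray(x)

    def unpack(self, x: np.ndarray) -> PopulationModel:
        pop = self.template
        k = 0
        theta = {}
        for p in pop.structural.param_names:
            theta[p] = math.exp(x[k])
            k += 1
        effects = list(pop.covariate_effects)
        if self.fit_covariates:
            effects = []
            for e in pop.covariate_effects:
                effects.append(CovariateEffect(
                    e.parameter, e.covariate, e.form, float(x[k]), e.center, e.level
                ))
                k += 1
        if self.omega_slots:
            L = np.zeros((self.d, self.d))
            for i, j in self.omega_slots:
                # clip so an extreme line-search trial can't overflow L @ L.T
                L[i, j] = math.exp(min(x[k], 150.0)) if i == j else x[k]
                k += 1
            omega = OmegaMatrix(L @ L.T, pop.omega.structure)
        else:
            omega = pop.omega
        sig = {"sigma_add": pop.error.sigma_add, "sigma_prop": pop.error.sigma_prop}
        for s in pop.error.sigma_names:
            sig[s] = math.exp(x[k])
            k += 1
        error = ErrorModel(pop.error.form, sig["sigma_add"], sig["sigma_prop"])
        return PopulationModel(
            structural=pop.structural, theta=theta, omega=omega, error=error,
            covariate_effects=effects, eta_params=pop.eta_params,
        )


def _ofv_for(packed: PackedData, pop: PopulationModel, inner_gtol: float = 1e-6,
             eta0: np.ndarray | None = None):
    ctx = JointContext(packed, pop)
    eta, q, H, conv = _batched_eta_mode(ctx, gtol=inner_gtol, eta0=eta0)
    terms = _laplace_ofv_terms(q, H, ctx.d)
    return float(np.sum(terms)), eta, H, bool(conv.all()), ctx


def fit_population(
    ds: PKDataset,
    pop_init: PopulationModel,
    fit_covariates: bool = True,
    fit_omega: bool = True,
    maxiter: int = 300,
    gtol: float = 1e-5,
    inner_gtol: float = 1e-6,
    compute_se: bool = True,
) -> FitResult:
    """Maximum-likelihood population fit via the Laplace-with-interaction
    approximation; BLQ records contribute censored-normal terms (M3).

    ``pop_init`` supplies the model structure and starting values; use
    :func:`naive_pooled_fit` to obtain sensible typical-value inits.
    """
    if len(ds.subjects) < 2:
        raise ValueError("population fit requires at least 2 subjects")
    packed = PackedData.from_dataset(ds)
    tf = _ParamTransform(pop_init, fit_covariates, fit_omega)
    x0 = tf.pack(pop_init)

    # warm-start the inner Newton from the previous evaluation's modes; the
    # mode is located to gtol regardless of the start, so the objective stays
    # a well-defined function of x while the iteration count drops sharply
    state = {"eta": None}

    def objective(x):
        try:
            pop = tf.unpack(x)
            ofv, eta, *_ = _ofv_for(packed, pop, inner_gtol, eta0=state["eta"])
        except (ValueError, np.linalg.LinAlgError, OverflowError):
            return 1e10
        if not np.isfinite(ofv):
            return 1e10
        state["eta"] = eta
        return ofv

    res = optimize.minimize(
        objective, x0, method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-10, "gtol": gtol, "eps": 1e-5},
    )
    pop = tf.unpack(res.x)
    ofv, eta, H, inner_ok, ctx = _ofv_for(packed, pop, inner_gtol)
    converged = bool(res.success) and inner_ok

    # per-observation predictions
    f_pop = ctx.predictions(np.zeros_like(eta))
    f_ind = ctx.predictions(eta)
    rows = []
    for i, s in enumerate(packed.subjects):
        for j, r in enumerate(s.observations()):
            rows.append({
                "cid": s.cid, "timeh": r.timeh,
                "dv": r.dv if not r.is_blq else np.nan, "blq": r.is_blq,
                "pred_pop": f_pop[i, j], "pred_ind": f_ind[i, j],
            })
    predictions = pd.DataFrame(rows)

    se: dict[str, float] = {}
    cov = None
    cond = np.nan
    if compute_se:
        se, cov, cond = _wald_se(objective, res.x, tf)

    return FitResult(
        pop=pop, ofv=ofv, converged=converged,
        message=str(res.message), n_subjects=packed.n,
        eta=eta, predictions=predictions, se=se, covariance=cov,
        se_names=tuple(tf.names), condition_number=cond,
        grad_norm=float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan,
        n_obs=int(packed.obs_mask.sum() + packed.blq_mask.sum()),
        dataset_fingerprint=_dataset_fingerprint(ds.subjects),
    )


def _wald_se(objective, x_opt, tf: _ParamTransform):
    """Wald standard errors: numerical Hessian of OFV/2, delta method back to
    the natural scale for log-transformed components."""
    p = len(x_opt)
    h = 1e-3
    Hm = np.zeros((p, p))
    f0 = objective(x_opt)
    fp = np.zeros(p)
    fm = np.zeros(p)
    e = np.eye(p)
    for i in range(p):
        fp[i] = objective(x_opt + h * e[i])
        fm[i] = objective(x_opt - h * e[i])
        Hm[i, i] = (fp[i] - 2 * f0 + fm[i]) / h**2
    for i in range(p):
        for j in range(i + 1, p):
            fpp = objective(x_opt + h * (e[i] + e[j]))
            fmm = objective(x_opt - h * (e[i] + e[j]))
            Hm[i, j] = Hm[j, i] = (fpp + fmm - fp[i] - fm[i] - fp[j] - fm[j] + 2 * f0) / (2 * h**2)
    Hm *= 0.5  # OFV/2 = negative log-likelihood
    se: dict[str, float] = {}
    try:
        ev = np.linalg.eigvalsh(Hm)
        cond = float(ev.max() / ev.min()) if ev.min() > 0 else np.inf
        cov = np.linalg.inv(Hm)
        sd = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        return {}, None, np.inf
    for name, xi, s in zip(tf.names, x_opt, sd):
        if name.startswith("TV_") or name.startswith("log_sigma"):
            se[name] = math.exp(xi) * s  # delta method for log-scale params
        else:
            se[name] = s
    return se, cov, cond


def naive_pooled_fit(
    ds: PKDataset,
    structural: StructuralModel = ONE_COMPARTMENT,
    error: ErrorModel | None = None,
    init: Mapping[str, float] | None = None,
) -> dict:
    """Single-theta fit ignoring between-subject variability.

    Used to explore compartment count and to initialize the population fit.
    Returns a dict with the parameter estimates, sigmas and the pooled OFV.
    """
    error = error or ErrorModel("proportional", sigma_prop=0.2)
    packed = PackedData.from_dataset(ds)
    names = structural.param_names
    if init is None:
        # crude but scale-aware: V from dose over peak, CL from V and a
        # factor-like half-life guess of 12 h
        peak = max(float(np.max(packed.y[packed.obs_mask], initial=1.0)), 1.0)
        dose = float(np.mean(packed.dose_rate * packed.dose_dur))
        v = max(dose / peak, 0.1)
        init = {"CL": v * math.log(2) / 12.0, "V": v, "V1": v, "Q": v * 0.05,
                "V2": v, "Q2": v * 0.05, "V3": v * 2, "Q3": v * 0.01}
    x0 = [math.log(init[p]) for p in names]
    for s in error.sigma_names:
        x0.append(math.log(max(getattr(error, s), 1e-3)))
    x0 = np.asarray(x0)
    n_mask = packed.obs_mask | packed.blq_mask

    def neg2ll(x):
        try:
            params = np.exp(x[: len(names)])
            sig = dict(sigma_add=error.sigma_add, sigma_prop=error.sigma_prop)
            for i, s in enumerate(error.sigma_names):
                sig[s] = math.exp(x[len(names) + i])
            em = ErrorModel(error.form, sig["sigma_add"], sig["sigma_prop"])
            pmat = np.tile(params, (packed.n, 1))
            f = _batched_concentration(structural, pmat, packed)
        except (ValueError, FloatingPointError, np.linalg.LinAlgError):
            return 1e10
        if em.form == "exponential":
            g = np.full_like(f, em.sigma_prop)
            z = (np.log(np.maximum(packed.y, 1e-300)) - np.log(np.maximum(f, 1e-300))) / g
            zc = (np.log(packed.loq) - np.log(np.maximum(f, 1e-300))) / g
        else:
            g = f * em.sigma_prop if em.form == "proportional" else (
                np.full_like(f, em.sigma_add) if em.form == "additive"
                else np.sqrt(f * f * em.sigma_prop**2 + em.sigma_add**2)
            )
            if np.any(g[n_mask] <= 0):
                return 1e10
            z = (packed.y - f) / g
            zc = (packed.loq - f) / g
        term = _LOG_2PI + 2 * np.log(np.where(packed.obs_mask, g, 1.0)) + z * z
        val = np.sum(np.where(packed.obs_mask, term, 0.0))
        if packed.blq_mask.any():
            val += -2.0 * np.sum(np.where(
                packed.blq_mask, special.log_ndtr(np.where(packed.blq_mask, zc, 0.0)), 0.0
            ))
        return val if np.isfinite(val) else 1e10

    res = optimize.minimize(neg2ll, x0, method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
    params = {p: float(math.exp(v)) for p, v in zip(names, res.x)}
    sigmas = {s: float(math.exp(res.x[len(names) + i])) for i, s in enumerate(error.sigma_names)}
    return {"params": params, "sigmas": sigmas, "ofv": float(res.fun),
            "converged": bool(res.success), "error_form": error.form}


# ---------------------------------------------------------------------------
# model comparison & covariate selection
# ---------------------------------------------------------------------------

def lrt_threshold(df: int = 1) -> float:
    """OFV-drop required for superiority of a model with ``df`` more
    parameters: the 95% chi-squared quantile at the printed 2-decimal
    precision (3.84 for one degree of freedom)."""
    return round(float(stats.chi2.ppf(0.95, df)), 2)


@dataclass
class ModelComparison:
    ofv_reduced: float
    ofv_full: float
    added_df: int
    threshold: float
    delta_ofv: float
    superior: bool


def compare_models(reduced: FitResult, full: FitResult, added_df: int = 1) -> ModelComparison:
    """Likelihood-ratio comparison of nested fits on the identical dataset."""
    if added_df < 1:
        raise ValueError("added_df must be >= 1")
    if (reduced.dataset_fingerprint and full.dataset_fingerprint
            and reduced.dataset_fingerprint != full.dataset_fingerprint):
        raise ValueError("models were fitted on different datasets; comparison refused")
    thr = lrt_threshold(added_df)
    delta = reduced.ofv - full.ofv
    return ModelComparison(reduced.ofv, full.ofv, added_df, thr, delta, delta >= thr)


def test_omega_structure(ds: PKDataset, pop: PopulationModel, **fit_kwargs) -> ModelComparison:
    """Diagonal vs unstructured Omega: tests correlation between random effects."""
    d = pop.omega.dim
    if d < 2:
        raise ValueError("omega structure test requires >= 2 eta-bearing parameters")
    diag_pop = pop.with_updates(omega=OmegaMatrix(np.diag(np.diag(pop.omega.matrix)), "diagonal"))
    fit_diag = fit_population(ds, diag_pop, compute_se=False, **fit_kwargs)
    full_init = fit_diag.pop.with_updates(
        omega=OmegaMatrix(fit_diag.pop.omega.matrix + 0.0, "unstructured")
    )
    fit_full = fit_population(ds, full_init, compute_se=False, **fit_kwargs)
    return compare_models(fit_diag, fit_full, added_df=d * (d - 1) // 2)


def stepwise_covariates(
    ds: PKDataset,
    base: FitResult,
    candidates: Sequence[CovariateEffect],
    alpha_forward: float = 0.05,
    backward: bool = False,
    alpha_backward: float = 0.01,
    **fit_kwargs,
) -> tuple[FitResult, pd.DataFrame]:
    """Forward stepwise covariate inclusion at the 3.84 OFV criterion.

    Each round fits every remaining candidate on top of the current model;
    the candidate with the largest significant OFV drop whose coefficient's
    95% Wald interval excludes zero is added.  The trace records every model
    tested.  An optional stricter backward pass (default off) re-tests the
    included effects at ``alpha_backward``.
    """
    del alpha_forward  # forward threshold is the fixed 3.84 criterion
    current = base
    remaining = list(candidates)
    trace_rows = []
    rnd = 0
    while remaining:
        rnd += 1
        results = []
        for cand in remaining:
            pop_c = current.pop.with_updates(
                covariate_effects=list(current.pop.covariate_effects) + [cand]
            )
            try:
                fit_c = fit_population(ds, pop_c, **fit_kwargs)
            except (ValueError, np.linalg.LinAlgError):
                trace_rows.append({"round": rnd, "candidate": _cand_label(cand),
                                   "ofv": np.nan, "delta_ofv": np.nan,
                                   "ci_excludes_zero": False, "selected": False})
                continue
            delta = current.ofv - fit_c.ofv
            name = f"theta_{cand.covariate}_{cand.parameter}"
            se = fit_c.se.get(name, np.nan)
            est = fit_c.pop.covariate_effects[-1].theta
            ci_ok = bool(np.isfinite(se) and se > 0 and abs(est) > 1.96 * se)
            results.append((delta, ci_ok, cand, fit_c))
            trace_rows.append({"round": rnd, "candidate": _cand_label(cand),
                               "ofv": fit_c.ofv, "delta_ofv": delta,
                               "ci_excludes_zero": ci_ok, "selected": False})
        eligible = [r for r in results if r[0] >= lrt_threshold(1) and r[1]]
        if not eligible:
            break
        best = max(eligible, key=lambda r: r[0])
        current = best[3]
        remaining.remove(best[2])
        for row in trace_rows:
            if row["round"] == rnd and row["candidate"] == _cand_label(best[2]):
                row["selected"] = True
    if backward:
        current, trace_rows = _backward_pass(
            ds, current, trace_rows, lrt_threshold_value=round(
                float(stats.chi2.ppf(1 - alpha_backward, 1)), 2
            ), **fit_kwargs,
        )
    return current, pd.DataFrame(trace_rows)


def _cand_label(e: CovariateEffect) -> str:
    return f"{e.covariate}->{e.parameter} ({e.form})"


def _backward_pass(ds, current, trace_rows, lrt_threshold_value, **fit_kwargs):
    improved = True
    while improved and current.pop.covariate_effects:
        improved = False
        for e in list(current.pop.covariate_effects):
            reduced_pop = current.pop.with_updates(
                covariate_effects=[x for x in current.pop.covariate_effects if x is not e]
            )
            fit_r = fit_population(ds, reduced_pop, **fit_kwargs)
            delta = fit_r.ofv - current.ofv
            keep = delta >= lrt_threshold_value
            trace_rows.append({"round": -1, "candidate": f"drop {_cand_label(e)}",
                               "ofv": fit_r.ofv, "delta_ofv": delta,
                               "ci_excludes_zero": keep, "selected": not keep})
            if not keep:
                current = fit_r
                improved = True
                break
    return current, trace_rows


_CATEGORICAL_COVARIATES = {"RACE", "BTYPE"}


def screen_eta_covariates(fit: FitResult, ds: PKDataset) -> pd.DataFrame:
    """Rank covariate-eta associations (the plot-based screen, numerically).

    Continuous covariates: Pearson correlation with each eta-hat; categorical
    covariates: one-way ANOVA across groups.  Constant covariates are
    reported with an undefined statistic.
    """
    packed = PackedData.from_dataset(ds)
    rows = []
    for k, pname in enumerate(fit.pop.eta_params):
        e = fit.eta[:, k]
        for cname, vals in packed.covariates.items():
            ok = np.isfinite(vals)
            v, ee = vals[ok], e[ok]
            if ok.sum() < 3 or np.ptp(v) == 0:
                rows.append({"eta": pname, "covariate": cname, "kind": "undefined",
                             "statistic": np.nan, "p_value": np.nan})
                continue
            if cname in _CATEGORICAL_COVARIATES:
                groups = [ee[v == lvl] for lvl in np.unique(v)]
                groups = [g for g in groups if len(g) > 0]
                if len(groups) < 2:
                    rows.append({"eta": pname, "covariate": cname, "kind": "undefined",
                                 "statistic": np.nan, "p_value": np.nan})
                    continue
                stat, p = stats.f_oneway(*groups)
                rows.append({"eta": pname, "covariate": cname, "kind": "anova-F",
                             "statistic": float(stat), "p_value": float(p)})
            else:
                r, p = stats.pearsonr(v, ee)
                rows.append({"eta": pname, "covariate": cname, "kind": "pearson-r",
                             "statistic": float(r), "p_value": float(p)})
    df = pd.DataFrame(rows)
    df["rank"] = df["p_value"].rank(method="min")
    return df.sort_values(["p_value"], na_position="last").reset_index(drop=True)


# ---------------------------------------------------------------------------
# model variant registry (the multi-model decision algorithm)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelVariant:
    name: str
    model: PopulationModel
    required_covariates: tuple[str, ...]
    precision_rank: int  # lower = more precise = preferred


def build_variant_registry(variants: Sequence[ModelVariant]) -> tuple[ModelVariant, ...]:
    """Validate a registry: it must contain an age/weight-only fallback, so a
    request carrying only the mandatory covariates can always be served."""
    if not variants:
        raise ValueError("variant registry is empty")
    fallback = [v for v in variants
                if set(c.upper() for c in v.required_covariates) <= {"AGE", "BW"}]
    if not fallback:
        raise ValueError("registry must include an age/weight-only fallback variant")
    return tuple(sorted(variants, key=lambda v: v.precision_rank))


def select_model_variant(
    available_covariates: Sequence[str], registry: Sequence[ModelVariant]
) -> ModelVariant:
    """Most-preferred variant whose required covariates are all available.

    Age and weight are always treated as available (they are mandatory for
    every estimation request)."""
    avail = {c.upper() for c in available_covariates} | {"AGE", "BW"}
    for v in sorted(registry, key=lambda v: v.precision_rank):
        if {c.upper() for c in v.required_covariates} <= avail:
            return v
    raise ValueError("no model variant satisfiable with the available covariates")
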