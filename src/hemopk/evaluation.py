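"""Model evaluation: diagnostics, bootstrap stability, cross-validation and
sparse-subset validation.

All outputs are plot-ready tidy tables; no figures are rendered here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import PKDataset, SubjectData
from .estimation import (
    FitResult,
    JointContext,
    PackedData,
    conditional_eta_mode,
    fit_population,
)
from .population import PopulationModel, residual_sd
from .structural import terminal_halflife, time_to_level

__all__ = [
    "DiagnosticsBundle",
    "BootstrapResult",
    "CrossValResult",
    "compute_diagnostics",
    "bootstrap",
    "cross_validate",
    "sparse_subset_validation",
]


@dataclass
class DiagnosticsBundle:
    residuals: pd.DataFrame          # cid, timeh, dv, pred_pop, pred_ind, cwres, iwres
    eta: pd.DataFrame                # cid, eta_<param> columns
    eta_shrinkage_pct: dict[str, float]
    eps_shrinkage_pct: float
    condition_number: float
    vif: dict[str, float]
    qq: pd.DataFrame                 # theoretical vs sample quantiles of CWRES


def _eta_gradient(ctx: JointContext, eta: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """dF/deta at eta, per subject: shape (n, m, d)."""
    n, d = eta.shape
    G = np.empty((n, ctx.packed.times.shape[1], d))
    for j in range(d):
        e = np.zeros_like(eta)
        e[:, j] = h
        G[:, :, j] = (ctx.predictions(eta + e) - ctx.predictions(eta - e)) / (2 * h)
    return G


def compute_diagnostics(fit: FitResult, ds: PKDataset) -> DiagnosticsBundle:
    """Conditional weighted residuals, shrinkages and collinearity metrics.

    CWRES uses the first-order-conditional construction: the model is
    linearized in eta about the conditional mode, so for subject i

        E[y] ~ f(eta_hat) - G eta_hat,   Cov[y] ~ G Omega G' + diag(g^2)

    and CWRES = Cov^{-1/2} (y - E[y]).  BLQ rows carry no residual (they are
    censored, not observed) and are excluded.  Shrinkages follow the
    SD-based definitions: eta-shrinkage_k = (1 - SD(eta_hat_k)/omega_k)*100
    and eps-shrinkage = (1 - SD(IWRES))*100.
    """
    if not fit.converged:
        raise ValueError("diagnostics require a converged fit")
    packed = PackedData.from_dataset(ds)
    ctx = JointContext(packed, fit.pop)
    eta = fit.eta
    f_ind = ctx.predictions(eta)
    f_pop = ctx.predictions(np.zeros_like(eta))
    G = _eta_gradient(ctx, eta)
    om = fit.pop.omega.matrix
    rows = []
    cwres_all = []
    iwres_all = []
    for i, s in enumerate(packed.subjects):
        obs = s.observations()
        sel = np.array([not r.is_blq for r in obs], dtype=bool)
        idx = np.arange(len(obs))
        y = np.array([r.dv for r in obs])
        gi = G[i, : len(obs)][sel]
        fi = f_ind[i, : len(obs)]
        gm = residual_sd(fi, fit.pop.error)
        mu = fi[sel] - gi @ eta[i]
        cov = gi @ om @ gi.T + np.diag(gm[sel] ** 2)
        # inverse square root via eigendecomposition
        w, V = np.linalg.eigh(cov)
        cov_isqrt = V @ np.diag(1.0 / np.sqrt(np.maximum(w, 1e-12))) @ V.T
        cwres_i = cov_isqrt @ (y[sel] - mu)
        iwres_i = (y[sel] - fi[sel]) / gm[sel]
        it = iter(range(sel.sum()))
        for j in idx:
            r = obs[j]
            if sel[j]:
                k = next(it)
                rows.append({
                    "cid": s.cid, "timeh": r.timeh, "dv": r.dv,
                    "pred_pop": f_pop[i, j], "pred_ind": f_ind[i, j],
                    "cwres": cwres_i[k], "iwres": iwres_i[k], "blq": False,
                })
            else:
                rows.append({
                    "cid": s.cid, "timeh": r.timeh, "dv": np.nan,
                    "pred_pop": f_pop[i, j], "pred_ind": f_ind[i, j],
                    "cwres": np.nan, "iwres": np.nan, "blq": True,
                })
        cwres_all.append(cwres_i)
        iwres_all.append(iwres_i)
    residuals = pd.DataFrame(rows)
    cwres = np.concatenate(cwres_all) if cwres_all else np.array([])
    iwres = np.concatenate(iwres_all) if iwres_all else np.array([])

    eta_shrink = {}
    for k, p in enumerate(fit.pop.eta_params):
        omega_k = np.sqrt(om[k, k])
        sd_k = float(np.std(eta[:, k], ddof=1)) if eta.shape[0] > 1 else 0.0
        eta_shrink[p] = (1.0 - sd_k / omega_k) * 100.0 if omega_k > 0 else np.nan
    eps_shrink = (1.0 - float(np.std(iwres, ddof=1))) * 100.0 if iwres.size > 1 else np.nan

    vif = _covariate_vif(packed)
    from scipy import stats as st

    srt = np.sort(cwres)
    theo = st.norm.ppf((np.arange(1, srt.size + 1) - 0.5) / srt.size) if srt.size else np.array([])
    qq = pd.DataFrame({"theoretical": theo, "sample": srt})
    eta_df = pd.DataFrame(
        {**{"cid": [s.cid for s in packed.subjects]},
         **{f"eta_{p}": eta[:, k] for k, p in enumerate(fit.pop.eta_params)}}
    )
    return DiagnosticsBundle(
        residuals=residuals, eta=eta_df, eta_shrinkage_pct=eta_shrink,
        eps_shrinkage_pct=eps_shrink, condition_number=fit.condition_number,
        vif=vif, qq=qq,
    )


def _covariate_vif(packed: PackedData) -> dict[str, float]:
    """Variance inflation factors among the continuous covariates."""
    names = [n for n, v in packed.covariates.items()
             if np.isfinite(v).all() and np.ptp(v) > 0 and n not in ("RACE", "BTYPE")]
    out = {}
    if len(names) < 2:
        return {n: 1.0 for n in names}
    X = np.column_stack([packed.covariates[n] for n in names])
    for j, n in enumerate(names):
        yj = X[:, j]
        Xo = np.column_stack([np.ones(len(yj)), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(Xo, yj, rcond=None)
        resid = yj - Xo @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        out[n] = 1.0 / max(1.0 - r2, 1e-12)
    return out


@dataclass
class BootstrapResult:
    n_resamples: int
    n_converged: int
    percentiles: pd.DataFrame        # parameter, p2.5, p50, p97.5
    estimates: pd.DataFrame          # one row per converged resample
    stable: bool
    seed: int


def bootstrap(
    ds: PKDataset,
    pop_init: PopulationModel,
    n_resamples: int,
    seed: int,
    **fit_kwargs,
) -> BootstrapResult:
    """Subject-level nonparametric bootstrap of the population fit.

    Each resample draws ``n`` subjects with replacement, refits, and the
    2.5/50/97.5 percentiles of the converged estimates are reported.  A
    convergence success rate below 50% marks the result unstable.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    rng = np.random.default_rng(seed)
    fit_kwargs.setdefault("compute_se", False)
    rows = []
    n_conv = 0
    n = len(ds.subjects)
    for b in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        subjects = []
        for new_cid, i in enumerate(idx, start=1):
            src = ds.subjects[i]
            from dataclasses import replace as _replace

            subjects.append(SubjectData([_replace(r, cid=new_cid) for r in src.records]))
        bs = PKDataset(subjects, provenance=f"bootstrap#{b}")
        try:
            fit = fit_population(bs, pop_init, **fit_kwargs)
        except (ValueError, np.linalg.LinAlgError):
            continue
        if not fit.converged:
            continue
        n_conv += 1
        row = {f"TV_{p}": v for p, v in fit.pop.theta.items()}
        for k, p in enumerate(fit.pop.eta_params):
            row[f"omega2_{p}"] = fit.pop.omega.matrix[k, k]
        for s in fit.pop.error.sigma_names:
            row[s] = getattr(fit.pop.error, s)
        rows.append(row)
    est = pd.DataFrame(rows)
    if len(est):
        pct = est.quantile([0.025, 0.5, 0.975]).T
        pct.columns = ["p2.5", "p50", "p97.5"]
        pct = pct.reset_index(names="parameter")
    else:
        pct = pd.DataFrame(columns=["parameter", "p2.5", "p50", "p97.5"])
    return BootstrapResult(
        n_resamples=n_resamples, n_converged=n_conv, percentiles=pct,
        estimates=est, stable=n_conv >= 0.5 * n_resamples, seed=seed,
    )


@dataclass
class CrossValResult:
    scheme: str
    per_fold: pd.DataFrame           # fold, n_obs, me, mse
    me: float                        # pooled mean error (pred - obs), IU/L
    mse: float                       # pooled mean squared error, (IU/L)^2


def _population_prediction_errors(
    train_fit_pop: PopulationModel, held_out: Sequence[SubjectData], log_scale: bool
) -> np.ndarray:
    errs = []
    packed = PackedData(list(held_out))
    ctx = JointContext(packed, train_fit_pop)
    f = ctx.predictions(np.zeros((packed.n, train_fit_pop.omega.dim)))
    for i, s in enumerate(packed.subjects):
        for j, r in enumerate(s.observations()):
            if r.is_blq:
                continue
            if log_scale:
                errs.append(np.log(max(f[i, j], 1e-9)) - np.log(max(r.dv, 1e-9)))
            else:
                errs.append(f[i, j] - r.dv)
    return np.asarray(errs)


def cross_validate(
    ds: PKDataset,
    pop_init: PopulationModel,
    scheme: str = "kfold",
    k: int = 5,
    holdout_fraction: float = 0.2,
    seed: int = 0,
    log_scale: bool = False,
    refit: bool = True,
    **fit_kwargs,
) -> CrossValResult:
    """Holdout or k-fold cross-validation at the subject level.

    Folds partition subjects, never observations within a subject.  Held-out
    subjects are predicted at the population level (eta = 0, own covariates
    and dose); ME = mean(pred - obs) and MSE = mean((pred - obs)^2) over
    their non-BLQ observations, per fold and pooled.

    ``refit=False`` skips the per-fold training fit and evaluates
    ``pop_init`` as a fixed external model on each fold.
    """
    n = len(ds.subjects)
    rng = np.random.default_rng(seed)
    fit_kwargs.setdefault("compute_se", False)
    order = rng.permutation(n)
    if scheme == "holdout":
        n_test = max(1, int(round(holdout_fraction * n)))
        folds = [order[:n_test]]
    elif scheme == "kfold":
        if k > n:
            raise ValueError("k must not exceed the number of subjects")
        folds = [order[i::k] for i in range(k)]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    per_fold = []
    all_err = []
    for fold_id, test_idx in enumerate(folds):
        test = [ds.subjects[i] for i in sorted(test_idx)]
        train = [ds.subjects[i] for i in range(n) if i not in set(test_idx)]
        if refit:
            fit = fit_population(PKDataset(train, provenance="cv-train"),
                                 pop_init, **fit_kwargs)
            pop = fit.pop
        else:
            pop = pop_init
        errs = _population_prediction_errors(pop, test, log_scale)
        if errs.size == 0:
            raise ValueError(f"fold {fold_id} holds no valid observations")
        per_fold.append({"fold": fold_id, "n_obs": errs.size,
                         "me": float(errs.mean()), "mse": float((errs**2).mean())})
        all_err.append(errs)
    pooled = np.concatenate(all_err)
    return CrossValResult(
        scheme=scheme, per_fold=pd.DataFrame(per_fold),
        me=float(pooled.mean()), mse=float((pooled**2).mean()),
    )


def sparse_subset_validation(
    ds_rich: PKDataset,
    pop: PopulationModel,
    subset_times: Sequence[float],
    thresholds_iul: Sequence[float] = (50.0, 20.0, 10.0),
) -> pd.DataFrame:
    """Forecast agreement between the full profile and a 3-4 sample subset.

    For each subject the empirical-Bayes parameters are estimated twice —
    from the complete profile and from the sparse subset — and the derived
    quantities (terminal half-life, times to the clinical thresholds) are
    compared as relative differences (sparse vs full)."""
    from .simulate import sparsify
    from .population import individual_parameters

    ds_sparse = sparsify(ds_rich, subset_times)
    sparse_by_cid = {s.cid: s for s in ds_sparse.subjects}
    rows = []
    for s in ds_rich.subjects:
        sp = sparse_by_cid.get(s.cid)
        if sp is None or len(sp.observations()) == 0:
            import warnings

            warnings.warn(f"subject {s.cid}: no subset observations; skipped")
            continue
        out = {"cid": s.cid}
        for label, subj in (("full", s), ("sparse", sp)):
            eta, _, _ = conditional_eta_mode(subj, pop)
            params = individual_parameters(pop, subj.covariates(), eta)
            out[f"thalf_{label}"] = terminal_halflife(pop.structural, params)
            for thr in thresholds_iul:
                t = time_to_level(pop.structural, params, subj.regimen(),
                                  subj.initial_state(), thr)
                out[f"t{int(thr)}_{label}"] = np.nan if t is None else t
        out["thalf_reldiff"] = (out["thalf_sparse"] - out["thalf_full"]) / out["thalf_full"]
        for thr in thresholds_iul:
            a, b = out[f"t{int(thr)}_sparse"], out[f"t{int(thr)}_full"]
            out[f"t{int(thr)}_reldiff"] = (a - b) / b if np.isfinite(a) and np.isfinite(b) and b else np.nan
        rows.append(out)
    return pd.DataFrame(rows)
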