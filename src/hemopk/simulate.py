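"""Synthetic factor-level cohorts with known ground truth.

Real dense factor-VIII/IX PK datasets are proprietary, so development and
testing run on simulated cohorts that mimic their structure: a classical
11-sample design (4 samples in the distribution phase within the first
hour, 7 in the elimination phase out to 48-72 h), weight-based dosing as a
short IV infusion, hemophilia-like covariate ranges, log-normal
between-subject variability, combined additive-proportional residual error,
and censoring at the 0.01 IU/mL assay limit of quantification.

The default truth parameters are implementation defaults chosen to be
factor-VIII-like (terminal half-life 12 h in a ~3 L central volume); they do
not reproduce any specific commercial product.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import (
    DEFAULT_LOQ_IU_ML,
    PKDataset,
    SubjectData,
    assemble_subject,
    iu_ml_to_iul,
)
from .population import ErrorModel, OmegaMatrix, PopulationModel, typical_value
from .structural import ONE_COMPARTMENT, DoseRegimen, InitialState, concentration

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "default_fviii_model",
    "default_fviii_spec",
    "simulate_cohort",
    "sparsify",
    "inject_errors",
]

# 11-point rich schedule: 4 distribution-phase samples in 0-1 h,
# 7 elimination-phase samples out to 48 h
RICH_SCHEDULE_H = (0.25, 0.5, 0.75, 1.0, 3.0, 6.0, 9.0, 12.0, 24.0, 32.0, 48.0)


def default_fviii_model(
    omega_cl: float = 0.09,
    omega_v: float = 0.09,
    error: ErrorModel | None = None,
    covariate_effects=(),
) -> PopulationModel:
    """Factor-VIII-like 1-compartment truth: V = 3 L, terminal t1/2 = 12 h."""
    tvv = 3.0
    tvcl = tvv * np.log(2.0) / 12.0  # = 0.1733 L/h
    return PopulationModel(
        structural=ONE_COMPARTMENT,
        theta={"CL": tvcl, "V": tvv},
        omega=OmegaMatrix.diagonal([omega_cl, omega_v]),
        error=error or ErrorModel("combined", sigma_add=2.0, sigma_prop=0.10),
        covariate_effects=list(covariate_effects),
        eta_params=("CL", "V"),
    )


@dataclass
class SimulationSpec:
    """Everything needed to simulate a cohort reproducibly."""

    truth: PopulationModel
    n_subjects: int = 40
    schedule_h: tuple[float, ...] = RICH_SCHEDULE_H
    dose_iu_per_kg: float = 50.0
    infusion_duration_h: float = 1.0 / 6.0      # 10-minute administration
    loq_iul: float = iu_ml_to_iul(DEFAULT_LOQ_IU_ML)
    age_range: tuple[float, float] = (12.0, 65.0)
    weight_range: tuple[float, float] = (42.0, 130.0)
    baseline_iul: float = 5.0                   # severe hemophilia, 0.5% of normal
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.schedule_h:
            raise ValueError("sampling schedule must be non-empty")
        if self.loq_iul <= 0:
            raise ValueError("LOQ must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def default_fviii_spec(n_subjects: int = 40, seed: int = 0, **model_kwargs) -> SimulationSpec:
    return SimulationSpec(truth=default_fviii_model(**model_kwargs),
                          n_subjects=n_subjects, seed=seed)


@dataclass
class GroundTruth:
    subjects: pd.DataFrame       # cid, eta_*, theta_*, covariates
    observations: pd.DataFrame   # cid, timeh, f_true, y, censored


def _draw_covariates(spec: SimulationSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_subjects
    age = rng.uniform(*spec.age_range, size=n)
    # weight conditional on age: linear growth to 18 y, then a stable adult
    # distribution; a crude two-segment stand-in for pediatric-to-adult cohorts
    bw_child = 10.0 + 3.0 * age
    bw_adult = rng.normal(75.0, 14.0, size=n)
    bw = np.where(age < 18.0, bw_child + rng.normal(0.0, 5.0, size=n), bw_adult)
    bw = np.clip(bw, *spec.weight_range)
    return pd.DataFrame({"AGE": np.round(age, 1), "BW": np.round(bw, 1)})


def simulate_cohort(spec: SimulationSpec) -> tuple[PKDataset, GroundTruth]:
    """Simulate a cohort and assemble it into the standard dataset layout.

    Residual error is drawn per the truth's error model; realized values
    below the LOQ become BLQ rows.  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    cov = _draw_covariates(spec, rng)
    truth = spec.truth
    d = truth.omega.dim
    etas = rng.multivariate_normal(np.zeros(d), truth.omega.matrix, size=spec.n_subjects)
    subjects = []
    subj_rows = []
    obs_rows = []
    times = np.asarray(spec.schedule_h)
    for i in range(spec.n_subjects):
        cid = i + 1
        cdict = {k: float(cov.loc[i, k]) for k in cov.columns}
        params = {}
        for p in truth.structural.param_names:
            tv = typical_value(truth, p, cdict)
            if p in truth.eta_params:
                tv *= float(np.exp(etas[i, truth.eta_params.index(p)]))
            params[p] = tv
        if any(v <= 0 for v in params.values()):
            raise ValueError(f"simulation spec yields non-positive parameters for subject {cid}")
        amount = spec.dose_iu_per_kg * cdict["BW"]
        # simulate with the duration as it will be recorded (4-decimal
        # truncation), so dataset and ground truth describe the same infusion
        from .dataset import truncate4

        regimen = DoseRegimen.single(amount, truncate4(spec.infusion_duration_h))
        init = InitialState(baseline_iul=spec.baseline_iul)
        f = concentration(truth.structural, params, regimen, init, times)
        em = truth.error
        if em.form == "exponential":
            y = f * np.exp(em.sigma_prop * rng.standard_normal(times.size))
        else:
            eps_p = rng.standard_normal(times.size)
            eps_a = rng.standard_normal(times.size)
            y = f.copy()
            if em.form in ("proportional", "combined"):
                y = y * (1.0 + em.sigma_prop * eps_p)
            if em.form in ("additive", "combined"):
                y = y + em.sigma_add * eps_a
        y = np.maximum(y, 0.0)
        subj = assemble_subject(
            dose={"amount_iu": amount, "duration_h": spec.infusion_duration_h},
            observations=[{"time_h": t, "conc_iul": c} for t, c in zip(times, y)],
            demographics={"age": cdict["AGE"], "bw": cdict["BW"]},
            baseline_measured=spec.baseline_iul,
            loq_iul=spec.loq_iul,
            cid=cid,
        )
        subjects.append(subj)
        row = {"cid": cid, **{f"eta_{p}": etas[i, j] for j, p in enumerate(truth.eta_params)},
               **{f"theta_{p}": params[p] for p in params}, **cdict}
        subj_rows.append(row)
        for t, ft, yt in zip(times, f, y):
            obs_rows.append({"cid": cid, "timeh": t, "f_true": ft, "y": yt,
                             "censored": yt < spec.loq_iul})
    ds = PKDataset(subjects, provenance=f"simulated(seed={spec.seed})")
    return ds, GroundTruth(pd.DataFrame(subj_rows), pd.DataFrame(obs_rows))


def sparsify(ds: PKDataset, keep_times: Sequence[float]) -> PKDataset:
    """Keep only observation/BLQ rows at the given times (a sparse design of
    as few as 3-4 factor levels); pre-dose and dose records are untouched."""
    if len(keep_times) == 0:
        raise ValueError("keep_times must be non-empty")
    keep = set(float(t) for t in keep_times)
    new_subjects = []
    for s in ds.subjects:
        recs = [r for r in s.records
                if not (r.is_observation or r.is_blq) or float(r.timeh) in keep]
        new_subjects.append(SubjectData(recs))
    return PKDataset(new_subjects, provenance=ds.provenance + "+sparsified")


def inject_errors(
    ds: PKDataset,
    error_menu: dict[str, int],
    seed: int,
) -> tuple[PKDataset, pd.DataFrame]:
    """Plant detectable errors for validation testing.

    ``error_menu`` maps {'rising-concentration','duplicate','covariate-outlier',
    'missing'} to counts.  Returns the corrupted dataset and a ledger of the
    planted errors (cid, row_index, category).
    """
    rng = np.random.default_rng(seed)
    allowed = {"rising-concentration", "duplicate", "covariate-outlier", "missing"}
    bad = set(error_menu) - allowed
    if bad:
        raise ValueError(f"unknown error categories: {sorted(bad)}")
    subjects = [SubjectData(list(s.records)) for s in ds.subjects]
    ledger = []

    def pick_subject_with_obs():
        order = rng.permutation(len(subjects))
        for si in order:
            idx = [i for i, r in enumerate(subjects[si].records)
                   if r.is_observation and r.timeh > 1.0]
            if len(idx) >= 2:
                return si, idx
        raise ValueError("no subject with enough late observations to corrupt")

    for _ in range(error_menu.get("rising-concentration", 0)):
        si, idx = pick_subject_with_obs()
        i = int(idx[-1])
        prev = subjects[si].records[idx[-2]]
        r = subjects[si].records[i]
        subjects[si].records[i] = replace(r, dv=prev.dv * 1.5)
        ledger.append({"cid": subjects[si].cid, "row_index": i,
                       "category": "rising-concentration"})
    for _ in range(error_menu.get("duplicate", 0)):
        si = int(rng.integers(len(subjects)))
        recs = subjects[si].records
        i = int(rng.integers(2, len(recs)))
        recs.insert(i + 1, replace(recs[i]))
        ledger.append({"cid": subjects[si].cid, "row_index": i + 1,
                       "category": "duplicate-record"})
    for _ in range(error_menu.get("covariate-outlier", 0)):
        si = int(rng.integers(len(subjects)))
        recs = subjects[si].records
        subjects[si].records[:] = [replace(r, age=250.0) for r in recs]
        ledger.append({"cid": subjects[si].cid, "row_index": 0,
                       "category": "covariate-outlier"})
    for _ in range(error_menu.get("missing", 0)):
        si = int(rng.integers(len(subjects)))
        recs = subjects[si].records
        obs_idx = [i for i, r in enumerate(recs) if r.is_observation]
        i = int(rng.choice(obs_idx))
        recs[i] = replace(recs[i], dv=float("nan"))
        ledger.append({"cid": subjects[si].cid, "row_index": i,
                       "category": "missing-value"})
    return (PKDataset(subjects, provenance=ds.provenance + "+errors"),
            pd.DataFrame(ledger, columns=["cid", "row_index", "category"]))
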