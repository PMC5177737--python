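"""Hierarchical population-PK model components.

A population model couples a structural disposition model with three layers
of variability:

* typical values modified by covariate effects (linear, power, exponential
  or categorical-fraction forms, composed multiplicatively),
* between-subject variability (BSV): log-normally distributed individual
  parameters, ``theta_ij = TV(theta_i | covariates) * exp(eta_ij)`` with
  ``eta ~ N(0, Omega)``,
* residual unexplained variability (RUV): additive, proportional,
  exponential (log-scale additive) or combined additive-proportional error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

import numpy as np

from .structural import StructuralModel

__all__ = [
    "ErrorModel",
    "CovariateEffect",
    "OmegaMatrix",
    "PopulationModel",
    "typical_value",
    "individual_parameters",
    "residual_sd",
    "CovariateUnavailableError",
]

ErrorForm = Literal["additive", "proportional", "exponential", "combined"]
CovariateForm = Literal["linear", "power", "exponential", "categorical"]


class CovariateUnavailableError(KeyError):
    """A covariate required by the selected model is absent for a subject."""


@dataclass(frozen=True)
class ErrorModel:
    form: ErrorForm = "combined"
    sigma_add: float = 0.0
    sigma_prop: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_add < 0 or self.sigma_prop < 0:
            raise ValueError("sigma parameters must be non-negative")
        if self.form not in ("additive", "proportional", "exponential", "combined"):
            raise ValueError(f"unknown error form {self.form!r}")

    @property
    def sigma_names(self) -> tuple[str, ...]:
        return {
            "additive": ("sigma_add",),
            "proportional": ("sigma_prop",),
            "exponential": ("sigma_prop",),
            "combined": ("sigma_prop", "sigma_add"),
        }[self.form]


def residual_sd(f, em: ErrorModel):
    """Residual standard deviation at predicted concentration ``f`` (IU/L).

    For the exponential form the error is additive on log concentration and
    the returned value is the log-scale standard deviation.
    """
    f = np.asarray(f, dtype=float)
    if em.form == "additive":
        return np.broadcast_to(em.sigma_add, f.shape).astype(float)
    if em.form == "proportional":
        return f * em.sigma_prop
    if em.form == "exponential":
        return np.broadcast_to(em.sigma_prop, f.shape).astype(float)
    return np.sqrt(f * f * em.sigma_prop**2 + em.sigma_add**2)


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate-parameter relationship.

    forms (x = covariate value, c = centering constant, th = coefficient):
      linear       TV * (1 + th * (x - c))
      power        TV * (x / c) ** th
      exponential  TV * exp(th * (x - c))
      categorical  TV * (1 + th * 1{x == level})
    """

    parameter: str
    covariate: str
    form: CovariateForm
    theta: float
    center: float = 0.0
    level: int | None = None

    def __post_init__(self) -> None:
        if self.form == "power" and self.center <= 0:
            raise ValueError("power form requires a positive centering value")
        if self.form == "categorical" and self.level is None:
            raise ValueError("categorical form requires a level")

    def factor(self, x):
        x = np.asarray(x, dtype=float)
        if self.form == "linear":
            return 1.0 + self.theta * (x - self.center)
        if self.form == "power":
            return (x / self.center) ** self.theta
        if self.form == "exponential":
            return np.exp(self.theta * (x - self.center))
        return 1.0 + self.theta * (x == self.level)


@dataclass(frozen=True)
class OmegaMatrix:
    """BSV variance-covariance matrix over the eta vector."""

    matrix: np.ndarray
    structure: Literal["diagonal", "unstructured"] = "diagonal"

    def __post_init__(self) -> None:
        m = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if m.shape[0] != m.shape[1]:
            raise ValueError("omega matrix must be square")
        if not np.allclose(m, m.T):
            raise ValueError("omega matrix must be symmetric")
        if np.any(np.linalg.eigvalsh(m) < -1e-10):
            raise ValueError("omega matrix must be positive semi-definite")
        if self.structure == "diagonal" and np.any(m != np.diag(np.diag(m))):
            raise ValueError("diagonal structure requires zero off-diagonals")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def diagonal(cls, variances) -> "OmegaMatrix":
        return cls(np.diag(np.asarray(variances, dtype=float)), "diagonal")

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]


@dataclass
class PopulationModel:
    structural: StructuralModel
    theta: dict[str, float]                       # typical values, keyed by parameter
    omega: OmegaMatrix
    error: ErrorModel
    covariate_effects: list[CovariateEffect] = field(default_factory=list)
    eta_params: tuple[str, ...] = ()              # parameters carrying BSV, in eta order

    def __post_init__(self) -> None:
        names = set(self.structural.param_names)
        if set(self.theta) != names:
            raise ValueError(f"theta must provide exactly {sorted(names)}")
        for tv in self.theta.values():
            if tv <= 0:
                raise ValueError("typical values must be positive")
        for eff in self.covariate_effects:
            if eff.parameter not in names:
                raise ValueError(f"covariate effect targets unknown parameter {eff.parameter!r}")
        if not self.eta_params:
            self.eta_params = tuple(self.structural.param_names)
        if any(p not in names for p in self.eta_params):
            raise ValueError("eta_params must be structural parameters")
        if self.omega.dim != len(self.eta_params):
            raise ValueError("omega dimension must match number of eta-bearing parameters")

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "n_compartments": self.structural.n_compartments,
            "theta": dict(self.theta),
            "omega": {"matrix": self.omega.matrix.tolist(), "structure": self.omega.structure},
            "error": {
                "form": self.error.form,
                "sigma_add": self.error.sigma_add,
                "sigma_prop": self.error.sigma_prop,
            },
            "covariate_effects": [
                {
                    "parameter": e.parameter,
                    "covariate": e.covariate,
                    "form": e.form,
                    "theta": e.theta,
                    "center": e.center,
                    "level": e.level,
                }
                for e in self.covariate_effects
            ],
            "eta_params": list(self.eta_params),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PopulationModel":
        return cls(
            structural=StructuralModel(int(d["n_compartments"])),
            theta={k: float(v) for k, v in d["theta"].items()},
            omega=OmegaMatrix(np.asarray(d["omega"]["matrix"], dtype=float), d["omega"]["structure"]),
            error=ErrorModel(
                d["error"]["form"],
                float(d["error"]["sigma_add"]),
                float(d["error"]["sigma_prop"]),
            ),
            covariate_effects=[
                CovariateEffect(
                    parameter=e["parameter"],
                    covariate=e["covariate"],
                    form=e["form"],
                    theta=float(e["theta"]),
                    center=float(e.get("center", 0.0)),
                    level=e.get("level"),
                )
                for e in d.get("covariate_effects", [])
            ],
            eta_params=tuple(d.get("eta_params") or ()),
        )

    def save(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "PopulationModel":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def with_updates(self, **kwargs) -> "PopulationModel":
        return replace(self, **kwargs)

    # ---- evaluation ----------------------------------------------------
    def required_covariates(self) -> tuple[str, ...]:
        seen: list[str] = []
        for e in self.covariate_effects:
            if e.covariate not in seen:
                seen.append(e.covariate)
        return tuple(seen)


def typical_value(pop: PopulationModel, param: str, covariates: Mapping[str, float]) -> float:
    """Covariate-adjusted typical value of one structural parameter."""
    tv = pop.theta[param]
    for eff in pop.covariate_effects:
        if eff.parameter != param:
            continue
        if eff.covariate not in covariates or covariates[eff.covariate] is None:
            raise CovariateUnavailableError(eff.covariate)
        tv = tv * float(eff.factor(covariates[eff.covariate]))
    return tv


def typical_value_matrix(pop: PopulationModel, covariates: Mapping[str, np.ndarray]) -> np.ndarray:
    """Typical values for many subjects at once: shape (n_subjects, n_params)."""
    names = pop.structural.param_names
    n = None
    for v in covariates.values():
        n = np.asarray(v).shape[0]
        break
    if n is None:
        raise ValueError("covariates mapping is empty")
    out = np.tile([pop.theta[p] for p in names], (n, 1))
    for eff in pop.covariate_effects:
        if eff.covariate not in covariates:
            raise CovariateUnavailableError(eff.covariate)
        j = names.index(eff.parameter)
        out[:, j] *= eff.factor(np.asarray(covariates[eff.covariate], dtype=float))
    return out


def individual_parameters(
    pop: PopulationModel, covariates: Mapping[str, float], eta
) -> dict[str, float]:
    """Individual parameters theta_ij = TV * exp(eta) on eta-bearing parameters."""
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (len(pop.eta_params),):
        raise ValueError(
            f"eta must have length {len(pop.eta_params)}, got shape {eta.shape}"
        )
    out = {}
    for p in pop.structural.param_names:
        tv = typical_value(pop, p, covariates)
        if p in pop.eta_params:
            tv = tv * float(np.exp(eta[pop.eta_params.index(p)]))
        out[p] = tv
    return out
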