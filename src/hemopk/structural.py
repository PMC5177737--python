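"""Closed-form linear compartmental disposition models for IV infusion.

Clotting-factor concentrates are dosed as short constant-rate intravenous
infusions.  The plasma concentration in the central compartment of a linear
1-, 2- or 3-compartment model is a sum of 1-3 exponentials; the module
computes those exponentials (rate constants and bolus coefficients) from the
clearance-volume parameterizations used throughout hemophilia PopPK work
(CL, V / CL, V1, Q, V2 / CL, V1, Q2, V2, Q3, V3), superposes an arbitrary
dosing history, and adds the patient's endogenous baseline and any residual
factor from a previous dose.

Concentrations are IU/L, amounts IU, times hours, clearances L/h, volumes L.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "StructuralModel",
    "DoseRegimen",
    "InitialState",
    "ONE_COMPARTMENT",
    "TWO_COMPARTMENT",
    "THREE_COMPARTMENT",
    "exp_coefficients",
    "concentration",
    "terminal_halflife",
    "time_to_level",
]

_PARAM_NAMES = {
    1: ("CL", "V"),
    2: ("CL", "V1", "Q", "V2"),
    3: ("CL", "V1", "Q2", "V2", "Q3", "V3"),
}


@dataclass(frozen=True)
class StructuralModel:
    """A linear mammillary disposition model with 1, 2 or 3 compartments."""

    n_compartments: int

    def __post_init__(self) -> None:
        if self.n_compartments not in _PARAM_NAMES:
            raise ValueError(f"n_compartments must be 1, 2 or 3, got {self.n_compartments}")

    @property
    def param_names(self) -> tuple[str, ...]:
        return _PARAM_NAMES[self.n_compartments]

    @property
    def central_volume_name(self) -> str:
        return "V" if self.n_compartments == 1 else "V1"


ONE_COMPARTMENT = StructuralModel(1)
TWO_COMPARTMENT = StructuralModel(2)
THREE_COMPARTMENT = StructuralModel(3)


@dataclass(frozen=True)
class Infusion:
    start_h: float
    duration_h: float
    amount_iu: float

    def __post_init__(self) -> None:
        if self.duration_h <= 0:
            raise ValueError("infusion duration must be positive")
        if self.amount_iu < 0:
            raise ValueError("infusion amount must be non-negative")

    @property
    def rate(self) -> float:
        return self.amount_iu / self.duration_h

    @property
    def end_h(self) -> float:
        return self.start_h + self.duration_h


@dataclass
class DoseRegimen:
    """An ordered sequence of constant-rate infusions."""

    infusions: list[Infusion] = field(default_factory=list)

    def __post_init__(self) -> None:
        starts = [inf.start_h for inf in self.infusions]
        if any(b < a for a, b in zip(starts, starts[1:])):
            raise ValueError("infusion starts must be non-decreasing")

    @classmethod
    def single(cls, amount_iu: float, duration_h: float, start_h: float = 0.0) -> "DoseRegimen":
        return cls([Infusion(start_h, duration_h, amount_iu)])

    @property
    def end_of_last_infusion(self) -> float:
        if not self.infusions:
            return 0.0
        return max(inf.end_h for inf in self.infusions)


@dataclass(frozen=True)
class InitialState:
    """Endogenous baseline (constant, additive) and residual pre-dose factor.

    ``residual_iul`` is the measured pre-dose concentration in excess of
    baseline; it is treated as an initial amount ``residual*V_central`` in the
    central compartment and decays according to the disposition model.
    """

    baseline_iul: float = 0.0
    residual_iul: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_iul < 0 or self.residual_iul < 0:
            raise ValueError("baseline and residual must be non-negative")


def _validate_params(model: StructuralModel, params: dict) -> np.ndarray:
    vals = []
    for name in model.param_names:
        if name not in params:
            raise ValueError(f"missing structural parameter {name!r}")
        v = float(params[name])
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"structural parameter {name!r} must be strictly positive, got {v}")
        vals.append(v)
    return np.asarray(vals)


def exp_coefficients(model: StructuralModel, params: dict | np.ndarray):
    """Exponential representation of the unit-bolus central concentration.

    Returns ``(lam, w)`` such that a bolus of amount D into the central
    compartment produces central concentration ``D * sum_i w_i exp(lam_i t)``
    with ``lam_i < 0`` and ``sum_i w_i = 1/V_central``.

    ``params`` may be a dict of scalars or an array of shape ``(..., p)`` in
    the canonical parameter order; the returned arrays then have shape
    ``(..., n_compartments)``.
    """
    if isinstance(params, dict):
        p = _validate_params(model, params)
    else:
        p = np.asarray(params, dtype=float)
    n = model.n_compartments
    if n == 1:
        cl, v = p[..., 0], p[..., 1]
        lam = -(cl / v)[..., None]
        w = (1.0 / v)[..., None]
        return lam, w
    if n == 2:
        cl, v1, q, v2 = (p[..., i] for i in range(4))
        k10, k12, k21 = cl / v1, q / v1, q / v2
        s = k10 + k12 + k21
        disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
        alpha = 0.5 * (s + disc)
        beta = 0.5 * (s - disc)
        # guard eigenvalue ties for the partial-fraction coefficients
        denom = np.where(np.abs(alpha - beta) < 1e-12 * alpha, 1e-12 * alpha, alpha - beta)
        w_a = (alpha - k21) / (v1 * denom)
        w_b = (k21 - beta) / (v1 * denom)
        lam = np.stack([-alpha, -beta], axis=-1)
        w = np.stack([w_a, w_b], axis=-1)
        return lam, w
    # 3 compartments: eigendecomposition of the micro-constant matrix
    cl, v1, q2, v2, q3, v3 = (p[..., i] for i in range(6))
    k10, k12, k21 = cl / v1, q2 / v1, q2 / v2
    k13, k31 = q3 / v1, q3 / v3
    shape = np.broadcast_shapes(np.shape(k10), ())
    K = np.zeros(shape + (3, 3))
    K[..., 0, 0] = -(k10 + k12 + k13)
    K[..., 0, 1] = k21
    K[..., 0, 2] = k31
    K[..., 1, 0] = k12
    K[..., 1, 1] = -k21
    K[..., 2, 0] = k13
    K[..., 2, 2] = -k31
    lam, P = np.linalg.eig(K)
    lam = np.real(lam)
    # perturb numerically tied eigenvalues so the inverse stays well-conditioned
    order = np.argsort(lam, axis=-1)
    lam = np.take_along_axis(lam, order, axis=-1)
    P = np.take_along_axis(np.real(P), order[..., None, :], axis=-1)
    close = np.abs(np.diff(lam, axis=-1)) < 1e-12 * np.abs(lam[..., :-1])
    if np.any(close):
        lam = lam + 1e-12 * np.abs(lam) * np.arange(3)
    Pinv = np.linalg.inv(P)
    w = P[..., 0, :] * Pinv[..., :, 0] / v1[..., None]
    return lam, w


def _infusion_response(lam, w, rate, start, duration, t):
    """Central concentration from one infusion, vectorized over exponentials.

    lam, w: (..., d); t: (..., m) broadcastable against lam[..., None, :].
    Returns array shaped like t.
    """
    tau = t[..., :, None] - start
    lam_ = lam[..., None, :]
    w_ = w[..., None, :]
    during = np.expm1(lam_ * np.maximum(tau, 0.0)) / lam_
    after = (np.exp(lam_ * np.maximum(tau, 0.0)) - np.exp(lam_ * np.maximum(tau - duration, 0.0))) / lam_
    resp = np.where(tau <= duration, during, after)
    resp = np.where(tau <= 0, 0.0, resp)
    return rate * np.sum(w_ * resp, axis=-1)


def concentration(
    model: StructuralModel,
    params: dict,
    regimen: DoseRegimen,
    init: InitialState,
    times: Sequence[float],
) -> np.ndarray:
    """Central-compartment concentration (IU/L) at the given times (h)."""
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    lam, w = exp_coefficients(model, params)
    out = np.full(t.shape, float(init.baseline_iul))
    if init.residual_iul > 0:
        v_c = float(params[model.central_volume_name])
        amount = init.residual_iul * v_c
        out = out + amount * np.sum(w[None, :] * np.exp(lam[None, :] * t[:, None]), axis=-1)
    for inf in regimen.infusions:
        if inf.amount_iu == 0:
            continue
        out = out + _infusion_response(lam, w, inf.rate, inf.start_h, inf.duration_h, t)
    return out


def terminal_halflife(model: StructuralModel, params: dict) -> float:
    """Terminal elimination half-life, ln2 over the slowest rate constant."""
    lam, _ = exp_coefficients(model, params)
    return float(np.log(2.0) / np.min(np.abs(lam)))


def time_to_level(
    model: StructuralModel,
    params: dict,
    regimen: DoseRegimen,
    init: InitialState,
    level_iul: float,
    search_window_h: float = 500.0,
) -> float | None:
    """First time after the end of the last infusion at which the
    concentration falls to or below ``level_iul``.

    Returns ``None`` when the level is at or below the asymptotic floor
    (the endogenous baseline) and hence never reached.  Refined to better
    than 0.01 h.
    """
    if level_iul <= init.baseline_iul:
        return None
    t_end = regimen.end_of_last_infusion
    f = lambda t: concentration(model, params, regimen, init, np.atleast_1d(t))[0] - level_iul
    if f(t_end) <= 0:
        return t_end
    # bracket on a grid, then refine
    from scipy.optimize import brentq

    t_hi = t_end + search_window_h
    grid = np.linspace(t_end, t_hi, 512)
    vals = concentration(model, params, regimen, init, grid) - level_iul
    below = np.nonzero(vals <= 0)[0]
    if below.size == 0:
        return None
    i = below[0]
    return float(brentq(f, grid[i - 1], grid[i], xtol=1e-4))
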