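"""Closed-form kinetics of a two-compartment model with zero-order IV infusion.

Units are fixed throughout the package: time in hours, dose amounts in mg,
volumes in litres, concentrations in mg/L.  The model is linear in dose, so
multi-dose concentration profiles are superpositions of single-infusion
responses.  The closed form keeps Monte Carlo dosing simulation cheap; ODE
integration is deliberately not part of the library (the test suite uses a
stiff integrator as an independent oracle).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "IndividualParams",
    "DoseEvent",
    "MicroConstants",
    "SecondaryParams",
    "micro_constants",
    "secondary_params",
    "conc_single_infusion",
    "simulate_profile",
    "conc_profiles",
]

#: column order used for parameter matrices throughout the package
PARAM_ORDER = ("V1", "V2", "Q", "CL")


@dataclass(frozen=True)
class IndividualParams:
    """Realized two-compartment parameters for one subject.

    Parameters
    ----------
    V1, V2 : float
        Central and peripheral volumes of distribution (L).
    Q : float
        Inter-compartment clearance (L/h).
    CL : float
        Elimination clearance (L/h).
    """

    V1: float
    V2: float
    Q: float
    CL: float

    def __post_init__(self) -> None:
        for name in PARAM_ORDER:
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0.0):
                raise ValueError(f"{name} must be finite and > 0, got {value!r}")

    def as_array(self) -> np.ndarray:
        """Return the parameters as ``[V1, V2, Q, CL]``."""
        return np.array([self.V1, self.V2, self.Q, self.CL], dtype=float)


@dataclass(frozen=True)
class DoseEvent:
    """A single zero-order IV infusion.

    ``start_time`` is hours since the first dose; ``amount`` in mg;
    ``duration`` the infusion length in hours (default 1 h -- the source
    protocol never records the infusion length, so it is configurable
    everywhere a schedule is built).
    """

    start_time: float
    amount: float
    duration: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.start_time) and self.start_time >= 0.0):
            raise ValueError(f"start_time must be >= 0, got {self.start_time!r}")
        if not (math.isfinite(self.amount) and self.amount > 0.0):
            raise ValueError(f"amount must be > 0, got {self.amount!r}")
        if not (math.isfinite(self.duration) and self.duration > 0.0):
            raise ValueError(f"duration must be > 0, got {self.duration!r}")

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    @property
    def rate(self) -> float:
        """Infusion rate (mg/h)."""
        return self.amount / self.duration


@dataclass(frozen=True)
class MicroConstants:
    """First-order micro rate constants (1/h): k10 = CL/V1, k12 = Q/V1, k21 = Q/V2."""

    k10: float
    k12: float
    k21: float


@dataclass(frozen=True)
class SecondaryParams:
    """Hybrid rate constants, half-lives and steady-state volume."""

    alpha: float
    beta: float
    t_half_alpha: float
    t_half_beta: float
    Vss: float


def micro_constants(p: IndividualParams) -> MicroConstants:
    """Micro rate constants of the two-compartment model."""
    return MicroConstants(k10=p.CL / p.V1, k12=p.Q / p.V1, k21=p.Q / p.V2)


def _macro(V1, V2, Q, CL):
    """Hybrid rates and unit-bolus coefficients, vectorized over parameter arrays.

    Returns ``(alpha, beta, A, B)`` with the unit-bolus central concentration
    ``C(t) = (D/V1) * (A exp(-alpha t) + B exp(-beta t))``.
    """
    k10 = CL / V1
    k12 = Q / V1
    k21 = Q / V2
    s = k10 + k12 + k21
    # stable discriminant: (k10-k21)^2 + k12 (k12 + 2 k10 + 2 k21) > 0 for k12 > 0
    disc = np.sqrt((k10 - k21) ** 2 + k12 * (k12 + 2.0 * (k10 + k21)))
    alpha = 0.5 * (s + disc)
    beta = (k10 * k21) / alpha
    A = (alpha - k21) / (alpha - beta)
    B = (k21 - beta) / (alpha - beta)
    return alpha, beta, A, B


def secondary_params(p: IndividualParams) -> SecondaryParams:
    """Hybrid rate constants alpha > beta, their half-lives and Vss = V1 + V2."""
    alpha, beta, _, _ = _macro(*[np.asarray(getattr(p, n)) for n in PARAM_ORDER])
    ln2 = math.log(2.0)
    return SecondaryParams(
        alpha=float(alpha),
        beta=float(beta),
        t_half_alpha=ln2 / float(alpha),
        t_half_beta=ln2 / float(beta),
        Vss=p.V1 + p.V2,
    )


def _infusion_kernel(t_rel, duration, rate, V1, alpha, beta, A, B):
    """Central concentration of one infusion at time ``t_rel`` after its start.

    Valid both during (t_rel <= duration) and after the infusion; returns 0
    for t_rel <= 0.  All arguments broadcast.
    """
    t = np.maximum(t_rel, 0.0)
    t1 = np.minimum(t, duration)  # elapsed infusion time
    t2 = t - t1  # elapsed post-infusion time
    ca = (A / alpha) * (-np.expm1(-alpha * t1)) * np.exp(-alpha * t2)
    cb = (B / beta) * (-np.expm1(-beta * t1)) * np.exp(-beta * t2)
    return (rate / V1) * (ca + cb)


def conc_single_infusion(p: IndividualParams, dose: DoseEvent, t) -> np.ndarray | float:
    """Central-compartment concentration (mg/L) from one infusion.

    ``t`` is absolute time (h, same clock as ``dose.start_time``); scalar or
    array.  Zero for times at or before the start of the infusion.
    """
    t = np.asarray(t, dtype=float)
    alpha, beta, A, B = _macro(p.V1, p.V2, p.Q, p.CL)
    out = _infusion_kernel(t - dose.start_time, dose.duration, dose.rate, p.V1, alpha, beta, A, B)
    if out.ndim == 0:
        return float(out)
    return out


def simulate_profile(
    p: IndividualParams, doses: Sequence[DoseEvent], times
) -> np.ndarray:
    """Concentration profile under a multi-dose schedule by superposition.

    ``times`` must be sorted and non-negative.  Overlapping infusions simply
    add.  An empty dose list yields all zeros.
    """
    times = np.asarray(times, dtype=float)
    if times.size and (np.any(times < 0.0) or np.any(np.diff(times) < 0.0)):
        raise ValueError("times must be sorted and non-negative")
    out = np.zeros_like(times)
    if not doses:
        return out
    alpha, beta, A, B = _macro(p.V1, p.V2, p.Q, p.CL)
    for dose in doses:
        out += _infusion_kernel(
            times - dose.start_time, dose.duration, dose.rate, p.V1, alpha, beta, A, B
        )
    return out


def conc_profiles(params, times, dose_times, dose_amounts, dose_durations) -> np.ndarray:
    """Vectorized profiles for many subjects sharing a dosing time grid.

    Parameters
    ----------
    params : (n, 4) array
        Rows of ``[V1, V2, Q, CL]`` per subject.
    times : (m,) array
        Evaluation times (h).
    dose_times, dose_durations : (d,) arrays
        Shared schedule of infusion starts and durations.
    dose_amounts : (d,) or (n, d) array
        Amounts (mg); a 2-D array gives per-subject amounts (e.g. mg/kg
        scaling by body weight).

    Returns
    -------
    (n, m) array of concentrations.
    """
    params = np.asarray(params, dtype=float)
    times = np.asarray(times, dtype=float)
    dose_times = np.asarray(dose_times, dtype=float)
    dose_durations = np.broadcast_to(np.asarray(dose_durations, dtype=float), dose_times.shape)
    amounts = np.asarray(dose_amounts, dtype=float)
    n = params.shape[0]
    if amounts.ndim == 1:
        amounts = np.broadcast_to(amounts, (n, dose_times.size))
    V1 = params[:, 0][:, None, None]
    alpha, beta, A, B = _macro(params[:, 0], params[:, 1], params[:, 2], params[:, 3])
    alpha = alpha[:, None, None]
    beta = beta[:, None, None]
    A = A[:, None, None]
    B = B[:, None, None]
    t_rel = times[None, :, None] - dose_times[None, None, :]
    rate = (amounts / dose_durations)[:, None, :]
    c = _infusion_kernel(t_rel, dose_durations[None, None, :], rate, V1, alpha, beta, A, B)
    return c.sum(axis=2)
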