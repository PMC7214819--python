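"""Stochastic model layers: lognormal inter-individual variability and the
four residual unexplained-variability (RUV) candidate forms.

IIV: each PK parameter is ``P_i = typical * exp(eta_i)`` with
``eta ~ N(0, omega^2)``, diagonal across parameters.  Omegas are reported on
the 100*sqrt(omega^2) percent scale; residual sigma on the SD scale.

RUV forms (SD of the observation around the individual prediction IPRED):
additive sigma; proportional sigma*IPRED; combined
sqrt(sigma1^2 IPRED^2 + sigma2^2); power sigma*IPRED^power.  The printed
source forms of the proportional/combined models are treated as typos for
these standard mean-unbiased versions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .covariates import CovariateRecord, ThetaVector, typical_values
from .pk_core import IndividualParams

logger = logging.getLogger("teicopk")

__all__ = [
    "OmegaMatrix",
    "EtaVector",
    "ResidualSpec",
    "RESIDUAL_FORMS",
    "individual_params",
    "residual_sd",
    "sample_eta",
    "sample_individuals",
    "draw_observations",
]

RESIDUAL_FORMS = ("additive", "proportional", "combined", "power")

#: assay quantification floor (mg/L); simulated observations below it are censored
LLOQ = 2.0


@dataclass(frozen=True)
class OmegaMatrix:
    """Diagonal IIV variances (omega^2) for V1, V2, CL and Q."""

    omega2_v1: float
    omega2_v2: float
    omega2_cl: float
    omega2_q: float

    def __post_init__(self) -> None:
        for name in ("omega2_v1", "omega2_v2", "omega2_cl", "omega2_q"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_percent(cls, v1: float, v2: float, cl: float, q: float) -> "OmegaMatrix":
        """Build from the reporting convention omega(%) = 100 * sqrt(omega^2)."""
        return cls(*((p / 100.0) ** 2 for p in (v1, v2, cl, q)))

    def sd_array(self) -> np.ndarray:
        """SDs in the order (V1, V2, CL, Q)."""
        return np.sqrt(
            np.array([self.omega2_v1, self.omega2_v2, self.omega2_cl, self.omega2_q])
        )

    def percent(self) -> np.ndarray:
        """Omegas on the 100*sqrt(omega^2) scale, order (V1, V2, CL, Q)."""
        return 100.0 * self.sd_array()


@dataclass(frozen=True)
class EtaVector:
    """Per-subject random effects (dimensionless, unbounded)."""

    eta_v1: float = 0.0
    eta_v2: float = 0.0
    eta_cl: float = 0.0
    eta_q: float = 0.0


@dataclass(frozen=True)
class ResidualSpec:
    """Residual error model: form, SD parameter(s) and the power exponent
    (fixed at 0.5 in the final model)."""

    form: str = "power"
    sigma: float = 0.46
    sigma2: float = 0.0
    power: float = 0.5

    def __post_init__(self) -> None:
        if self.form not in RESIDUAL_FORMS:
            raise ValueError(f"form must be one of {RESIDUAL_FORMS}, got {self.form!r}")
        if self.sigma < 0.0 or self.sigma2 < 0.0:
            raise ValueError("sigma must be >= 0")
        if not (0.0 < self.power <= 1.0):
            raise ValueError(f"power must be in (0, 1], got {self.power}")


def individual_params(tv: IndividualParams, eta: EtaVector) -> IndividualParams:
    """Apply lognormal IIV: each parameter is typical * exp(eta)."""
    return IndividualParams(
        V1=tv.V1 * math.exp(eta.eta_v1),
        V2=tv.V2 * math.exp(eta.eta_v2),
        Q=tv.Q * math.exp(eta.eta_q),
        CL=tv.CL * math.exp(eta.eta_cl),
    )


def residual_sd(ipred, spec: ResidualSpec):
    """SD of the observation around IPRED for the given residual model.

    Vectorized over ``ipred`` (must be >= 0).
    """
    ipred = np.asarray(ipred, dtype=float)
    if np.any(ipred < 0.0):
        raise ValueError("ipred must be non-negative")
    if spec.form == "additive":
        out = np.full_like(ipred, spec.sigma)
    elif spec.form == "proportional":
        out = spec.sigma * ipred
    elif spec.form == "combined":
        out = np.sqrt(spec.sigma**2 * ipred**2 + spec.sigma2**2)
    else:  # power
        out = spec.sigma * ipred**spec.power
    if out.ndim == 0:
        return float(out)
    return out


def sample_eta(omega: OmegaMatrix, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw an (n, 4) matrix of independent etas in the order (V1, V2, CL, Q)."""
    return rng.standard_normal((n, 4)) * omega.sd_array()


def sample_individuals(
    theta: ThetaVector,
    omega: OmegaMatrix,
    cohort: Sequence[CovariateRecord],
    seed: int,
) -> list[IndividualParams]:
    """Draw realized parameters for a cohort: covariates -> typical values ->
    independent lognormal IIV.  Deterministic for a given seed."""
    rng = np.random.default_rng(seed)
    etas = sample_eta(omega, len(cohort), rng)
    out = []
    for record, eta in zip(cohort, etas):
        tv = typical_values(theta, record)
        out.append(
            individual_params(
                tv, EtaVector(eta_v1=eta[0], eta_v2=eta[1], eta_cl=eta[2], eta_q=eta[3])
            )
        )
    return out


def draw_observations(
    ipred,
    spec: ResidualSpec,
    rng: np.random.Generator,
    lloq: float | None = LLOQ,
):
    """Simulate observations around individual predictions.

    Draws ``Y = IPRED + sd(IPRED) * z``; values below the assay floor are
    re-drawn once and dropped if still below (the censoring rule used for all
    synthetic datasets).  Negative values are truncated at 0 with a warning.

    Returns ``(y, keep)`` where ``keep`` flags observations that survive
    censoring.
    """
    ipred = np.atleast_1d(np.asarray(ipred, dtype=float))
    sd = np.atleast_1d(residual_sd(ipred, spec))
    y = ipred + sd * rng.standard_normal(ipred.shape)
    keep = np.ones(ipred.shape, dtype=bool)
    if lloq is not None:
        below = y < lloq
        if below.any():
            y[below] = ipred[below] + sd[below] * rng.standard_normal(int(below.sum()))
            keep = ~(y < lloq)
    negative = keep & (y < 0.0)
    if negative.any():
        logger.warning("truncated %d simulated concentrations at 0", int(negative.sum()))
        y[negative] = 0.0
    return y, keep
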