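"""Covariate machinery: renal function, maturation clearance candidates and
the final covariate model for typical parameter values.

The clearance covariate structure uses allometric body-weight scaling with a
renal-function (eGFR) power term; the central volume scales with the natural
log of body weight normalized by the literal constant 2.3 (the published
form of the equation, kept as printed rather than ``ln 10``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .pk_core import IndividualParams

__all__ = [
    "InvalidParameterError",
    "RenalGroup",
    "RENAL_GROUPS",
    "CovariateRecord",
    "ThetaVector",
    "CandidateCLModel",
    "egfr_schwartz",
    "inverse_schwartz_scr",
    "bsa_mosteller",
    "classify_renal",
    "typical_values",
    "candidate_cl",
    "apply_covariate_form",
]

#: unit conversion for serum creatinine, 1 mg/dL = 88.4 umol/L
SCR_UMOL_PER_MGDL = 88.4
#: bedside Schwartz coefficient (height in cm, SCR in mg/dL)
SCHWARTZ_K = 0.413


class InvalidParameterError(ValueError):
    """A covariate/parameter combination yields an invalid (non-positive)
    parameter proposal; estimation must reject it."""


@dataclass(frozen=True)
class RenalGroup:
    """One renal-function stratum: a half-open eGFR interval [lower, upper)."""

    label: str
    lower: float
    upper: float

    def contains(self, egfr: float) -> bool:
        return self.lower <= egfr < self.upper


#: the four modelled strata, in increasing eGFR order
RENAL_GROUPS = (
    RenalGroup("moderate", 30.0, 60.0),
    RenalGroup("mild", 60.0, 90.0),
    RenalGroup("normal", 90.0, 130.0),
    RenalGroup("augmented", 130.0, math.inf),
)

RENAL_LABELS = tuple(g.label for g in RENAL_GROUPS)


def egfr_schwartz(height: float, scr: float) -> float:
    """Estimated GFR (ml/min/1.73m2) by the bedside Schwartz formula.

    ``height`` in cm, ``scr`` in umol/L (converted internally to mg/dL, which
    the 0.413 coefficient assumes).
    """
    height = float(height)
    scr = float(scr)
    if not (height > 0.0 and scr > 0.0):
        raise InvalidParameterError(f"height and scr must be > 0, got {height}, {scr}")
    return SCHWARTZ_K * height / (scr / SCR_UMOL_PER_MGDL)


def inverse_schwartz_scr(height: float, egfr: float) -> float:
    """Serum creatinine (umol/L) consistent with a target eGFR; inverse of
    :func:`egfr_schwartz`."""
    if not (height > 0.0 and egfr > 0.0):
        raise InvalidParameterError(f"height and egfr must be > 0, got {height}, {egfr}")
    return SCHWARTZ_K * height * SCR_UMOL_PER_MGDL / egfr


def bsa_mosteller(height: float, wt: float) -> float:
    """Body surface area (m2) by the Mosteller formula."""
    if not (height > 0.0 and wt > 0.0):
        raise InvalidParameterError("height and wt must be > 0")
    return math.sqrt(height * wt / 3600.0)


def classify_renal(egfr: float) -> RenalGroup:
    """Assign an eGFR value to one of the four modelled renal strata.

    Values below 30 ml/min/1.73m2 are outside the modelled range (no stratum
    is defined there) and raise a ``ValueError``.
    """
    egfr = float(egfr)
    if not math.isfinite(egfr) or egfr < 30.0:
        raise ValueError(
            f"eGFR {egfr!r} is outside the modelled range (no stratum below 30)"
        )
    for group in RENAL_GROUPS:
        if group.contains(egfr):
            return group
    raise AssertionError("unreachable: strata partition [30, inf)")


@dataclass
class CovariateRecord:
    """Per-subject covariates.

    Mandatory: age (years), sex ('M'/'F'), wt (kg), height (cm), scr
    (umol/L).  eGFR and BSA are derived when not supplied.  The remaining
    laboratory values are optional screening covariates.
    """

    age: float
    sex: str
    wt: float
    height: float
    scr: float
    egfr: Optional[float] = None
    bsa: Optional[float] = None
    bun: Optional[float] = None
    ua: Optional[float] = None
    cys_c: Optional[float] = None
    alt: Optional[float] = None
    ast: Optional[float] = None
    ggt: Optional[float] = None
    tbil: Optional[float] = None

    def __post_init__(self) -> None:
        if self.age < 0.0:
            raise InvalidParameterError(f"age must be >= 0, got {self.age}")
        for name in ("wt", "height", "scr"):
            if not getattr(self, name) > 0.0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.egfr is None:
            self.egfr = egfr_schwartz(self.height, self.scr)
        if self.egfr <= 0.0:
            raise InvalidParameterError(f"egfr must be > 0, got {self.egfr}")
        if self.bsa is None:
            self.bsa = bsa_mosteller(self.height, self.wt)


@dataclass(frozen=True)
class ThetaVector:
    """Fixed effects of the final covariate model.

    ``theta1``..``theta4`` are the covariate exponents (lnWT on V1, WT on V2,
    WT on CL, eGFR on CL); the reference medians normalize the covariates.
    """

    theta_v1: float
    theta_v2: float
    theta_cl: float
    theta_q: float
    theta1: float
    theta2: float
    theta3: float
    theta4: float
    wt_median: float = 10.0
    egfr_median: float = 118.99
    lnwt_ref: float = 2.3

    def __post_init__(self) -> None:
        for name in ("theta_v1", "theta_v2", "theta_cl", "theta_q", "wt_median", "egfr_median"):
            if not getattr(self, name) > 0.0:
                raise InvalidParameterError(f"{name} must be > 0")

    def as_array(self) -> np.ndarray:
        """Theta in the package's canonical order (base TVs then exponents)."""
        return np.array(
            [
                self.theta_v1,
                self.theta_v2,
                self.theta_cl,
                self.theta_q,
                self.theta1,
                self.theta2,
                self.theta3,
                self.theta4,
            ],
            dtype=float,
        )


def typical_values(theta: ThetaVector, cov: CovariateRecord) -> IndividualParams:
    """Typical (population) PK parameters for a subject's covariates.

    V1 = theta_V1 * (ln WT / 2.3)^theta1
    V2 = theta_V2 * (WT / WT_median)^theta2
    CL = theta_CL * (WT / WT_median)^theta3 * (eGFR / eGFR_median)^theta4
    Q  = theta_Q
    """
    wt = float(cov.wt)
    egfr = float(cov.egfr)
    if wt <= 1.0:
        raise InvalidParameterError(
            f"WT={wt} kg gives ln WT <= 0; the log-weight V1 model is undefined"
        )
    if egfr <= 0.0:
        raise InvalidParameterError("eGFR must be > 0")
    v1 = theta.theta_v1 * (math.log(wt) / theta.lnwt_ref) ** theta.theta1
    v2 = theta.theta_v2 * (wt / theta.wt_median) ** theta.theta2
    cl = (
        theta.theta_cl
        * (wt / theta.wt_median) ** theta.theta3
        * (egfr / theta.egfr_median) ** theta.theta4
    )
    return IndividualParams(V1=v1, V2=v2, Q=theta.theta_q, CL=cl)


@dataclass(frozen=True)
class CandidateCLModel:
    """One of the four candidate maturation/allometric clearance models.

    I   -- simple allometry, exponent ``k1`` estimated, MF = 1
    II  -- fixed exponent 0.75 with sigmoid age maturation
           MF = 1 / (1 + (age / TM50)^(-gamma))
    III -- body-weight-dependent exponent
           k1 = k0 - kmax * WT^gamma / (k50^gamma + WT^gamma)
    IV  -- as III with age in place of WT
    """

    model_id: str
    k1: Optional[float] = None
    tm50: Optional[float] = None
    gamma: Optional[float] = None
    k0: Optional[float] = None
    kmax: Optional[float] = None
    k50: Optional[float] = None

    def __post_init__(self) -> None:
        if self.model_id not in {"I", "II", "III", "IV"}:
            raise ValueError(f"unknown model_id {self.model_id!r}")


def candidate_cl(
    model: CandidateCLModel,
    tv_cl: float,
    wt: float,
    age: float,
    wt_median: float = 10.0,
) -> float:
    """Clearance under one of the candidate maturation models.

    All share ``CL = TV(CL) * (WT / WT_median)^k1 * MF``; the models differ
    in how ``k1`` and the maturation fraction ``MF`` are formed.
    """
    if not (wt > 0.0 and age >= 0.0 and wt_median > 0.0):
        raise InvalidParameterError("wt, wt_median must be > 0 and age >= 0")
    mid = model.model_id
    if mid == "I":
        k1 = model.k1
        mf = 1.0
    elif mid == "II":
        k1 = 0.75
        if not model.tm50 > 0.0:
            raise InvalidParameterError("TM50 must be > 0")
        if age == 0.0:
            mf = 0.0 if model.gamma > 0 else 1.0
        else:
            mf = 1.0 / (1.0 + (age / model.tm50) ** (-model.gamma))
    elif mid == "III":
        g = model.gamma
        k1 = model.k0 - model.kmax * wt**g / (model.k50**g + wt**g)
        mf = 1.0
    else:  # IV
        g = model.gamma
        k1 = model.k0 - model.kmax * age**g / (model.k50**g + age**g)
        mf = 1.0
    return tv_cl * (wt / wt_median) ** k1 * mf


def apply_covariate_form(
    form: int,
    tv: float,
    theta: float,
    cov: float,
    cov_median: float | None = None,
) -> float:
    """Generic covariate inclusion forms for a single parameter.

    11: TV + theta * (COV / COV_median)
    12: TV + theta * (COV - COV_median)
    13: TV * (COV / COV_median)^theta
    14: TV * exp(theta)  when the categorical flag ``cov`` is set

    Additive forms can propose non-positive parameter values; those raise
    :class:`InvalidParameterError` so estimation rejects the proposal.
    """
    if form in (11, 12, 13):
        if cov_median is None or not cov_median > 0.0:
            raise InvalidParameterError("cov_median must be > 0 for continuous forms")
    if form == 11:
        value = tv + theta * (cov / cov_median)
    elif form == 12:
        value = tv + theta * (cov - cov_median)
    elif form == 13:
        if not cov > 0.0:
            raise InvalidParameterError("power form needs COV > 0")
        value = tv * (cov / cov_median) ** theta
    elif form == 14:
        value = tv * math.exp(theta) if cov else tv
    else:
        raise ValueError(f"unknown covariate form {form!r}")
    if value <= 0.0:
        raise InvalidParameterError(
            f"covariate form {form} proposed non-positive parameter {value!r}"
        )
    return value


def records_from_frame(frame: pd.DataFrame) -> list[CovariateRecord]:
    """Build :class:`CovariateRecord` objects from a cohort covariate table
    (columns AGE, SEX, WT, HT, SCR and optionally EGFR/BSA/...)."""
    out = []
    for _, row in frame.iterrows():
        out.append(
            CovariateRecord(
                age=float(row["AGE"]),
                sex=str(row["SEX"]),
                wt=float(row["WT"]),
                height=float(row["HT"]),
                scr=float(row["SCR"]),
                egfr=float(row["EGFR"]) if "EGFR" in row and pd.notna(row["EGFR"]) else None,
                bsa=float(row["BSA"]) if "BSA" in row and pd.notna(row["BSA"]) else None,
                bun=float(row["BUN"]) if "BUN" in row and pd.notna(row["BUN"]) else None,
                ua=float(row["UA"]) if "UA" in row and pd.notna(row["UA"]) else None,
                alt=float(row["ALT"]) if "ALT" in row and pd.notna(row["ALT"]) else None,
                ast=float(row["AST"]) if "AST" in row and pd.notna(row["AST"]) else None,
                tbil=float(row["TBIL"]) if "TBIL" in row and pd.notna(row["TBIL"]) else None,
            )
        )
    return out
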