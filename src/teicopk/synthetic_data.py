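"""Virtual cohorts and sparse concentration datasets.

The raw clinical dataset behind the model is not deposited, so every
analysis in this package runs on synthetic cohorts that reproduce its
statistical structure: 136 children, age median 1.25 y (0.17-9.42), weight
median 10 kg (3.5-38), height 52-145 cm, eGFR 30-280 ml/min/1.73m2 split
8/23/63/42 across the four renal strata, 1-3 sparse samples per child under
the clinical regimen (10 mg/kg q12h x3 loading, then 10 mg/kg qd).

Serum creatinine is back-solved from the stratum-assigned eGFR through the
Schwartz formula, which guarantees stratum membership and exact round-trip
consistency.  Age-weight-height dependence uses a simple log-linear growth
model with jitter anchored to the cohort medians, not external growth-chart
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import reference
from .covariates import RENAL_GROUPS, bsa_mosteller, inverse_schwartz_scr
from .data import PKDataset
from .dosing import PRE_DOSE_OFFSET, RegimenSpec, regimen_to_doses
from .estimation import ModelSpec, final_model
from .pk_core import PARAM_ORDER, simulate_profile, IndividualParams
from .popmodel import ResidualSpec, draw_observations

__all__ = [
    "CohortSpec",
    "StudyDesign",
    "generate_cohort",
    "sampling_rule",
    "generate_dataset",
]

#: default stratum mix (moderate, mild, normal, augmented)
DEFAULT_FRACTIONS = tuple(c / sum(reference.STRATUM_COUNTS) for c in reference.STRATUM_COUNTS)


@dataclass(frozen=True)
class CohortSpec:
    """Distributional recipe for a virtual cohort."""

    n_subjects: int = 136
    stratum_fractions: tuple[float, float, float, float] = DEFAULT_FRACTIONS
    age_median: float = 1.25
    age_log_sd: float = 0.77
    age_range: tuple[float, float] = (0.17, 9.42)
    wt_range: tuple[float, float] = (3.5, 38.0)
    wt_log_sd: float = 0.12
    height_range: tuple[float, float] = (52.0, 145.0)
    height_log_sd: float = 0.04
    egfr_max: float = 280.0
    male_fraction: float = 79.0 / 136.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if abs(sum(self.stratum_fractions) - 1.0) > 1e-9:
            raise ValueError("stratum fractions must sum to 1")


def _truncated_lognormal(rng, median, log_sd, lo, hi, n, max_rounds=1000):
    """Rejection-sample a truncated lognormal; errors out if the truncation
    window is infeasible."""
    out = np.empty(n)
    remaining = np.arange(n)
    for _ in range(max_rounds):
        draw = median * np.exp(log_sd * rng.standard_normal(remaining.size))
        ok = (draw >= lo) & (draw <= hi)
        out[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]
        if remaining.size == 0:
            return out
    raise RuntimeError("infeasible truncation bounds for cohort covariate sampling")


def _median_wt(age):
    """Median weight (kg) at a given age (y); anchored so age 1.25 -> 10 kg."""
    return 10.0 * ((age + 0.8) / 2.05) ** 0.9


def _median_height(age):
    """Median height (cm) at a given age (y); anchored so age 1.25 -> 80 cm."""
    return 80.0 * ((age + 0.6) / 1.85) ** 0.33


def generate_cohort(spec: CohortSpec, seed: Optional[int] = None) -> pd.DataFrame:
    """Draw a virtual cohort; deterministic for a given seed.

    Returns a covariate table with columns ID, AGE, SEX, WT, HT, BSA, SCR,
    EGFR, BUN, UA, ALT, AST, TBIL and the stratum label RENAL.
    """
    if seed is None:
        seed = spec.seed
    if seed is None:
        raise ValueError("an explicit seed is required")
    rng = np.random.default_rng(seed)
    n = spec.n_subjects

    age = _truncated_lognormal(rng, spec.age_median, spec.age_log_sd, *spec.age_range, n)
    wt = _truncated_lognormal(rng, 1.0, spec.wt_log_sd, 0.0, np.inf, n) * _median_wt(age)
    wt = np.clip(wt, *spec.wt_range)
    height = _truncated_lognormal(rng, 1.0, spec.height_log_sd, 0.0, np.inf, n) * _median_height(age)
    height = np.clip(height, *spec.height_range)

    stratum_idx = rng.choice(4, size=n, p=spec.stratum_fractions)
    lower = np.array([g.lower for g in RENAL_GROUPS])
    upper = np.array([min(g.upper, spec.egfr_max) for g in RENAL_GROUPS])
    egfr = rng.uniform(lower[stratum_idx], upper[stratum_idx])
    scr = np.array([inverse_schwartz_scr(h, e) for h, e in zip(height, egfr)])

    sex = np.where(rng.uniform(size=n) < spec.male_fraction, "M", "F")
    bsa = np.array([bsa_mosteller(h, w) for h, w in zip(height, wt)])

    # decoy laboratory covariates (lognormal around the cohort medians)
    bun = _truncated_lognormal(rng, 3.26, 0.45, 0.8, 10.1, n)
    ua = _truncated_lognormal(rng, 208.85, 0.40, 53.2, 588.0, n)
    alt = _truncated_lognormal(rng, 23.0, 0.80, 6.0, 1000.0, n)
    ast = _truncated_lognormal(rng, 50.5, 0.70, 14.0, 750.0, n)
    tbil = _truncated_lognormal(rng, 6.55, 0.60, 2.0, 150.6, n)

    return pd.DataFrame(
        {
            "ID": np.arange(n),
            "AGE": age,
            "SEX": sex,
            "WT": wt,
            "HT": height,
            "BSA": bsa,
            "SCR": scr,
            "EGFR": egfr,
            "BUN": bun,
            "UA": ua,
            "ALT": alt,
            "AST": ast,
            "TBIL": tbil,
            "RENAL": np.array([RENAL_GROUPS[i].label for i in stratum_idx]),
        }
    )


@dataclass(frozen=True)
class StudyDesign:
    """Dosing regimen plus the sparse sampling rule.

    Sampling times are a mixture over the steady-state window (doses after
    ``first_sampling_dose``): a pre-dose trough with probability ~1/3, an
    early post-infusion peak with probability ~0.15, otherwise a uniform
    time within a dosing interval.  The mixture matches the observed
    composition of the modelled dataset; explicit sampling times per draw
    can be forced for testing.
    """

    regimen: RegimenSpec = field(default_factory=RegimenSpec)  # clinical default 10/10
    trough_prob: float = 0.3355
    peak_prob: float = 0.1484
    peak_window: float = 0.5
    n_samples_probs: tuple[float, float, float] = (0.5, 0.3, 0.2)
    first_sampling_dose: int = 4

    def __post_init__(self) -> None:
        if self.trough_prob + self.peak_prob > 1.0:
            raise ValueError("mixture probabilities exceed 1")
        if abs(sum(self.n_samples_probs) - 1.0) > 1e-9:
            raise ValueError("n_samples_probs must sum to 1")


def sampling_rule(
    design: StudyDesign,
    rng: np.random.Generator,
    n_samples: Optional[int] = None,
    kinds: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Draw observation times (h) for one subject under the design.

    ``kinds`` forces the category of each draw ('trough' | 'peak' | 'ss')
    instead of sampling the mixture (used for calibration tests).
    """
    times, _ = design.regimen.schedule()
    eligible = np.arange(design.first_sampling_dose, len(times))
    if eligible.size == 0:
        raise ValueError("design has no doses in the steady-state sampling window")
    if n_samples is None:
        n_samples = int(rng.choice((1, 2, 3), p=design.n_samples_probs))
    if kinds is None:
        u = rng.uniform(size=n_samples)
        kinds = np.where(
            u < design.trough_prob,
            "trough",
            np.where(u < design.trough_prob + design.peak_prob, "peak", "ss"),
        )
    out = []
    duration = design.regimen.infusion_duration
    interval = design.regimen.maintenance_interval
    for kind in kinds:
        di = int(rng.choice(eligible))
        if kind == "trough":
            out.append(times[di] - PRE_DOSE_OFFSET)
        elif kind == "peak":
            out.append(times[di] + duration + rng.uniform(0.0, design.peak_window))
        else:  # steady-state window sample
            out.append(times[di] + rng.uniform(0.0, interval))
    return np.sort(np.asarray(out))


def generate_dataset(
    cohort: pd.DataFrame,
    design: StudyDesign,
    theta=None,
    omega_sd=None,
    residual: ResidualSpec | None = None,
    seed: int = 0,
    model: ModelSpec | None = None,
    sample_times: Optional[Sequence[np.ndarray]] = None,
    lloq: Optional[float] = reference.LLOQ,
) -> PKDataset:
    """Simulate a sparse event-record dataset for a cohort.

    Per subject: typical values from the covariate model, lognormal IIV,
    closed-form profile under the design's weight-based doses, observation
    times from the sampling rule (or ``sample_times`` when given), residual
    noise, then censoring below the quantification floor.  Subjects whose
    every observation is censored are dropped.
    """
    model = model or final_model()
    theta = np.asarray(theta if theta is not None else reference.REFERENCE_THETA, float)
    omega_sd = np.asarray(
        omega_sd if omega_sd is not None else reference.REFERENCE_OMEGA_SD, float
    )
    residual = residual or ResidualSpec(
        form="power", sigma=reference.REFERENCE_SIGMA, power=reference.REFERENCE_POWER
    )
    rng = np.random.default_rng(seed)

    cohort = cohort.reset_index(drop=True)
    tv = model.typical(theta, cohort)
    # omega entries follow model.eta_on; map them onto the (V1, V2, Q, CL) columns
    sd_cols = np.zeros(4)
    for i, name in enumerate(model.eta_on):
        sd_cols[PARAM_ORDER.index(name)] = omega_sd[i]
    eta = rng.standard_normal((len(cohort), 4)) * sd_cols
    params = tv * np.exp(eta)

    dose_rows, obs_rows, kept_cov = [], [], []
    new_isub = 0
    for i in range(len(cohort)):
        wt = float(cohort.at[i, "WT"])
        doses = regimen_to_doses(design.regimen, wt)
        times = (
            np.asarray(sample_times[i], dtype=float)
            if sample_times is not None
            else sampling_rule(design, rng)
        )
        p = IndividualParams(*params[i])
        ipred = simulate_profile(p, doses, times)
        if residual.sigma == 0.0 and residual.sigma2 == 0.0:
            y, keep = ipred.copy(), np.ones(len(times), dtype=bool)
            if lloq is not None:
                keep = y >= lloq
        else:
            y, keep = draw_observations(ipred, residual, rng, lloq=lloq)
        if not keep.any():
            continue  # all observations censored; drop the subject
        for d in doses:
            dose_rows.append((new_isub, d.start_time, d.amount, d.duration))
        for t, v in zip(times[keep], y[keep]):
            obs_rows.append((new_isub, float(t), float(v)))
        kept_cov.append(i)
        new_isub += 1

    covariates = cohort.iloc[kept_cov].reset_index(drop=True)
    covariates["ID"] = np.arange(len(covariates))
    return PKDataset(
        covariates=covariates,
        doses=pd.DataFrame(dose_rows, columns=["ISUB", "TIME", "AMT", "DUR"]),
        obs=pd.DataFrame(obs_rows, columns=["ISUB", "TIME", "DV"]),
    )
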