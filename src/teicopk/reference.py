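"""Reference parameter values of the pediatric teicoplanin population model.

These are the final-model estimates used as defaults for simulation, dosing
optimization and synthetic-data generation.  Theta order matches the
canonical layout used by :mod:`teicopk.estimation`: the four base typical
values (V1, V2, CL, Q) followed by the covariate exponents
(lnWT on V1, WT on V2, WT on CL, eGFR on CL).
"""

from __future__ import annotations

import numpy as np

#: reference covariate medians used to normalize the model
WT_MEDIAN = 10.0  # kg
EGFR_MEDIAN = 118.99  # ml/min/1.73m2
LNWT_REF = 2.3  # literal constant in the V1 log-weight term

THETA_NAMES = (
    "tv_V1",
    "tv_V2",
    "tv_CL",
    "tv_Q",
    "V1-lnWT",
    "V2-WT",
    "CL-WT",
    "CL-EGFR",
)

#: final-model fixed effects
REFERENCE_THETA = np.array([2.31, 16.19, 0.13, 0.23, 0.14, 0.19, 0.74, 0.60])

#: IIV SDs (sqrt omega^2) in eta order (V1, V2, CL, Q); reported as % * 100
REFERENCE_OMEGA_SD = np.array([1.0543, 0.1958, 0.4467, 0.4286])

#: power residual model, SD = sigma * IPRED^0.5
REFERENCE_SIGMA = 0.46
REFERENCE_POWER = 0.5

#: assay quantification floor (mg/L)
LLOQ = 2.0

#: therapeutic trough target window (mg/L)
TROUGH_WINDOW = (10.0, 30.0)

#: renal stratum composition of the modelled cohort
#: (moderate, mild, normal, augmented)
STRATUM_COUNTS = (8, 23, 63, 42)
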