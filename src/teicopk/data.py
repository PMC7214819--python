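"""Event-record dataset dialect and the in-memory dataset container.

The on-disk format is a single CSV (comma separated, UTF-8, dot decimal, one
header row) with one row per dose or observation event:

====== =====================================================================
column meaning
====== =====================================================================
ID     subject identifier (string or int)
TIME   event time, hours since the subject's first dose (>= 0)
EVID   1 for dose rows, 0 for observation rows
AMT    dose amount (mg); empty on observation rows
DUR    infusion duration (h); empty on observation rows
DV     observed concentration (mg/L); empty on dose rows
BLQ    1 if the observation is below the 2.0 mg/L quantification floor
AGE    years          SEX  'M'/'F'        WT  kg        HT   cm
BSA    m2 (optional)  SCR  umol/L         BUN mmol/L    UA   umol/L
EGFR   ml/min/1.73m2 (recomputed from HT/SCR when absent)
ALT    U/L            AST  U/L            TBIL umol/L   (all optional)
====== =====================================================================

Below-limit observations are flagged and excluded from estimation with a
logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .covariates import egfr_schwartz
from .reference import LLOQ

logger = logging.getLogger("teicopk")

__all__ = ["PKDataset", "read_dataset", "write_dataset", "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = ["ID", "TIME", "EVID", "AMT", "DUR", "DV", "AGE", "SEX", "WT", "HT", "SCR"]
COVARIATE_COLUMNS = [
    "AGE", "SEX", "WT", "HT", "BSA", "SCR", "BUN", "UA", "EGFR", "ALT", "AST", "TBIL",
]
OPTIONAL_COVARIATES = ["BSA", "BUN", "UA", "EGFR", "ALT", "AST", "TBIL"]


class DatasetError(ValueError):
    """Malformed event-record input."""


@dataclass
class PKDataset:
    """In-memory event-record dataset.

    ``covariates`` has one row per subject (columns ``ID`` plus the covariate
    columns); ``doses`` and ``obs`` reference subjects by the integer
    positional index ``ISUB`` into ``covariates``.
    """

    covariates: pd.DataFrame
    doses: pd.DataFrame  # ISUB, TIME, AMT, DUR
    obs: pd.DataFrame  # ISUB, TIME, DV
    n_blq: int = 0

    def __post_init__(self) -> None:
        self.covariates = self.covariates.reset_index(drop=True)
        self.doses = self.doses.sort_values(["ISUB", "TIME"], kind="mergesort").reset_index(drop=True)
        self.obs = self.obs.sort_values(["ISUB", "TIME"], kind="mergesort").reset_index(drop=True)
        n = len(self.covariates)
        for frame, label in ((self.doses, "dose"), (self.obs, "observation")):
            if len(frame) and (
                frame["ISUB"].min() < 0 or frame["ISUB"].max() >= n
            ):
                raise DatasetError(f"{label} rows reference unknown subjects")
        dose_counts = np.bincount(self.doses["ISUB"], minlength=n) if len(self.doses) else np.zeros(n)
        if (dose_counts == 0).any():
            missing = self.covariates["ID"].iloc[np.flatnonzero(dose_counts == 0)].tolist()
            raise DatasetError(f"subjects without any dose event: {missing}")

    @property
    def n_subjects(self) -> int:
        return len(self.covariates)

    @property
    def n_obs(self) -> int:
        return len(self.obs)

    def subset(self, subject_indices) -> "PKDataset":
        """New dataset from (possibly repeated) subject positional indices;
        used by the nonparametric bootstrap."""
        subject_indices = np.asarray(subject_indices, dtype=int)
        cov = self.covariates.iloc[subject_indices].reset_index(drop=True)
        cov["ID"] = np.arange(len(cov))
        dose_parts, obs_parts = [], []
        for new, old in enumerate(subject_indices):
            d = self.doses[self.doses["ISUB"] == old].copy()
            o = self.obs[self.obs["ISUB"] == old].copy()
            d["ISUB"] = new
            o["ISUB"] = new
            dose_parts.append(d)
            obs_parts.append(o)
        return PKDataset(
            covariates=cov,
            doses=pd.concat(dose_parts, ignore_index=True),
            obs=pd.concat(obs_parts, ignore_index=True),
        )

    def to_record_frame(self) -> pd.DataFrame:
        """Flatten to the on-disk event-record layout."""
        rows = []
        for isub in range(self.n_subjects):
            cov = self.covariates.iloc[isub]
            common = {c: cov.get(c, np.nan) for c in COVARIATE_COLUMNS}
            common["ID"] = cov["ID"]
            for _, d in self.doses[self.doses["ISUB"] == isub].iterrows():
                rows.append(
                    dict(common, TIME=d["TIME"], EVID=1, AMT=d["AMT"], DUR=d["DUR"], DV=np.nan, BLQ=0)
                )
            for _, o in self.obs[self.obs["ISUB"] == isub].iterrows():
                rows.append(
                    dict(common, TIME=o["TIME"], EVID=0, AMT=np.nan, DUR=np.nan, DV=o["DV"], BLQ=int(o["DV"] < LLOQ))
                )
        frame = pd.DataFrame(rows)
        order = ["ID", "TIME", "EVID", "AMT", "DUR", "DV", "BLQ"] + COVARIATE_COLUMNS
        return frame[order].sort_values(["ID", "TIME", "EVID"], kind="mergesort").reset_index(drop=True)


def read_dataset(path, lloq: float = LLOQ) -> PKDataset:
    """Parse an event-record CSV into a :class:`PKDataset`.

    Below-limit observations (``BLQ`` flag set or DV < ``lloq``) are excluded
    from the observation table with a logged count.  Raises
    :class:`DatasetError` with row numbers for structural problems.
    """
    frame = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise DatasetError(f"missing mandatory columns: {missing}")
    if (frame["TIME"] < 0).any():
        bad = frame.index[frame["TIME"] < 0].tolist()
        raise DatasetError(f"negative TIME at rows {bad}")
    if not frame["EVID"].isin((0, 1)).all():
        bad = frame.index[~frame["EVID"].isin((0, 1))].tolist()
        raise DatasetError(f"EVID must be 0 or 1; bad rows {bad}")

    ids = frame["ID"].drop_duplicates().tolist()
    id_to_isub = {v: i for i, v in enumerate(ids)}

    cov_rows = []
    for sid in ids:
        sub = frame[frame["ID"] == sid]
        row = {"ID": sid}
        for col in COVARIATE_COLUMNS:
            row[col] = sub[col].iloc[0] if col in sub.columns else np.nan
        if pd.isna(row.get("EGFR")):
            row["EGFR"] = egfr_schwartz(float(row["HT"]), float(row["SCR"]))
        cov_rows.append(row)
    covariates = pd.DataFrame(cov_rows)

    doses = frame[frame["EVID"] == 1].copy()
    obs = frame[frame["EVID"] == 0].copy()
    if doses["AMT"].isna().any() or doses["DUR"].isna().any():
        bad = doses.index[doses["AMT"].isna() | doses["DUR"].isna()].tolist()
        raise DatasetError(f"dose rows need AMT and DUR; bad rows {bad}")
    if obs["DV"].isna().any():
        bad = obs.index[obs["DV"].isna()].tolist()
        raise DatasetError(f"observation rows need DV; bad rows {bad}")

    first_dose = doses.groupby("ID")["TIME"].min()
    for row_idx, o in obs.iterrows():
        t0 = first_dose.get(o["ID"], np.inf)
        if o["TIME"] <= t0:
            raise DatasetError(
                f"observation before (or at) first dose for subject {o['ID']!r} at row {row_idx}"
            )

    blq_flag = obs["DV"] < lloq
    if "BLQ" in obs.columns:
        blq_flag = blq_flag | (obs["BLQ"].fillna(0).astype(int) == 1)
    n_blq = int(blq_flag.sum())
    if n_blq:
        logger.warning("excluded %d below-quantification observations (< %.1f mg/L)", n_blq, lloq)
    obs = obs[~blq_flag]

    doses_out = pd.DataFrame(
        {
            "ISUB": doses["ID"].map(id_to_isub).to_numpy(int),
            "TIME": doses["TIME"].to_numpy(float),
            "AMT": doses["AMT"].to_numpy(float),
            "DUR": doses["DUR"].to_numpy(float),
        }
    )
    obs_out = pd.DataFrame(
        {
            "ISUB": obs["ID"].map(id_to_isub).to_numpy(int),
            "TIME": obs["TIME"].to_numpy(float),
            "DV": obs["DV"].to_numpy(float),
        }
    )
    return PKDataset(covariates=covariates, doses=doses_out, obs=obs_out, n_blq=n_blq)


def write_dataset(dataset: PKDataset, path) -> None:
    """Write a dataset in the event-record CSV dialect."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    dataset.to_record_frame().to_csv(path, index=False)
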