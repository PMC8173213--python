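"""Cohort CSV input/output with row-level validation.

A cohort table carries one row per subject visit with the documented header:
``id, cohort, diagnosis, conversion_label, visit_month, age, sex, education,
apoe4, tiv, mmse, csf_abeta`` plus one ``vol_<region>`` column per panel
region.  Synthetic cohorts additionally carry hidden ground-truth columns
prefixed ``true_``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import BiomarkerPanel, DEFAULT_PANEL

MANDATORY_COLUMNS = ("id", "cohort", "diagnosis", "conversion_label", "visit_month",
                     "age", "sex", "education", "apoe4", "tiv", "mmse", "csf_abeta")

VALID_DIAGNOSES = {"CN", "MCI", "AD"}
VALID_CONVERSION = {"sMCI", "pMCI", "none"}


@dataclass
class RowError:
    row: int
    subject_id: str
    reason: str


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path, panel: BiomarkerPanel = DEFAULT_PANEL,
                collect_errors: bool = False):
    """Read and validate a cohort CSV.

    Missing mandatory columns raise immediately, naming the column.  Rows
    violating range invariants (non-positive volumes, MMSE outside 0..30,
    negative visit month, unknown diagnosis) are rejected and collected; set
    ``collect_errors`` to also receive the list of :class:`RowError`.
    """
    df = pd.read_csv(path)
    vol_cols = [f"vol_{r}" for r in panel.names]
    for col in list(MANDATORY_COLUMNS) + vol_cols:
        if col not in df.columns:
            raise ValueError(f"cohort file is missing mandatory column {col!r}")

    for col in vol_cols + ["age", "tiv", "mmse", "visit_month"]:
        if not np.issubdtype(df[col].dtype, np.number):
            converted = pd.to_numeric(df[col], errors="coerce")
            if converted.isna().sum() > df[col].isna().sum():
                raise ValueError(f"non-numeric values in column {col!r}")
            df[col] = converted

    errors: list[RowError] = []
    keep = np.ones(len(df), dtype=bool)
    vols = df[vol_cols].to_numpy(dtype=float)
    checks = [
        ((vols <= 0).any(axis=1) | np.isnan(vols).any(axis=1), "non-positive or missing volume"),
        (~df["mmse"].between(0, 30).to_numpy(), "MMSE outside [0, 30]"),
        ((df["visit_month"].to_numpy(dtype=float) < 0), "negative visit_month"),
        (~df["diagnosis"].isin(VALID_DIAGNOSES).to_numpy(), "unknown diagnosis"),
        (~df["conversion_label"].isin(VALID_CONVERSION).to_numpy(), "unknown conversion label"),
    ]
    for bad, reason in checks:
        for r in np.flatnonzero(bad & keep):
            errors.append(RowError(row=int(r), subject_id=str(df.iloc[r]["id"]), reason=reason))
        keep &= ~bad

    clean = df.loc[keep].reset_index(drop=True)
    if collect_errors:
        return clean, errors
    return clean
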