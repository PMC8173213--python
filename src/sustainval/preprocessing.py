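"""Volume-to-z-score preprocessing.

Raw regional volumes are corrected for age, sex, education, APOE-e4
carriership and total intracranial volume by multiple linear regression,
then converted to z-scores against the adjusted-volume distribution of the
amyloid-negative cognitively normal reference (CSF abeta1-42 > 192 pg/ml).
Atrophying regions score positive when smaller than the reference; the
ventricles score positive when larger.  CSF values measured on a different
assay are rescaled to the training distribution's mean and SD.

The correction is fitted separately per cohort; the z-scoring reference
always comes from the training cohort's amyloid-negative controls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import BiomarkerPanel, ATROPHY
from .synthetic import COVARIATES, ABETA_CUTOFF


def _volume_cols(panel: BiomarkerPanel) -> list[str]:
    return [f"vol_{r}" for r in panel.names]


def merge_hemispheres(df: pd.DataFrame, panel: BiomarkerPanel) -> pd.DataFrame:
    """Average left/right volume pairs; sum 3rd + lateral ventricles.

    Columns named ``vol_<region>_left``/``vol_<region>_right`` are averaged
    into ``vol_<region>``; ``vol_ventricles_3rd`` and
    ``vol_ventricles_lateral`` are summed into ``vol_ventricles``.  Columns
    already merged are passed through.
    """
    out = df.copy()
    for r in panel.names:
        col = f"vol_{r}"
        if col in out.columns:
            continue
        left, right = f"{col}_left", f"{col}_right"
        third, lateral = f"{col}_3rd", f"{col}_lateral"
        if left in out.columns and right in out.columns:
            out[col] = (out[left] + out[right]) / 2.0
            out = out.drop(columns=[left, right])
        elif third in out.columns and lateral in out.columns:
            out[col] = out[third] + out[lateral]
            out = out.drop(columns=[third, lateral])
        else:
            raise ValueError(f"no volume columns found for region {r!r}")
    return out


def select_amyloid_negative_controls(cohort: pd.DataFrame,
                                     cutoff: float = ABETA_CUTOFF) -> np.ndarray:
    """Ids of CN subjects with non-missing CSF abeta strictly above ``cutoff``."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    mask = (cohort["diagnosis"] == "CN") & cohort["csf_abeta"].notna() \
        & (cohort["csf_abeta"] > cutoff)
    ids = cohort.loc[mask, "id"].to_numpy()
    if len(ids) == 0:
        raise ValueError("no amyloid-negative CN subjects: reference unusable")
    return ids


@dataclass
class AdjustmentModel:
    """Per-region linear confound model and the covariate means it references."""

    regions: tuple[str, ...]
    covariates: tuple[str, ...]
    intercepts: np.ndarray            # (B,)
    coefficients: np.ndarray          # (B, n_cov)
    reference_means: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "regions": list(self.regions),
            "covariates": list(self.covariates),
            "intercepts": np.asarray(self.intercepts).tolist(),
            "coefficients": np.asarray(self.coefficients).tolist(),
            "reference_means": {k: float(v) for k, v in self.reference_means.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "AdjustmentModel":
        return cls(regions=tuple(d["regions"]), covariates=tuple(d["covariates"]),
                   intercepts=np.asarray(d["intercepts"]),
                   coefficients=np.asarray(d["coefficients"]),
                   reference_means=d["reference_means"])

    @classmethod
    def from_json(cls, path) -> "AdjustmentModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    """Raise naming the first covariate that adds no rank to the design."""
    full = np.linalg.matrix_rank(X)
    if full == X.shape[1]:
        return
    rank = 0
    for j in range(X.shape[1]):
        new = np.linalg.matrix_rank(X[:, : j + 1])
        if new == rank:
            raise ValueError(f"rank-deficient design: covariate {names[j]!r} "
                             "is collinear with the preceding columns")
        rank = new
    raise ValueError("rank-deficient design")  # pragma: no cover


def fit_covariate_adjustment(cohort: pd.DataFrame, panel: BiomarkerPanel,
                             covariates=COVARIATES,
                             reference_means: dict | None = None) -> AdjustmentModel:
    """Per-region OLS of raw volume on the covariates (complete cases only)."""
    covariates = tuple(covariates)
    vol_cols = _volume_cols(panel)
    data = cohort[list(covariates) + vol_cols].dropna()
    n_par = len(covariates) + 1
    if len(data) < max(6, n_par + 1):
        raise ValueError("too few complete-covariate subjects to fit the adjustment")

    Xc = data[list(covariates)].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(data)), Xc])
    _check_full_rank(X, ["intercept"] + list(covariates))
    Y = data[vol_cols].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)

    refs = reference_means or {c: float(data[c].mean()) for c in covariates}
    return AdjustmentModel(regions=panel.names, covariates=covariates,
                           intercepts=beta[0], coefficients=beta[1:].T,
                           reference_means={c: float(refs[c]) for c in covariates})


def apply_adjustment(model: AdjustmentModel, cohort: pd.DataFrame,
                     panel: BiomarkerPanel) -> tuple[pd.DataFrame, np.ndarray]:
    """Residualise volumes to the reference covariate values.

    adjusted = raw - sum_j coef_j * (covariate_j - reference_mean_j); a subject
    sitting exactly at the reference means is unchanged.  Rows with missing
    covariates are excluded and their ids returned as flagged.
    """
    if tuple(model.regions) != tuple(panel.names):
        raise ValueError("adjustment model regions do not match panel")
    covs = list(model.covariates)
    complete = cohort[covs].notna().all(axis=1)
    flagged = cohort.loc[~complete, "id"].to_numpy()
    rows = cohort.loc[complete]
    delta = rows[covs].to_numpy(dtype=float) - np.array(
        [model.reference_means[c] for c in covs])[None, :]
    raw = rows[_volume_cols(panel)].to_numpy(dtype=float)
    adjusted = raw - delta @ np.asarray(model.coefficients).T
    out = pd.DataFrame(adjusted, columns=_volume_cols(panel), index=rows.index)
    out.insert(0, "id", rows["id"].to_numpy())
    return out, flagged


@dataclass
class ControlStats:
    """Adjusted-volume mean/SD of the amyloid-negative CN reference."""

    regions: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    n_reference: int

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.n_reference < 2:
            raise ValueError("reference must contain at least 2 subjects")
        if (self.sd <= 0).any():
            raise ValueError("reference SD must be positive for every region")

    def to_dict(self) -> dict:
        return {"regions": list(self.regions), "mean": self.mean.tolist(),
                "sd": self.sd.tolist(), "n_reference": self.n_reference}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "ControlStats":
        return cls(regions=tuple(d["regions"]), mean=np.asarray(d["mean"]),
                   sd=np.asarray(d["sd"]), n_reference=d["n_reference"])

    @classmethod
    def from_json(cls, path) -> "ControlStats":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def compute_control_stats(adjusted: pd.DataFrame, reference_ids,
                          panel: BiomarkerPanel) -> ControlStats:
    ref = adjusted[adjusted["id"].isin(np.asarray(reference_ids))]
    if len(ref) < 2:
        raise ValueError("reference must contain at least 2 subjects")
    vals = ref[_volume_cols(panel)].to_numpy(dtype=float)
    return ControlStats(regions=panel.names, mean=vals.mean(axis=0),
                        sd=vals.std(axis=0, ddof=1), n_reference=len(ref))


def control_stats_from_ground_truth(gt) -> ControlStats:
    """Oracle reference stats taken from a synthetic generator's true parameters."""
    return ControlStats(regions=gt.panel.names, mean=gt.control_mean.copy(),
                        sd=gt.control_sd.copy(), n_reference=2)


def compute_zscores(adjusted: pd.DataFrame, stats: ControlStats,
                    panel: BiomarkerPanel) -> pd.DataFrame:
    """Directional z-scores: abnormality is positive for every region.

    Atrophy regions: z = (control mean - value) / control SD; expansion
    regions (ventricles): z = (value - control mean) / control SD.
    """
    if tuple(stats.regions) != tuple(panel.names):
        raise ValueError("control stats regions do not match panel")
    vals = adjusted[_volume_cols(panel)].to_numpy(dtype=float)
    signed = np.where(np.asarray(panel.directions) == ATROPHY,
                      stats.mean[None, :] - vals, vals - stats.mean[None, :])
    z = signed / stats.sd[None, :]
    out = pd.DataFrame(z, columns=[f"z_{r}" for r in panel.names], index=adjusted.index)
    out.insert(0, "id", adjusted["id"].to_numpy())
    return out


def zscore_matrix(zdf: pd.DataFrame, panel: BiomarkerPanel) -> np.ndarray:
    return zdf[[f"z_{r}" for r in panel.names]].to_numpy(dtype=float)


def rescale_csf(values, source_mean: float, source_sd: float,
                target_mean: float, target_sd: float):
    """Match a differently-assayed CSF distribution to the training scale.

    y = (x - source mean) / source SD * target SD + target mean; missing
    values stay missing.
    """
    if source_sd <= 0:
        raise ValueError("source SD must be positive")
    x = np.asarray(values, dtype=float)
    return (x - source_mean) / source_sd * target_sd + target_mean
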