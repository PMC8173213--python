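"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a multi-centre volumetric study of the Alzheimer's
continuum: a small number of atrophy-progression subtypes (piecewise-linear
z-score trajectories over 13 regions, ventricles expanding and all other
regions shrinking), diagnosis-dependent stage distributions, additive linear
covariate confounds on the raw volumes, MMSE declining with stage, a bimodal
CSF amyloid-beta distribution around the 192 pg/ml abnormality cut-off, and a
slow longitudinal stage drift (0.8 +/- 1.5 stages per 12 months).

Ground truth (subtype, stage, noise-free and realised z-scores) is carried in
``true_``-prefixed columns so every downstream stage can be checked against
it; real cohorts never have these columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .panel import BiomarkerPanel, DEFAULT_PANEL, Z_LEVELS
from .model import (
    EventSequence,
    SustainModel,
    MAX_SUBTYPES,
    expected_zscore_matrix,
)

DIAGNOSES = ("CN", "MCI", "AD")

#: Covariates confounding the raw volumes, in the order the correction uses.
COVARIATES = ("age", "sex", "education", "apoe4", "tiv")

#: Reference covariate values at which a subject's volumes are unconfounded.
COVARIATE_REFERENCE = {"age": 72.0, "sex": 0.5, "education": 14.0,
                       "apoe4": 0.45, "tiv": 1.45e6}

# Typical control-scale volumes (mm^3, hemispheres averaged; ventricles =
# 3rd + lateral) and their control SDs.  Values are round numbers in the
# range reported for elderly cognitively normal cohorts.
_CONTROL_MEANS = {
    "hippocampus": 3700.0, "fusiform": 9000.0, "entorhinal": 1900.0,
    "middle_temporal": 10500.0, "precuneus": 9500.0, "amygdala": 1500.0,
    "insula": 6500.0, "thalamus": 7000.0, "putamen": 4800.0,
    "caudate": 3400.0, "accumbens": 550.0, "pallidum": 1600.0,
    "ventricles": 30000.0,
}
_CONTROL_SD_FRACTION = {"ventricles": 0.40}  # others default to 0.10

# Onset stage and inter-level spacing (in latent event-time units) defining
# the three default progression patterns: (1) typical -- ventricles and
# medial-temporal structures early, ventricles last to full abnormality;
# (2) subcortical / hippocampal-sparing -- thalamus and pallidum early;
# (3) ventricles fully abnormal before atrophy starts elsewhere.
_DEFAULT_PATTERNS = [
    {
        "ventricles": (0.5, 9.0), "hippocampus": (1.0, 2.0), "entorhinal": (1.5, 2.0),
        "amygdala": (2.0, 2.5), "middle_temporal": (4.0, 3.0), "fusiform": (5.0, 3.0),
        "precuneus": (6.0, 3.0), "insula": (7.0, 3.0), "thalamus": (8.0, 3.0),
        "putamen": (8.5, 3.0), "caudate": (9.0, 3.0), "accumbens": (9.5, 3.0),
        "pallidum": (10.0, 3.0),
    },
    {
        "thalamus": (0.5, 2.5), "pallidum": (1.0, 2.5), "caudate": (2.0, 2.5),
        "putamen": (2.5, 2.5), "insula": (3.5, 3.0), "precuneus": (4.5, 3.0),
        "fusiform": (5.5, 3.0), "middle_temporal": (6.0, 3.0), "accumbens": (6.5, 3.0),
        "hippocampus": (7.0, 1.5), "amygdala": (7.5, 3.0), "entorhinal": (8.0, 3.0),
        "ventricles": (9.0, 4.0),
    },
    {
        "ventricles": (0.3, 0.5), "hippocampus": (5.0, 3.0), "entorhinal": (5.5, 3.0),
        "amygdala": (6.0, 3.0), "middle_temporal": (6.5, 3.0), "fusiform": (7.0, 3.0),
        "precuneus": (7.5, 3.0), "insula": (8.0, 3.0), "thalamus": (8.5, 3.0),
        "putamen": (9.0, 3.0), "caudate": (9.5, 3.0), "accumbens": (10.0, 3.0),
        "pallidum": (10.5, 3.0),
    },
]

_DEFAULT_FRACTIONS = {
    1: [1.0],
    2: [0.70, 0.30],
    3: [0.65, 0.30, 0.05],
    4: [0.55, 0.27, 0.13, 0.05],
    5: [0.50, 0.25, 0.12, 0.08, 0.05],
}

#: Baseline diagnosis mix (CN / MCI / AD), echoing a memory-clinic spectrum.
DIAGNOSIS_FRACTIONS = {"CN": 0.32, "MCI": 0.52, "AD": 0.16}

ABETA_CUTOFF = 192.0


def _sequence_from_pattern(pattern: dict, panel: BiomarkerPanel,
                           jitter: np.ndarray | None = None) -> EventSequence:
    """Order the 3*B events by latent time onset + level*spacing (+ jitter)."""
    t = np.empty((panel.n_biomarkers, len(Z_LEVELS)))
    for b, name in enumerate(panel.names):
        onset, spacing = pattern[name]
        t[b] = onset + spacing * np.arange(len(Z_LEVELS))
    if jitter is not None:
        t = t + jitter
    t = np.sort(t, axis=1)  # jitter must not break within-biomarker ordering
    order = np.argsort(t, axis=None, kind="stable")
    events = [(int(i // len(Z_LEVELS)), int(i % len(Z_LEVELS)) + 1) for i in order]
    return EventSequence(events, panel.n_biomarkers)


def _random_pattern(panel: BiomarkerPanel, rng: np.random.Generator) -> dict:
    onsets = rng.uniform(0.0, 10.0, size=panel.n_biomarkers)
    spacings = rng.uniform(1.5, 4.0, size=panel.n_biomarkers)
    return {name: (float(o), float(s))
            for name, o, s in zip(panel.names, onsets, spacings)}


@dataclass
class GroundTruth:
    """Generating parameters of a synthetic study population."""

    panel: BiomarkerPanel
    sequences: list[EventSequence]
    fractions: np.ndarray
    stage_dist: dict[str, np.ndarray]          # diagnosis -> pmf over stages 0..N
    covariate_effects: dict[str, np.ndarray]   # covariate -> per-region coefficient
    covariate_reference: dict[str, float]
    control_mean: np.ndarray
    control_sd: np.ndarray
    mmse_intercept: float = 29.0
    mmse_slope: float = 0.4                    # MMSE points lost per stage
    mmse_noise_sd: float = 1.2
    csf_params: dict = field(default_factory=lambda: {
        "negative_mean": 245.0, "negative_sd": 40.0,
        "positive_mean": 140.0, "positive_sd": 35.0,
    })
    drift_mean: float = 0.8                    # stages per 12 months
    drift_sd: float = 1.5

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        if not np.isclose(self.fractions.sum(), 1.0):
            raise ValueError("fractions must sum to 1")
        if self.drift_mean < 0:
            raise ValueError("drift_mean must be non-negative")
        n = self.panel.n_events
        for diag, pmf in self.stage_dist.items():
            pmf = np.asarray(pmf, dtype=float)
            if len(pmf) != n + 1 or not np.isclose(pmf.sum(), 1.0):
                raise ValueError(f"stage distribution for {diag} must be a pmf over 0..{n}")
            self.stage_dist[diag] = pmf
        self.control_mean = np.asarray(self.control_mean, dtype=float)
        self.control_sd = np.asarray(self.control_sd, dtype=float)

    @property
    def n_subtypes(self) -> int:
        return len(self.sequences)

    def as_model(self, sigma=1.0) -> SustainModel:
        """The generating parameters viewed as a fitted model (oracle assignments)."""
        return SustainModel(sequences=list(self.sequences), fractions=self.fractions.copy(),
                            sigma=sigma, panel=self.panel)

    def to_dict(self) -> dict:
        return {
            "panel": self.panel.to_dict(),
            "sequences": [[list(ev) for ev in s.events] for s in self.sequences],
            "fractions": self.fractions.tolist(),
            "stage_dist": {k: v.tolist() for k, v in self.stage_dist.items()},
            "covariate_effects": {k: np.asarray(v).tolist()
                                  for k, v in self.covariate_effects.items()},
            "covariate_reference": dict(self.covariate_reference),
            "control_mean": self.control_mean.tolist(),
            "control_sd": self.control_sd.tolist(),
            "mmse_intercept": self.mmse_intercept,
            "mmse_slope": self.mmse_slope,
            "mmse_noise_sd": self.mmse_noise_sd,
            "csf_params": dict(self.csf_params),
            "drift_mean": self.drift_mean,
            "drift_sd": self.drift_sd,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        panel = BiomarkerPanel.from_dict(d["panel"])
        return cls(
            panel=panel,
            sequences=[EventSequence([tuple(e) for e in s], panel.n_biomarkers)
                       for s in d["sequences"]],
            fractions=np.asarray(d["fractions"]),
            stage_dist={k: np.asarray(v) for k, v in d["stage_dist"].items()},
            covariate_effects={k: np.asarray(v) for k, v in d["covariate_effects"].items()},
            covariate_reference=d["covariate_reference"],
            control_mean=np.asarray(d["control_mean"]),
            control_sd=np.asarray(d["control_sd"]),
            mmse_intercept=d["mmse_intercept"],
            mmse_slope=d["mmse_slope"],
            mmse_noise_sd=d["mmse_noise_sd"],
            csf_params=d["csf_params"],
            drift_mean=d["drift_mean"],
            drift_sd=d["drift_sd"],
        )

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _default_stage_dists(n_events: int) -> dict[str, np.ndarray]:
    """Diagnosis-conditional stage pmfs on 0..N.

    CN: truncated geometric concentrated on the first few stages; MCI and AD:
    discretised normals centred mid-course and later, mirroring the ordering
    CN < MCI < AD of average stages without claiming exact values.
    """
    k = np.arange(n_events + 1, dtype=float)
    cn = 0.75 ** k
    mci = np.exp(-0.5 * ((k - 6.0) / 4.0) ** 2)
    ad = np.exp(-0.5 * ((k - 12.0) / 5.0) ** 2)
    return {"CN": cn / cn.sum(), "MCI": mci / mci.sum(), "AD": ad / ad.sum()}


def _default_effects(panel: BiomarkerPanel, mean: np.ndarray) -> dict[str, np.ndarray]:
    """Additive linear confound coefficients per region, scaled to region size."""
    tiv_ref = COVARIATE_REFERENCE["tiv"]
    return {
        "age": -0.004 * mean,                 # mm^3 per year
        "sex": 0.03 * mean,                   # male minus female offset
        "education": 0.0015 * mean,           # mm^3 per year of education
        "apoe4": -0.01 * mean,                # carrier offset
        "tiv": 0.3 * mean / tiv_ref,          # mm^3 per mm^3 of head size
    }


def make_ground_truth(n_subtypes: int = 3, panel: BiomarkerPanel = DEFAULT_PANEL,
                      seed: int = 0) -> GroundTruth:
    """Build generating parameters for ``n_subtypes`` mutually distinct progressions.

    For the default 13-region panel the first three subtypes follow curated
    atrophy patterns (typical, subcortical-early, ventricles-first); further
    subtypes, and all subtypes of non-default panels, use seeded random
    onset/spacing patterns.  Deterministic per seed.
    """
    if not 1 <= n_subtypes <= MAX_SUBTYPES:
        raise ValueError(f"n_subtypes must lie in [1, {MAX_SUBTYPES}]")
    if panel.n_biomarkers < 2:
        raise ValueError("panel must contain at least 2 biomarkers")
    rng = np.random.default_rng(seed)

    curated = _DEFAULT_PATTERNS if panel.names == DEFAULT_PANEL.names else []
    sequences: list[EventSequence] = []
    for c in range(n_subtypes):
        for _ in range(100):
            if c < len(curated):
                jitter = rng.normal(0.0, 0.05, size=(panel.n_biomarkers, len(Z_LEVELS)))
                seq = _sequence_from_pattern(curated[c], panel, jitter)
            else:
                seq = _sequence_from_pattern(_random_pattern(panel, rng), panel)
            if seq not in sequences:
                break
        else:  # pragma: no cover - 100 draws never collide in practice
            raise RuntimeError("could not generate distinct sequences")
        sequences.append(seq)

    if panel.names == DEFAULT_PANEL.names:
        mean = np.array([_CONTROL_MEANS[r] for r in panel.names])
        sd = np.array([_CONTROL_SD_FRACTION.get(r, 0.10) * _CONTROL_MEANS[r]
                       for r in panel.names])
    else:
        mean = np.linspace(3000.0, 10000.0, panel.n_biomarkers)
        sd = 0.10 * mean

    return GroundTruth(
        panel=panel,
        sequences=sequences,
        fractions=np.asarray(_DEFAULT_FRACTIONS[n_subtypes]),
        stage_dist=_default_stage_dists(panel.n_events),
        covariate_effects=_default_effects(panel, mean),
        covariate_reference=dict(COVARIATE_REFERENCE),
        control_mean=mean,
        control_sd=sd,
    )


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def sample_zscores(gt: GroundTruth, subtype: int, stage: int, noise_sd: float = 0.0,
                   seed: int | np.random.Generator = 0) -> np.ndarray:
    """One z-vector: the subtype's expected trajectory at ``stage`` plus Gaussian noise."""
    if not 0 <= subtype < gt.n_subtypes:
        raise IndexError(f"subtype index {subtype} out of range")
    n = gt.panel.n_events
    if not 0 <= stage <= n:
        raise ValueError(f"stage must lie in [0, {n}]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    expected = expected_zscore_matrix(gt.sequences[subtype])[stage]
    return expected + rng.normal(0.0, noise_sd, size=expected.shape) if noise_sd > 0 \
        else expected.copy()


@dataclass
class CohortConfig:
    """Study-condition knobs of :func:`generate_cohort`."""

    diagnosis_fractions: dict = field(default_factory=lambda: dict(DIAGNOSIS_FRACTIONS))
    noise_sd: float = 1.0
    csf_missing_rate: float = 0.0
    # pMCI labelling: an MCI subject progresses when its simulated future stage
    # (conversion_horizon_months ahead) crosses the threshold, with a
    # CSF-status-dependent probability of clinical conversion.
    conversion_horizon_months: float = 36.0
    conversion_stage_threshold: int = 10
    p_convert_csf_abnormal: float = 0.9
    p_convert_csf_normal: float = 0.25
    age_mean: float = 72.0
    age_sd: float = 7.0
    education_mean: float = 14.0
    education_sd: float = 3.0
    p_male: float = 0.5
    p_apoe4: float = 0.45
    tiv_mean: float = 1.45e6
    tiv_sd: float = 1.3e5

    def to_dict(self) -> dict:
        return asdict(self)


def _volume_columns(panel: BiomarkerPanel) -> list[str]:
    return [f"vol_{r}" for r in panel.names]


def cohort_columns(panel: BiomarkerPanel) -> list[str]:
    cols = ["id", "cohort", "diagnosis", "conversion_label", "visit_month",
            "age", "sex", "education", "apoe4", "tiv", "mmse", "csf_abeta"]
    cols += _volume_columns(panel)
    cols += ["true_subtype", "true_stage"] + [f"true_z_{r}" for r in panel.names]
    return cols


def _abnormal_csf_probability(stage: np.ndarray, n_events: int) -> np.ndarray:
    """P(amyloid-positive | stage): rises from ~0.3 at stage 0 to ~0.95 late."""
    return np.clip(0.30 + 0.05 * np.asarray(stage, dtype=float), 0.0, 0.95)


def _volumes_from_z(gt: GroundTruth, z: np.ndarray, covariates: pd.DataFrame) -> np.ndarray:
    """Raw volumes: control scale minus direction*z*SD plus additive confounds."""
    directions = np.asarray(gt.panel.directions, dtype=float)
    vol = gt.control_mean[None, :] - directions[None, :] * z * gt.control_sd[None, :]
    for cov in COVARIATES:
        coef = np.asarray(gt.covariate_effects[cov], dtype=float)
        delta = covariates[cov].to_numpy(dtype=float) - gt.covariate_reference[cov]
        vol = vol + delta[:, None] * coef[None, :]
    return vol


def _simulate_mmse(gt: GroundTruth, stage: np.ndarray, rng) -> np.ndarray:
    raw = gt.mmse_intercept - gt.mmse_slope * stage + rng.normal(0, gt.mmse_noise_sd, len(stage))
    return np.clip(np.round(raw), 0, 30).astype(int)


def _simulate_csf(gt: GroundTruth, abnormal: np.ndarray, rng) -> np.ndarray:
    p = gt.csf_params
    neg = rng.normal(p["negative_mean"], p["negative_sd"], len(abnormal))
    pos = rng.normal(p["positive_mean"], p["positive_sd"], len(abnormal))
    return np.where(abnormal, pos, neg)


def _assemble(gt, ids, cohort_label, visit_month, diagnosis, conversion, covs,
              subtype, stage, z, mmse, csf) -> pd.DataFrame:
    df = pd.DataFrame({
        "id": ids,
        "cohort": cohort_label,
        "diagnosis": diagnosis,
        "conversion_label": conversion,
        "visit_month": visit_month,
        "age": covs["age"].to_numpy(),
        "sex": covs["sex"].to_numpy(),
        "education": covs["education"].to_numpy(),
        "apoe4": covs["apoe4"].to_numpy(),
        "tiv": covs["tiv"].to_numpy(),
        "mmse": mmse,
        "csf_abeta": csf,
    })
    vol = _volumes_from_z(gt, z, covs)
    for j, col in enumerate(_volume_columns(gt.panel)):
        df[col] = vol[:, j]
    df["true_subtype"] = subtype
    df["true_stage"] = stage
    for j, r in enumerate(gt.panel.names):
        df[f"true_z_{r}"] = z[:, j]
    return df


def generate_cohort(gt: GroundTruth, n_subjects: int, config: CohortConfig | None = None,
                    seed: int = 0, cohort_label: str = "train") -> pd.DataFrame:
    """Sample a cross-sectional baseline cohort; deterministic per seed."""
    config = config or CohortConfig()
    if n_subjects < 0:
        raise ValueError("n_subjects must be non-negative")
    if n_subjects == 0:
        return pd.DataFrame(columns=cohort_columns(gt.panel))
    rng = np.random.default_rng(seed)
    n_events = gt.panel.n_events

    subtype = rng.choice(gt.n_subtypes, size=n_subjects, p=gt.fractions)
    diags = list(config.diagnosis_fractions)
    p_diag = np.asarray([config.diagnosis_fractions[d] for d in diags], dtype=float)
    diagnosis = np.asarray(diags)[rng.choice(len(diags), size=n_subjects, p=p_diag / p_diag.sum())]
    stage = np.empty(n_subjects, dtype=int)
    for d in diags:
        m = diagnosis == d
        stage[m] = rng.choice(n_events + 1, size=m.sum(), p=gt.stage_dist[d])

    expected = np.stack([expected_zscore_matrix(s) for s in gt.sequences])  # (C, N+1, B)
    z = expected[subtype, stage]
    if config.noise_sd > 0:
        z = z + rng.normal(0.0, config.noise_sd, size=z.shape)

    covs = pd.DataFrame({
        "age": rng.normal(config.age_mean, config.age_sd, n_subjects),
        "sex": (rng.random(n_subjects) < config.p_male).astype(int),
        "education": np.clip(rng.normal(config.education_mean, config.education_sd,
                                        n_subjects), 0, None),
        "apoe4": (rng.random(n_subjects) < config.p_apoe4).astype(int),
        "tiv": rng.normal(config.tiv_mean, config.tiv_sd, n_subjects),
    })

    mmse = _simulate_mmse(gt, stage, rng)
    csf_abnormal = rng.random(n_subjects) < _abnormal_csf_probability(stage, n_events)
    csf = _simulate_csf(gt, csf_abnormal, rng)
    if config.csf_missing_rate > 0:
        csf = np.where(rng.random(n_subjects) < config.csf_missing_rate, np.nan, csf)

    # longitudinal labels for MCI subjects (operational progression rule)
    conversion = np.full(n_subjects, "none", dtype=object)
    mci = diagnosis == "MCI"
    h = config.conversion_horizon_months / 12.0
    future = stage + np.clip(
        rng.normal(gt.drift_mean * h, gt.drift_sd * np.sqrt(h), n_subjects),
        0.0, None)
    p_conv = np.where(csf_abnormal, config.p_convert_csf_abnormal, config.p_convert_csf_normal)
    progresses = mci & (future >= config.conversion_stage_threshold) \
        & (rng.random(n_subjects) < p_conv)
    conversion[mci] = "sMCI"
    conversion[progresses] = "pMCI"

    ids = np.array([f"{cohort_label}_{i:05d}" for i in range(n_subjects)])
    return _assemble(gt, ids, cohort_label, 0.0, diagnosis, conversion, covs,
                     subtype, stage, z, mmse, csf)


def generate_crossed_cohort(gt: GroundTruth, n_profiles: int = 8, stages=None,
                            subtypes=None, noise_sd: float = 0.0, seed: int = 0,
                            cohort_label: str = "crossed") -> pd.DataFrame:
    """Cartesian (subtype, stage) x covariate-profile design.

    In this balanced design the centred covariates are exactly orthogonal to
    the disease signal in-sample, so the linear covariate correction can be
    estimated without finite-sample leakage; used to validate the
    preprocessing chain end to end.
    """
    rng = np.random.default_rng(seed)
    config = CohortConfig()
    n_events = gt.panel.n_events
    if stages is None:
        stages = np.arange(0, n_events + 1, 3)
    if subtypes is None:
        subtypes = np.arange(gt.n_subtypes)
    cells = [(c, k) for c in subtypes for k in stages]

    profiles = pd.DataFrame({
        "age": rng.normal(config.age_mean, config.age_sd, n_profiles),
        "sex": (rng.random(n_profiles) < config.p_male).astype(int),
        "education": np.clip(rng.normal(config.education_mean, config.education_sd,
                                        n_profiles), 0, None),
        "apoe4": (rng.random(n_profiles) < config.p_apoe4).astype(int),
        "tiv": rng.normal(config.tiv_mean, config.tiv_sd, n_profiles),
    })

    subtype = np.repeat([c for c, _ in cells], n_profiles)
    stage = np.repeat([k for _, k in cells], n_profiles)
    covs = pd.concat([profiles] * len(cells), ignore_index=True)

    expected = np.stack([expected_zscore_matrix(s) for s in gt.sequences])
    z = expected[subtype, stage]
    if noise_sd > 0:
        z = z + rng.normal(0.0, noise_sd, size=z.shape)

    n = len(subtype)
    diagnosis = np.where(stage <= 2, "CN", np.where(stage <= 9, "MCI", "AD"))
    mmse = _simulate_mmse(gt, stage, rng)
    csf_abnormal = rng.random(n) < _abnormal_csf_probability(stage, n_events)
    csf = _simulate_csf(gt, csf_abnormal, rng)
    ids = np.array([f"{cohort_label}_{i:05d}" for i in range(n)])
    return _assemble(gt, ids, cohort_label, 0.0, diagnosis,
                     np.full(n, "none", dtype=object), covs, subtype, stage, z, mmse, csf)


def is_synthetic(cohort: pd.DataFrame) -> bool:
    return "true_subtype" in cohort.columns and "true_stage" in cohort.columns


def advance_followup(cohort: pd.DataFrame, months: float, gt: GroundTruth,
                     seed: int = 0, noise_sd: float = 1.0) -> pd.DataFrame:
    """Follow-up visit rows: stages drift, subtype fixed, volumes regenerated.

    The per-subject stage increment is Normal(drift_mean * months/12,
    drift_sd * sqrt(months/12)); with the reported drift SD well above the
    mean, apparent stage regressions are part of the emulated measurement
    process, so increments are clipped only to the stage grid
    [-stage, N - stage].  Covariates and CSF are carried over.
    """
    if months < 0:
        raise ValueError("months must be non-negative")
    if not is_synthetic(cohort):
        raise ValueError("advance_followup requires a synthetic cohort with true_ columns")
    rng = np.random.default_rng(seed)
    n = len(cohort)
    n_events = gt.panel.n_events
    stage0 = cohort["true_stage"].to_numpy(dtype=int)
    subtype = cohort["true_subtype"].to_numpy(dtype=int)

    if months == 0:
        inc = np.zeros(n)
    else:
        h = months / 12.0
        inc = rng.normal(gt.drift_mean * h, gt.drift_sd * np.sqrt(h), n)
        inc = np.clip(inc, -stage0.astype(float), n_events - stage0)
    stage1 = np.clip(stage0 + np.round(inc).astype(int), 0, n_events)

    expected = np.stack([expected_zscore_matrix(s) for s in gt.sequences])
    z = expected[subtype, stage1]
    if noise_sd > 0:
        z = z + rng.normal(0.0, noise_sd, size=z.shape)

    covs = cohort[list(COVARIATES)].reset_index(drop=True)
    mmse = _simulate_mmse(gt, stage1, rng)
    out = _assemble(gt, cohort["id"].to_numpy(), cohort["cohort"].to_numpy(),
                    cohort["visit_month"].to_numpy(dtype=float) + months,
                    cohort["diagnosis"].to_numpy(),
                    cohort["conversion_label"].to_numpy(), covs,
                    subtype, stage1, z, mmse, cohort["csf_abeta"].to_numpy())
    return out
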