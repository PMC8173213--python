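"""Post-fit validation battery.

Covers the heuristic visual-rating subtype rules, longitudinal subtype
consistency, the stage-cognition (MMSE) regression, stable-vs-progressive
MCI conversion classification with logistic models, ROC/AUC, the DeLong test
for comparing AUCs across cohorts, and plain ANOVA/chi-square group tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit
import statsmodels.api as sm

from .model import Assignment

RATING_CATEGORIES = ("typical", "hippocampal-sparing", "limbic-predominant", "minimal")


@dataclass(frozen=True)
class RatingTriple:
    """Pre-thresholded visual atrophy ratings (abnormal yes/no)."""

    mta_abnormal: bool
    pa_abnormal: bool
    gcaf_abnormal: bool


def visual_rating_subtype(r: RatingTriple) -> str:
    """Heuristic atrophy subtype from MTA / PA / GCA-F abnormality.

    typical: abnormal MTA with abnormal PA and/or GCA-F; hippocampal-sparing:
    normal MTA with abnormal PA and/or GCA-F; limbic-predominant: abnormal MTA
    alone; minimal: all three normal.  Every triple maps to exactly one
    category.
    """
    posterior_or_frontal = r.pa_abnormal or r.gcaf_abnormal
    if r.mta_abnormal:
        return "typical" if posterior_or_frontal else "limbic-predominant"
    return "hippocampal-sparing" if posterior_or_frontal else "minimal"


# ---------------------------------------------------------------------------
# Longitudinal consistency
# ---------------------------------------------------------------------------

def subtype_consistency(a0: dict[str, Assignment], a1: dict[str, Assignment],
                        n_subtypes: int) -> tuple[float, np.ndarray]:
    """Fraction of matched subjects keeping their subtype, plus the CxC transition table.

    Subjects with an undefined subtype at either visit (stage 0 or N) are
    excluded, as the subtype is not identifiable there.
    """
    common = [i for i in a0 if i in a1 and a0[i].defined and a1[i].defined]
    if not common:
        raise ValueError("no overlapping subjects with defined subtypes")
    table = np.zeros((n_subtypes, n_subtypes), dtype=int)
    for i in common:
        table[a0[i].subtype, a1[i].subtype] += 1
    stable = float(np.trace(table)) / len(common)
    return stable, table


# ---------------------------------------------------------------------------
# Stage vs cognition
# ---------------------------------------------------------------------------

@dataclass
class StageCognitionFit:
    slope: float
    intercept: float
    r_squared: float
    n_stages: int
    per_stage_means: bool = True


def _fit_stage_mmse(stages: np.ndarray, mmse: np.ndarray,
                    per_stage_means: bool) -> StageCognitionFit:
    if per_stage_means:
        df = pd.DataFrame({"stage": stages, "mmse": mmse}).groupby("stage")["mmse"].mean()
        x, y = df.index.to_numpy(dtype=float), df.to_numpy(dtype=float)
    else:
        x, y = stages.astype(float), mmse.astype(float)
    if len(np.unique(x)) < 3:
        raise ValueError("at least 3 distinct stages required")
    res = sps.linregress(x, y)
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue ** 2)
    return StageCognitionFit(slope=float(res.slope), intercept=float(res.intercept),
                             r_squared=r2, n_stages=len(np.unique(x)),
                             per_stage_means=per_stage_means)


def stage_cognition_fit(assignments: dict[str, Assignment], mmse: dict[str, float],
                        per_subtype: bool = False, per_stage_means: bool = True):
    """OLS of MMSE on model stage (per-stage mean MMSE by default).

    Returns a :class:`StageCognitionFit`, or a dict subtype -> fit when
    ``per_subtype`` is set (undefined-subtype subjects are then excluded).
    """
    ids = [i for i in assignments if i in mmse]
    stages = np.array([assignments[i].stage for i in ids], dtype=float)
    scores = np.array([mmse[i] for i in ids], dtype=float)
    if not per_subtype:
        return _fit_stage_mmse(stages, scores, per_stage_means)
    out = {}
    subtypes = np.array([assignments[i].subtype if assignments[i].defined else -1
                         for i in ids])
    for c in sorted(set(subtypes[subtypes >= 0])):
        m = subtypes == c
        out[int(c)] = _fit_stage_mmse(stages[m], scores[m], per_stage_means)
    return out


# ---------------------------------------------------------------------------
# Conversion classification
# ---------------------------------------------------------------------------

FEATURE_NAMES = ("subtype", "stage", "mmse", "abeta")


def conversion_features(assignments: dict[str, Assignment], mmse: dict[str, float],
                        abeta: dict[str, float], spec: tuple[str, ...],
                        n_subtypes: int = 1) -> tuple[pd.DataFrame, int]:
    """Deterministic feature table for the logistic conversion model.

    Subtype enters as C-1 reference-coded indicators (subtype 0 is the
    reference).  Rows missing any required feature -- including an undefined
    subtype when ``subtype`` is requested -- are excluded; the count of
    excluded subjects is returned alongside the table.
    """
    spec = tuple(spec)
    if not spec:
        raise ValueError("feature spec must not be empty")
    unknown = set(spec) - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown features: {sorted(unknown)}")

    rows, excluded = {}, 0
    for i, a in assignments.items():
        row = {}
        ok = True
        if "subtype" in spec:
            if not a.defined:
                ok = False
            else:
                for c in range(1, n_subtypes):
                    row[f"subtype_{c}"] = 1.0 if a.subtype == c else 0.0
        if "stage" in spec:
            row["stage"] = float(a.stage)
        if "mmse" in spec:
            v = mmse.get(i)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                ok = False
            else:
                row["mmse"] = float(v)
        if "abeta" in spec:
            v = abeta.get(i)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                ok = False
            else:
                row["abeta"] = float(v)
        if ok:
            rows[i] = row
        else:
            excluded += 1

    cols = []
    if "subtype" in spec:
        cols += [f"subtype_{c}" for c in range(1, n_subtypes)]
    for name in ("stage", "mmse", "abeta"):
        if name in spec:
            cols.append(name)
    table = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    table.index.name = "id"
    return table, excluded


@dataclass
class LogisticModel:
    """Binomial GLM (logit link) fitted by IRLS."""

    feature_names: tuple[str, ...]
    intercept: float
    coefficients: np.ndarray
    converged: bool
    separation_warning: bool = False

    def decision_scores(self, features: pd.DataFrame) -> np.ndarray:
        X = features[list(self.feature_names)].to_numpy(dtype=float)
        return expit(self.intercept + X @ self.coefficients)


def fit_conversion_classifier(features: pd.DataFrame, labels) -> LogisticModel:
    """Maximum-likelihood logistic regression of pMCI (1) vs sMCI (0)."""
    y = np.asarray([1 if v in (1, "pMCI", True) else 0 for v in labels])
    if y.min() == y.max():
        raise ValueError("both classes (sMCI and pMCI) must be present")
    X = sm.add_constant(features.to_numpy(dtype=float), has_constant="add")
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            converged = bool(getattr(res, "converged", True))
        except Exception:
            # fall back to a ridge-stabilised fit and flag the separation
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(alpha=1e-6)
            converged, separation = False, True
        for w in caught:
            if "separat" in str(w.message).lower() or "overflow" in str(w.message).lower():
                separation = True
    params = np.asarray(res.params, dtype=float)
    if np.abs(params).max() > 1e3:
        separation = True
    return LogisticModel(feature_names=tuple(features.columns), intercept=float(params[0]),
                         coefficients=params[1:], converged=converged,
                         separation_warning=separation)


# ---------------------------------------------------------------------------
# ROC and the DeLong test
# ---------------------------------------------------------------------------

@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    scores: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)


def roc_curve(scores, labels) -> RocCurve:
    """ROC over all score thresholds; AUC equals the rank-sum (Mann-Whitney)
    concordance probability, ties counted half."""
    from sklearn import metrics

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray([1 if v in (1, "pMCI", True) else 0 for v in labels])
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    fpr, tpr, _ = metrics.roc_curve(labels, scores, drop_intermediate=False)
    auc = float(metrics.roc_auc_score(labels, scores))
    return RocCurve(fpr=fpr, tpr=tpr, auc=auc, scores=scores, labels=labels)


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _delong_auc_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance from placement values."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r, neg_r = _midrank(pos), _midrank(neg)
    # placement values: V10 (per positive), V01 (per negative)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    auc = float(v10.mean())
    var = float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)
    return auc, var


def delong_compare(roc_a: RocCurve, roc_b: RocCurve, paired: bool = False) -> dict:
    """Two-sided DeLong comparison of two AUCs.

    The unpaired variant (default) treats the two curves as coming from
    independent cohorts and sums their variances; the paired variant uses the
    placement-value covariance on matched subjects.
    """
    auc_a, var_a = _delong_auc_variance(roc_a.scores, roc_a.labels)
    auc_b, var_b = _delong_auc_variance(roc_b.scores, roc_b.labels)
    if paired:
        if len(roc_a.scores) != len(roc_b.scores) or \
                not np.array_equal(roc_a.labels, roc_b.labels):
            raise ValueError("paired comparison requires matched subjects and labels")
        labels = roc_a.labels
        m = int((labels == 1).sum())
        n = int((labels == 0).sum())
        v10 = np.empty((2, m))
        v01 = np.empty((2, n))
        for j, s in enumerate((roc_a.scores, roc_b.scores)):
            pos, neg = s[labels == 1], s[labels == 0]
            all_r = _midrank(np.concatenate([pos, neg]))
            v10[j] = (all_r[:m] - _midrank(pos)) / n
            v01[j] = 1.0 - (all_r[m:] - _midrank(neg)) / m
        s10 = np.cov(v10)
        s01 = np.cov(v01)
        var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
            + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    else:
        var = var_a + var_b
    delta = auc_a - auc_b
    if var <= 0:
        if abs(delta) < 1e-12:
            return {"auc_a": auc_a, "auc_b": auc_b, "delta": 0.0, "z": 0.0, "p_value": 1.0}
        raise ValueError("degenerate variance in DeLong comparison")
    z = delta / np.sqrt(var)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return {"auc_a": auc_a, "auc_b": auc_b, "delta": float(delta),
            "z": float(z), "p_value": p}


# ---------------------------------------------------------------------------
# Group tests
# ---------------------------------------------------------------------------

def group_difference_tests(data, groups=None) -> dict:
    """One-way ANOVA for continuous values with group labels, or Pearson
    chi-square (no continuity correction) for a contingency table."""
    if groups is None:
        table = np.asarray(data, dtype=float)
        if table.ndim != 2:
            raise ValueError("contingency table must be 2-dimensional")
        chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
        return {"test": "chi-square", "statistic": float(chi2), "p_value": float(p),
                "dof": int(dof)}
    values = np.asarray(data, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in pd.unique(groups)]
    if len(samples) < 2:
        raise ValueError("at least 2 groups required")
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group")
    if all(np.allclose(s, samples[0].mean()) for s in samples) and \
            all(np.allclose(s, s.mean()) for s in samples):
        return {"test": "anova", "statistic": 0.0, "p_value": 1.0}
    f, p = sps.f_oneway(*samples)
    return {"test": "anova", "statistic": float(f), "p_value": float(p)}
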