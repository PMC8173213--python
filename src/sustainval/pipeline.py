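"""End-to-end orchestration: simulate/load -> preprocess -> fit -> assign -> validate.

The pipeline mirrors the train-on-cohort-A / validate-on-cohort-B workflow:
the covariate correction is fitted separately per cohort, the z-scoring
reference always comes from the training cohort's amyloid-negative CN
subjects, the progression model is fitted on the training cohort only, and
both cohorts are subtyped/staged and pushed through the validation battery.

All randomness derives from ``RunConfig.seed``; rerunning with the same
config reproduces every numeric output bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import BiomarkerPanel, DEFAULT_PANEL
from .model import (MAX_SUBTYPES, SustainConfig, assign_cohort, cvic_select,
                    fit_sustain)
from . import preprocessing as prep
from . import synthetic as syn
from . import validation as val
from .io import read_cohort, write_cohort


@dataclass
class RunConfig:
    """Every option of a pipeline run; echoed verbatim into all outputs."""

    seed: int
    output_dir: str = "sustainval_output"
    # input cohorts: paths, or None to simulate
    train_path: str | None = None
    test_path: str | None = None
    train_followup_path: str | None = None
    test_followup_path: str | None = None
    # simulation options (used when paths are absent)
    simulate_n_train: int = 600
    simulate_n_test: int = 400
    simulate_n_subtypes: int = 3
    simulate_noise_sd: float = 1.0
    simulate_test_csf_missing: float = 0.5
    followup_months: float = 12.0
    # preprocessing
    abeta_cutoff: float = prep.ABETA_CUTOFF
    covariates: tuple[str, ...] = syn.COVARIATES
    # fitting
    n_subtypes: int | None = None        # fixed C; None -> CVIC selection
    max_subtypes: int = MAX_SUBTYPES
    cvic_folds: int = 5
    sigma: float = 1.0
    fit: SustainConfig = field(default_factory=SustainConfig)
    # validation
    feature_sets: tuple[tuple[str, ...], ...] = (
        ("subtype", "stage"),
        ("mmse", "abeta"),
        ("subtype", "stage", "mmse", "abeta"),
    )
    mmse_per_stage_means: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["covariates"] = list(self.covariates)
        d["feature_sets"] = [list(f) for f in self.feature_sets]
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _subseed(seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng([seed, *keys])


def _simulate_inputs(config: RunConfig, panel: BiomarkerPanel, log: list[str]):
    gt = syn.make_ground_truth(config.simulate_n_subtypes, panel, seed=config.seed)
    cc_train = syn.CohortConfig(noise_sd=config.simulate_noise_sd)
    cc_test = syn.CohortConfig(noise_sd=config.simulate_noise_sd,
                               csf_missing_rate=config.simulate_test_csf_missing)
    train = syn.generate_cohort(gt, config.simulate_n_train, cc_train,
                                seed=config.seed + 1, cohort_label="train")
    test = syn.generate_cohort(gt, config.simulate_n_test, cc_test,
                               seed=config.seed + 2, cohort_label="test")
    train_fu = syn.advance_followup(train, config.followup_months, gt,
                                    seed=config.seed + 3,
                                    noise_sd=config.simulate_noise_sd)
    test_fu = syn.advance_followup(test, config.followup_months, gt,
                                   seed=config.seed + 4,
                                   noise_sd=config.simulate_noise_sd)
    log.append(f"simulated cohorts: train n={len(train)}, test n={len(test)}, "
               f"{gt.n_subtypes} true subtypes")
    return gt, train, test, train_fu, test_fu


def _zscore_cohort(cohort, adj_model, stats, panel):
    adjusted, flagged = prep.apply_adjustment(adj_model, cohort, panel)
    z = prep.compute_zscores(adjusted, stats, panel)
    ids = z["id"].to_numpy()
    return ids, prep.zscore_matrix(z, panel), flagged


def _assignments_frame(ids, assignments, cohort_label, visit) -> pd.DataFrame:
    return pd.DataFrame({
        "id": ids,
        "cohort": cohort_label,
        "visit": visit,
        "subtype": [a.subtype if a.defined else -1 for a in assignments],
        "stage": [a.stage for a in assignments],
    })


def _conversion_analysis(model, ids, cohort, a_map, config, report_key, results):
    """Per-cohort conversion features, classifier scores held for ROC."""
    sub = cohort.set_index("id")
    keep = sub.loc[ids, "conversion_label"].isin(["sMCI", "pMCI"]).to_numpy()
    mmse = sub["mmse"].to_dict()
    abeta = sub["csf_abeta"].to_dict()
    out = {}
    for spec in config.feature_sets:
        feats, n_excl = val.conversion_features(
            {i: a_map[i] for i, k in zip(ids, keep) if k}, mmse, abeta,
            tuple(spec), n_subtypes=model.n_subtypes)
        if len(feats) == 0:
            out["+".join(spec)] = {"available": False, "excluded": int(n_excl)}
            continue
        y = sub.loc[feats.index, "conversion_label"].eq("pMCI").astype(int).to_numpy()
        out["+".join(spec)] = {"features": feats, "labels": y, "excluded": int(n_excl)}
    results[report_key] = out


def run_pipeline(config: RunConfig, panel: BiomarkerPanel = DEFAULT_PANEL) -> dict:
    """Execute the full workflow and write model/assignments/report artifacts."""
    if config.max_subtypes > MAX_SUBTYPES or \
            (config.n_subtypes is not None and config.n_subtypes > MAX_SUBTYPES):
        raise ValueError(f"at most {MAX_SUBTYPES} subtypes are supported")
    if config.seed is None:
        raise ValueError("config.seed is required")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"config hash {config.config_hash()}", f"seed {config.seed}"]

    # ---- stage 1: inputs -------------------------------------------------
    try:
        if config.train_path:
            train = read_cohort(config.train_path, panel)
            test = read_cohort(config.test_path, panel) if config.test_path else None
            train_fu = read_cohort(config.train_followup_path, panel) \
                if config.train_followup_path else None
            test_fu = read_cohort(config.test_followup_path, panel) \
                if config.test_followup_path else None
            gt = None
            log.append(f"loaded cohorts from {config.train_path}")
        else:
            gt, train, test, train_fu, test_fu = _simulate_inputs(config, panel, log)
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'inputs' failed: {e}") from e

    # ---- stage 2: preprocessing -----------------------------------------
    try:
        control_ids = prep.select_amyloid_negative_controls(train, config.abeta_cutoff)
        log.append(f"amyloid-negative CN reference: {len(control_ids)} subjects")
        adj_train = prep.fit_covariate_adjustment(train, panel, config.covariates)
        adjusted_train, _ = prep.apply_adjustment(adj_train, train, panel)
        stats = prep.compute_control_stats(adjusted_train, control_ids, panel)
        ids_tr, Z_tr, _ = _zscore_cohort(train, adj_train, stats, panel)
        cohorts = {"train": (ids_tr, Z_tr, train)}
        if train_fu is not None:
            cohorts["train_followup"] = (*_zscore_cohort(train_fu, adj_train, stats, panel)[:2],
                                         train_fu)
        if test is not None:
            adj_test = prep.fit_covariate_adjustment(test, panel, config.covariates)
            # CSF measured on a different assay: rescale to the training scale
            if test["csf_abeta"].notna().any():
                src = test["csf_abeta"].dropna()
                tgt = train["csf_abeta"].dropna()
                test = test.copy()
                test["csf_abeta"] = prep.rescale_csf(
                    test["csf_abeta"], src.mean(), src.std(ddof=1),
                    tgt.mean(), tgt.std(ddof=1))
                log.append("rescaled test-cohort CSF to the training distribution")
            else:
                log.append("test-cohort CSF entirely missing: rescaling skipped")
            cohorts["test"] = (*_zscore_cohort(test, adj_test, stats, panel)[:2], test)
            if test_fu is not None:
                cohorts["test_followup"] = (
                    *_zscore_cohort(test_fu, adj_test, stats, panel)[:2], test_fu)
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'preprocess' failed: {e}") from e

    # ---- stage 3: model fitting ------------------------------------------
    try:
        cvic_scores = None
        if config.n_subtypes is None:
            diag = train.set_index("id").loc[ids_tr, "diagnosis"].to_numpy()
            cvic_scores, n_sub = cvic_select(Z_tr, config.max_subtypes, config.cvic_folds,
                                             config.fit, config.sigma, config.seed,
                                             stratify_labels=diag)
            log.append(f"CVIC selected {n_sub} subtypes: "
                       + ", ".join(f"C={c}: {s:.1f}" for c, s in cvic_scores.items()))
        else:
            n_sub = config.n_subtypes
        model = fit_sustain(Z_tr, n_sub, config.fit, config.sigma,
                            _subseed(config.seed, 10), panel=panel)
        model.to_json(out_dir / "model.json")
        log.append(f"fitted {n_sub}-subtype model, log-likelihood {model.log_likelihood:.3f}")
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'fit' failed: {e}") from e

    # ---- stage 4: assignment ---------------------------------------------
    try:
        assignments = {}
        frames = []
        for key, (ids, Z, coh) in cohorts.items():
            a = assign_cohort(model, Z)
            assignments[key] = dict(zip(ids, a))
            visit = "followup" if key.endswith("followup") else "baseline"
            frames.append(_assignments_frame(ids, a, key.replace("_followup", ""), visit))
        assign_df = pd.concat(frames, ignore_index=True)
        assign_df.insert(0, "config_hash", config.config_hash())
        write_cohort(assign_df, out_dir / "assignments.csv")
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'assign' failed: {e}") from e

    # ---- stage 5: validation ----------------------------------------------
    try:
        report: dict = {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "n_subtypes": model.n_subtypes,
            "fractions": model.fractions.tolist(),
            "cvic_scores": cvic_scores,
            "mmse_regression_on": "per-stage means" if config.mmse_per_stage_means
                                  else "subject level",
        }
        for key in ("train", "test"):
            if key not in cohorts:
                report[key] = {"available": False}
                continue
            ids, Z, coh = cohorts[key]
            section: dict = {"available": True, "n": len(ids)}
            mmse = coh.set_index("id")["mmse"].to_dict()
            fit_all = val.stage_cognition_fit(assignments[key], mmse,
                                              per_stage_means=config.mmse_per_stage_means)
            section["mmse_stage"] = {"slope": fit_all.slope, "r_squared": fit_all.r_squared}
            per_sub = val.stage_cognition_fit(assignments[key], mmse, per_subtype=True,
                                              per_stage_means=config.mmse_per_stage_means)
            section["mmse_stage_per_subtype"] = {
                str(c): {"slope": f.slope, "r_squared": f.r_squared}
                for c, f in per_sub.items()}
            fu_key = f"{key}_followup"
            if fu_key in cohorts:
                stable, table = val.subtype_consistency(assignments[key],
                                                        assignments[fu_key],
                                                        model.n_subtypes)
                section["subtype_consistency"] = {"stable_fraction": stable,
                                                  "transitions": table.tolist()}
            report[key] = section

        # conversion classification: fit on training sMCI/pMCI, score both cohorts
        conv: dict = {}
        _conversion_analysis(model, cohorts["train"][0], cohorts["train"][2],
                             assignments["train"], config, "train", conv)
        if "test" in cohorts:
            _conversion_analysis(model, cohorts["test"][0], cohorts["test"][2],
                                 assignments["test"], config, "test", conv)
        report["conversion"] = {}
        for spec in config.feature_sets:
            name = "+".join(spec)
            tr = conv["train"].get(name, {})
            entry: dict = {}
            if "features" in tr and tr["labels"].min() != tr["labels"].max():
                clf = val.fit_conversion_classifier(tr["features"], tr["labels"])
                roc_tr = val.roc_curve(clf.decision_scores(tr["features"]), tr["labels"])
                entry["train_auc"] = roc_tr.auc
                entry["excluded_train"] = tr["excluded"]
                te = conv.get("test", {}).get(name, {})
                if "features" in te and te["labels"].min() != te["labels"].max():
                    roc_te = val.roc_curve(clf.decision_scores(te["features"]), te["labels"])
                    entry["test_auc"] = roc_te.auc
                    entry["excluded_test"] = te["excluded"]
                    entry["delong"] = val.delong_compare(roc_tr, roc_te, paired=False)
            else:
                entry["available"] = False
            report["conversion"][name] = entry

        # demographic group tests by subtype on the training cohort
        ids, _, coh = cohorts["train"]
        sub = np.array([assignments["train"][i].subtype
                        if assignments["train"][i].defined else -1 for i in ids])
        cohi = coh.set_index("id").loc[ids]
        defined = sub >= 0
        if len(np.unique(sub[defined])) >= 2:
            report["group_tests"] = {
                "age_by_subtype": val.group_difference_tests(
                    cohi["age"].to_numpy()[defined], sub[defined]),
                "sex_by_subtype": val.group_difference_tests(
                    pd.crosstab(sub[defined], cohi["sex"].to_numpy()[defined]).to_numpy()),
            }
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'validate' failed: {e}") from e

    report["log"] = log
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    with open(out_dir / "run.log", "w") as fh:
        fh.write("\n".join(log) + "\n")
    return report
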