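# sustainval

Subtype-and-stage inference for neurodegenerative disease progression from
cross-sectional regional brain volumes, with the full inter-cohort validation
battery: covariate-corrected z-scoring against amyloid-negative controls,
multi-subtype event-sequence fitting with cross-validated selection of the
number of subtypes, subject subtyping/staging, longitudinal consistency
checks, stage–cognition regression, and stable-vs-progressive MCI conversion
classification with ROC/DeLong comparison across cohorts.

## The problem

Event-based progression models treat a disease as an ordered sequence of
biomarker "events" and place each cross-sectional subject at a discrete stage
along that sequence. A single sequence cannot represent heterogeneous
diseases such as Alzheimer's, where distinct atrophy patterns (typical,
hippocampal-sparing, limbic-predominant) coexist. Subtype-and-stage inference
generalises the approach: each subtype c is its own sequence S_c of z-score
events — biomarker b reaching severity level z = 1, 2, 3 — and biomarker
trajectories rise piecewise-linearly through those levels, plateauing at
z = 3. With B = 13 regions the model has N = 3·13 = 39 stages. A subject with
z-scores **z** has marginal likelihood under subtype c

```
m_c(z) = (N+1)^-1 · Σ_k  Π_b  φ( z_b ; E(S_c, k, b), σ_b )
```

and the C-subtype model is the mixture Σ_c f_c · m_c(z). Subjects are
assigned to the maximising subtype and its most likely stage; stages 0 and N
are identical for every subtype, so the subtype is undefined there. The
number of subtypes (at most 5) is chosen by the cross-validation information
criterion — the summed held-out −2·log-likelihood across folds.

The package targets the transfer setting: fit on one cohort, assign and
validate on an independent one, with preprocessing (multiple-linear-regression
correction for age, sex, education, APOE-ε4 and TIV; z-scoring against the
training cohort's amyloid-negative CN subjects, CSF Aβ1-42 > 192 pg/ml; CSF
assay rescaling) handled per cohort as the transfer design requires. Because
the motivating cohorts are access-restricted, the package ships a seeded
synthetic-cohort generator reproducing their statistical structure (three
atrophy subtypes at 65/30/5% prevalence, diagnosis-dependent staging, MMSE
decline, bimodal CSF, 12-month stage drift of 0.8 ± 1.5), so every stage of
the pipeline is testable end to end. See `docs/methods.md` for the model,
defaults and limitations.

## Worked example

```python
import numpy as np
import sustainval as sv

gt = sv.make_ground_truth(3, seed=7)                      # 3 true subtypes
train = sv.generate_cohort(gt, 400, sv.CohortConfig(noise_sd=1.0),
                           seed=8, cohort_label="train")

controls = sv.select_amyloid_negative_controls(train)      # CN, Abeta > 192
adj = sv.fit_covariate_adjustment(train, gt.panel)
adjusted, _ = sv.apply_adjustment(adj, train, gt.panel)
stats = sv.compute_control_stats(adjusted, controls, gt.panel)
Z = sv.zscore_matrix(sv.compute_zscores(adjusted, stats, gt.panel), gt.panel)

cfg = sv.SustainConfig(n_restarts=4, n_splits=1, split_restarts=2, max_em_iter=20)
model = sv.fit_sustain(Z, 2, cfg, seed=9, panel=gt.panel)
print(np.round(model.fractions, 3), round(model.log_likelihood, 1))
print([(gt.panel.names[b], l) for b, l in model.sequences[0].events[:6]])
```

prints

```
[0.32 0.68] -8032.9
[('thalamus', 1), ('putamen', 1), ('pallidum', 1), ('caudate', 1), ('precuneus', 1), ('pallidum', 2)]
```

— the two fitted mixture fractions with the total data log-likelihood, and
the first events of the first fitted sequence: this subtype starts in the
thalamus, putamen and pallidum, i.e. the subcortical-early pattern, which the
fit estimates at 32% prevalence. Assigning subjects and regressing MMSE on
the assigned stages:

```python
amap = {i: a for i, a in zip(train["id"], sv.assign_cohort(model, Z))}
mmse = train.set_index("id")["mmse"].to_dict()
fit = sv.stage_cognition_fit(amap, mmse)
print("slope %.3f  R^2 %.3f" % (fit.slope, fit.r_squared))
```

```
slope -0.306  R^2 0.775
```

— per-stage mean MMSE falls by ~0.31 points per model stage, and stage
explains ~78% of its variance: the data-driven staging tracks cognition.

A command-line interface mirrors the stages
(`sustainval simulate | preprocess | fit | assign | validate | run-all`);
`run-all` executes the whole simulate → preprocess → fit/CVIC → assign →
validate workflow and writes `model.json`, `assignments.csv` and
`report.json`, bit-identically reproducible for a fixed seed and config.

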