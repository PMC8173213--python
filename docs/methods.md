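# Methods

## Model

`sustainval` implements subtype-and-stage inference for cross-sectional
biomarker data. A *panel* of B regional volumes (default B = 13: hippocampus,
fusiform, entorhinal, middle temporal, precuneus, amygdala, insula, thalamus,
putamen, caudate, accumbens, pallidum, ventricles) is scored as
control-referenced z-scores with abnormality always positive — atrophying
regions score `(mean_ctrl − x)/sd_ctrl`, the ventricles (which expand)
score `(x − mean_ctrl)/sd_ctrl`.

Each disease subtype c is an ordered sequence S_c of N = 3B events, where
event (b, l) is biomarker b reaching integer z-level l ∈ {1, 2, 3}. A subject
at stage k ∈ {0..N} has expected z-scores given by piecewise-linear
interpolation of each biomarker's trajectory through (0, 0), (p₁, 1), (p₂, 2),
(p₃, 3) — p₁ < p₂ < p₃ the 1-based positions of that biomarker's events in
S_c — with a plateau at z = 3 after the third event. Observations carry
independent Gaussian noise with per-biomarker SD σ_b (default 1, appropriate
for control-referenced z-scores; config-overridable). With a uniform stage
prior, the subject marginal under subtype c is

    m_c(z) = (N+1)⁻¹ Σ_k Π_b φ(z_b; E(S_c, k, b), σ_b)

and the data log-likelihood of a C-subtype model with mixture fractions f_c
is Σ_i log Σ_c f_c m_c(z_i).

Subjects are assigned to the subtype maximising f_c·m_c(z) (a flag disables
the fraction weighting) and then to the maximum-a-posteriori stage under that
subtype. At stage 0 and stage N every subtype predicts the same z profile, so
the subtype is reported as undefined there; ties break toward the lower stage
and the lower subtype index.

## Fitting

Sequences are optimised by greedy relocation hill-climbing: sweep the events
in seeded random order, evaluate every relocation of the current event that
preserves within-biomarker level ordering, take the best strictly-improving
position, and stop when a full sweep makes no move. De-novo fits use
multi-start (default 25 restarts from uniform random valid sequences). Candidate
scoring uses a single-precision matmul/logsumexp kernel (the subject-constant
terms drop out of the comparison); accepted models are always re-scored in
double precision. The improvement threshold is 10⁻⁶·(1+|objective|), above
single-precision round-off, so ties never cycle.

Multi-subtype models are fitted hierarchically: from the best (C−1)-model,
each cluster of ML-assigned subjects is bipartitioned — randomly
(`n_splits` times) and by worst model fit (the members with the lowest
log-marginals, at the fractions in `worst_fit_split_fractions`; these are the
likeliest carriers of an unmodelled, possibly rare, pattern) — each half is
refitted as a single subtype, and the resulting candidate C-models are
refined by EM: responsibilities r_ic ∝ f_c m_c(z_i), responsibility-weighted
greedy re-optimisation of each sequence (warm-started, so each M-step only
improves the EM surrogate), and fraction updates f_c = mean_i r_ic. The
candidate with the best final log-likelihood wins. Because M-steps never
decrease the weighted objective, the data log-likelihood is non-decreasing
across EM iterations up to the stopping tolerance.

An optional Metropolis pass over single-event relocations (default 10,000
iterations, thinning 10) summarises positional uncertainty of each event;
it is reporting-only and never feeds point estimates.

## Number of subtypes (CVIC)

The cross-validation information criterion is the sum over K folds (default
10, stratified by diagnosis when labels are present; 5 in the acceptance
battery) of −2× the held-out log-likelihood of the model fitted on the
fold's training part; the hierarchical fit is run once per fold and scored at
every C ≤ max (5, the model cap). Selection is the argmin. One caveat
observed in simulation: when orderings are weakly identified (very small
panels), a larger mixture can act as model averaging over orderings and win
a sliver of held-out likelihood without a true extra subtype;
`parsimony="1se"` (smallest C within one standard error of the minimum,
SE from paired per-fold differences) is available for that regime.

## Preprocessing

Raw volumes (hemispheres averaged, 3rd + lateral ventricles summed) are
corrected by per-region OLS on age, sex (0/1), education (years), APOE-ε4
carriership (0/1) and total intracranial volume (continuous, additive), then
re-centred at reference covariate values:
`adjusted = raw − Σ_j β_j (x_j − x̄_j)`. The regression is fitted on all
subjects of a cohort and separately per cohort; the z-scoring reference
(per-region mean/SD of adjusted volumes) always comes from the training
cohort's amyloid-negative CN subjects (CSF Aβ1-42 strictly above 192 pg/ml).
CSF values measured on a different assay are rescaled linearly to the
training distribution's mean and SD; when a cohort has no CSF at all,
rescaling is skipped and CSF-dependent analyses treat it as
missing-by-design. Rank-deficient designs are rejected naming the offending
covariate.

## Synthetic cohorts

The generator emulates the study's data structure so the whole chain is
testable without restricted data:

- Three default progression patterns built from per-region onset/spacing
  tables: (1) typical — ventricles, hippocampus, entorhinal and amygdala
  early, medial-temporal regions first to full abnormality, ventricles last;
  (2) subcortical-early / hippocampal-sparing — thalamus, pallidum, caudate,
  putamen first; (3) ventricles fully abnormal before atrophy starts
  elsewhere, with a weakly ordered remainder. Mixing fractions default to
  0.65/0.30/0.05. Extra subtypes (or non-default panels) use seeded random
  patterns, kept mutually distinct.
- Stage distributions by diagnosis: CN truncated-geometric (ratio 0.75,
  mass on stages 0–5), MCI discretised Normal(6, 4), AD discretised
  Normal(12, 5), all clipped to 0..N. These are stand-ins that reproduce the
  ordering and rough location of the diagnostic groups' average stages, not
  estimates. Diagnoses are drawn first (defaults CN/MCI/AD = 0.32/0.52/0.16)
  and stages conditionally on diagnosis.
- Volumes: `raw = mean_b − dir_b · z_b · sd_b + Σ_j γ_jb (x_j − x̄_j)` with
  round-number control means/SDs per region and additive linear confounds for
  all five covariates, TIV included. An additive TIV term (rather than a
  multiplicative head-size scale) is used deliberately: it is the confound
  structure the pipeline's multiple-linear-regression correction can remove
  exactly, which keeps the generator and the correction model consistent.
- MMSE = round(29 − 0.4·stage + ε), ε ~ N(0, 1.2), clipped to 0..30; a
  decline of 0.4 points/stage puts mid-course MCI near the high 20s and
  late-stage subjects in the low 20s.
- CSF Aβ1-42: two-component Gaussian mixture, amyloid-negative N(245, 40)
  and amyloid-positive N(135, 35) pg/ml around the 192 pg/ml cut-off, with
  P(positive | stage) = min(0.30 + 0.05·stage, 0.95) and an optional
  missingness mask (emulating cohorts where CSF was only partially
  collected).
- 12-month follow-up: per-subject stage increment Normal(0.8·m/12,
  1.5·√(m/12)) clipped to the stage grid [−stage, N−stage]. The drift SD is
  nearly twice the mean, so apparent stage regressions are part of the
  emulated measurement process; truncating increments at zero would inflate
  the mean drift to ~1.05 and was rejected. Subtype is fixed over time;
  z-scores, volumes and MMSE are regenerated at the new stage, covariates
  and CSF carried over.
- pMCI labelling (operational stand-in for a clinical conversion record): an
  MCI subject is pMCI when its simulated stage at a 36-month horizon crosses
  stage 10 and a CSF-status-dependent Bernoulli (0.9 abnormal / 0.25 normal)
  fires. This makes conversion predictable from stage, MMSE and Aβ jointly,
  which is the structure the classification analyses need.
- All randomness flows from one explicit seed; regeneration is bit-identical.

What the generator does *not* emulate: scanner/site effects, measurement
drift between visits beyond stage progression, non-linear covariate effects,
longitudinal attrition, diagnosis errors. Passing tests therefore demonstrate
correctness of the machinery under the stated generative assumptions, not
performance on real cohorts.

### The crossed design used by the preprocessing round-trip

With randomly drawn covariates, OLS coefficients absorb O(n^-1/2) chance
correlation between covariates and the disease signal, so hidden z-scores
cannot be recovered to numerical precision from a random design no matter how
large n is. `generate_crossed_cohort` therefore builds a balanced
(subtype, stage) × covariate-profile product in which the centred
covariate/signal cross-products are exactly zero; the correction then
recovers the generating coefficients to machine precision and, with the
generator's true control stats, the z-score chain returns the hidden
z-vectors exactly. The random-design cohorts are still what every other
analysis uses.

## Validation battery

- Visual-rating subtypes from MTA/PA/GCA-F abnormality flags: typical =
  MTA ∧ (PA ∨ GCA-F); hippocampal-sparing = ¬MTA ∧ (PA ∨ GCA-F);
  limbic-predominant = MTA ∧ ¬PA ∧ ¬GCA-F; minimal = none abnormal. The four
  rules partition all eight flag combinations.
- Longitudinal consistency: fraction of subjects keeping their subtype
  across visits plus the full transition table; undefined-subtype subjects
  (stage 0/N) excluded, since the subtype is not identifiable there.
- Stage–cognition: OLS of per-stage mean MMSE on stage (R² on subject-level
  points is available by flag and surfaced in the report metadata; per-stage
  means are the default because subject-level scatter at fixed stage mostly
  reflects the MMSE noise floor, not the progression signal).
- Conversion classification: logistic regression (statsmodels binomial GLM,
  IRLS) of pMCI vs sMCI on any subset of {subtype (reference-coded
  indicators, additive — no interaction), stage, MMSE, Aβ}; rows with
  missing required features are excluded and counted; perfect separation is
  flagged, with a ridge-stabilised fallback. The classifier is fitted on the
  training cohort and scored on both cohorts.
- ROC/AUC via threshold sweep; AUC equals the Mann-Whitney concordance
  probability with half-credit for ties. DeLong placement-value variance for
  AUC comparison; the unpaired variant (sum of the two variances) is the
  default because the compared curves come from disjoint cohorts; a paired
  variant with the placement covariance is provided for matched designs.
- Group tests: one-way ANOVA for continuous variables, Pearson chi-square
  without continuity correction for count tables. No multiple-testing
  correction is applied: the analyses are single planned comparisons at
  α = 0.05.

## Numerical and design choices

- Stage grid 0..N with uniform prior; N = 39 for the default panel.
- σ_b = 1 after z-scoring, overridable.
- Greedy optimiser defaults: 25 restarts, best-improvement single-event
  relocation, first-found tie-break; all seeded. EM tolerance 10⁻³ absolute
  log-likelihood change, max 50 iterations.
- Degenerate inputs: all-zero data leave the fitted ordering arbitrary (any
  valid sequence ties at stage 0; the stage posterior still peaks at 0);
  empty cohorts and one-class classification inputs are rejected with
  explicit errors.
- The acceptance battery runs CVIC at 5 folds with reduced restarts
  (3 restarts, 1 random + 1 worst-decile split per cluster, EM capped at 8
  iterations) and the recovery fit at 5 restarts/EM 40 — problem sizes chosen
  so the battery completes comfortably on a single core.

## Known limitations

- With subjects concentrated at early/mid stages (as the diagnosis-dependent
  stage distributions imply), late-sequence orderings are weakly identified:
  maximum-likelihood sequences fit noise in the tail, and Kendall-tau
  recovery of full 39-event orderings saturates around 0.75–0.85 even for
  well-populated subtypes; a 5%-prevalence subtype (~30 subjects at n = 600)
  is data-limited well below that. Recovery is therefore reported as the
  prevalence-weighted mean tau alongside per-subtype values.
- CVIC margins between adjacent C are small relative to fold-fit noise when
  one subtype is rare; selection of the exact C is stable only with adequate
  fitting effort per fold.
- The DeLong normal approximation is unreliable below a few tens of subjects
  per class, and AUC variance estimates inherit the usual small-sample
  caveats.
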