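# Methods

This note records the modelling conventions, parameter defaults and design
choices behind the package, and what the synthetic-data experiments do and
do not demonstrate.

## The affinity outcome

A patient–drug instance is scored from four utilisation quantities
extracted from the patient's admission record, capped at the first three
visits and two medication switches:

| raw quantity | definition | oriented component |
|---|---|---|
| inter-admission days | sum of (next admit − discharge) over consecutive capped visits | *t* = norm(x) |
| inter-switch days | mean gap between consecutive medication initiations, starting at the scored drug's first start | *s* = norm(x) |
| LOS days | total length of stay over capped visits | *ℓ* = 1 − norm(x) |
| visit count | number of capped visits | *v* = 1 − norm(x) |

with `norm` the min–max map fitted on **training-fold instances only**, the
base score the weighted mean (equal weights ¼ by default) and the final
score `A = clip(b − P, 0, 1)` with the switch-penalty map
{0: −0.05, 1: 0.10, 2: 0.20}.

Conventions the raw definitions pin down:

- **Switch counting.** A "switch" is an initiation of a *different* drug
  strictly after the scored drug's first start. Consecutive repeats of the
  same drug (continuation across admissions) are collapsed before
  counting. A visit with no prescription initiates the explicit NONE arm
  at admission time; a later drug start counts as a switch away from NONE.
- **Missing history.** A single-visit patient has no inter-admission gap
  and an unswitched instance no inter-switch time. The default policy
  scores the missing component 1.0 — no observed readmission / no switch
  is the best observable outcome proxy. The alternative
  (`single_visit_policy: renormalize`) drops the component and
  renormalises the remaining weights; it is exposed because the choice is
  genuinely open and materially affects the score distribution
  (single-visit patients are >half of a typical cohort).
- **Degenerate bounds.** When a training fold sees a single distinct value,
  the normalised value is the uninformative midpoint 0.5 rather than an
  arbitrary extreme — this matters in tiny external folds.
- **Out-of-range test values** clip into [0, 1]; extrapolation would let
  external cohorts push A outside its range.
- Sensitivity variants: `stability_heavy` re-weights to
  (0.35, 0.35, 0.15, 0.15); `burden_heavy` mirrors to
  (0.15, 0.15, 0.35, 0.35) and halves all penalties. The exact numbers are
  configuration values — any weighting with w_t = w_s > w_ℓ = w_v
  satisfies the stability-heavy definition — and can be overridden with a
  custom scheme block in the YAML config.

## Similarity engines

All engines operate per visit index, on a feature space fitted exclusively
on that visit's training consultations: one-hot encoding for categoricals
(unseen levels at transform time encode as an all-zero block, so external
dialects degrade gracefully instead of crashing) and z-standardisation for
numerics. Defaults:

- ε = 1e-9 in the Euclidean-to-similarity conversion 1/(1 + d + ε).
- Cosine values can dip below 0 after standardisation; they are clipped at
  0 so neighbour weights stay non-negative.
- RBF bandwidth γ = 1/n_encoded_features unless configured.
- ReliefF uses 10 neighbours per class, Manhattan distance on
  range-scaled features; scores are floored at 0 and rescaled to mean 1,
  then aggregated per original feature (summing a categorical's one-hot
  columns) to weight the Gower coefficient, which itself runs on the raw
  mixed-type records with training-fold numeric ranges.
- NCA: scikit-learn's NeighborhoodComponentsAnalysis, max 200 iterations,
  output dimension = input dimension, fixed seed; similarity is then the
  Euclidean conversion in the mapped space.
- ReliefF/NCA binarise training outcomes at affinity > 0.5. A degenerate
  fold whose labels are single-class makes the direct functions raise; the
  engine wrapper instead falls back to uniform Gower weights / the
  identity map with a warning, so a cross-validation run survives small
  inner folds. ReliefF weights all features; an optional top-m selection
  is available but off by default, since the attribute-weighting reading
  is the conservative one.

## Neighbourhood prediction and ranking

For a test consultation at visit v and arm d, the neighbourhood is
**per-drug**: the K most similar *visit-v training consultations* whose
patients have an observed affinity for d. (Per-drug neighbourhoods use the
sparse patient×drug matrix maximally; a global-then-filter neighbourhood
would starve rare arms.) The prediction is the similarity-weighted mean
Σ sim·A / Σ sim (an unweighted mean is available via config, and is also
the automatic fallback when every retained similarity is 0). Fewer than K
neighbours ⇒ use all; none ⇒ fall back to the arm's training-mean
affinity, then the global training mean — each prediction carries a
fallback flag so cold-arm coverage is auditable. Tied similarities are
broken by patient id, which makes predictions invariant to training-pool
row order; tied predictions rank by larger neighbour support, then
lexicographic arm name, so top-3 lists are bit-reproducible. The query's
own patient is always masked out of the pool.

## Evaluation harness

- **Fold plan.** Patients (never consultations) are shuffled by a seeded
  generator and split into 5 outer folds; each outer training set is
  re-split into 5 inner folds. A patient's consultations never straddle
  any split.
- **K selection** evaluates K ∈ {5, 10, …, 60} on each inner fold —
  predictions for the consultation's own prescribed drug, RMSE against
  observed affinities computed with inner-training bounds — and takes the
  argmin of the mean, ties toward smaller K. One neighbour sort is shared
  across the whole grid, which keeps the nested loop cheap.
- **Visit discipline.** A visit-1 query uses only other patients' data;
  visit-2/3 queries additionally carry the patient's own prior-visit
  fields inside the feature vector. Feature schemas are per-visit
  (4 / 8 / 12 fields), so neighbour pools are visit-stratified. The exact
  schema is inferred from the available predictors and kept configurable;
  comorbidity count is treated as per-visit (taken at the current
  admission as a baseline field).
- **Metrics.** RMSE on the prescribed drug's affinity; MAP@3 with
  relevant = arms the patient received (any capped visit) whose observed
  affinity exceeds 0.5 — consultations with an empty relevant set are
  skipped and counted, since average precision is undefined there;
  overlap/coverage as exact complements. Reports give mean ± sd over
  outer folds, overall and per visit, with both consultation and
  patient–drug-pair counts (the two possible "sample" readings).
- **Disagreement analysis.** On visit-1 consultations whose actual therapy
  is outside the top 3: paired differences d_i = predicted affinity of the
  model's top arm − observed affinity of the clinician's choice; paired t
  with n−1 df (two-sided p), Cohen's d = mean(d)/sd(d). A negative mean
  means clinicians outperformed the model's expectation.
- **External validation** applies a frozen model — feature spaces, bounds,
  similarity fit and K — to a second cohort with no re-tuning. Affinity
  bounds default to the development fold's (configurable), matching the
  train-only convention.
- **Leakage audit.** Each fold records its train/test patient sets'
  intersection (must be empty), the provenance tag of the normalisation
  bounds, and a count of non-null future-visit feature fields among test
  rows (must be 0). The audit is written as `leakage_audit.json`.
- Seeds default to 42 and feed every random choice; a re-run with the same
  config is byte-identical.

## Synthetic cohort generator

The generator emits raw `patients/visits/prescriptions` tables whose
marginals match the development-cohort profile it emulates: n = 1152, age
truncated-normal 27.9 ± 6.4 on [18, 40], 65.8% male, ethnicity
44.4/39.6/8.1/7.9%, visit counts 57.3/21.8/20.9%, log-normal LOS targeting
mean 6.6 / sd 10.5 days, and the printed drug-prevalence profile
renormalised to per-visit draws (the reported prevalences are per-patient
and exceed 1 summed; the residual "others" mass is split uniformly over
the ten unnamed antipsychotics). `validate_marginals` z-tests every
marginal (|z| ≤ 4 passes); the age check uses the truncated-normal
expectation, since the [18, 40] window shifts the raw mean by ~+0.37y.

The planted structure works entirely through the raw records:

- Each patient gets a **latent subgroup** from their demographics
  (gender × age side of the mean, 10% random flips) so feature similarity
  implies subgroup similarity; per-visit comorbidity counts are Poisson
  with a subgroup-dependent mean, giving the numeric block signal too.
- A subgroup×arm **response level** r = 0.5 ± 0.35·effect_size
  (alternating by subgroup-plus-arm-index parity, so the
  prevalence-weighted mean response stays ≈0.5 and subgroups of equal
  parity share a response profile while differing in feature space).
- Response drives the raw outcomes: LOS is log-normal with mean scaled by
  1 + 1.2·(0.5 − r) at constant coefficient of variation (stays truncated
  at 120 days); within-admission switch probability is
  0.22 + 0.9·(0.5 − r); readmission gaps are gamma with mean
  30 + 150·r days.
- Two realism couplings keep the marginals exact while making outcomes
  learnable: the visit-count *multiset* is drawn from the marginal and
  then allocated to patients by noisy expected-response rank (poor
  responders accumulate admissions), and prescriptions are tilted — with
  probability 0.35 the drawn drug is restricted to the patient's
  subgroup-appropriate arms. The tilt operates within antipsychotics
  only; the medicated/unmedicated split follows the NONE prevalence
  exactly. With `effect_size = 0` the response matrix is flat and every
  coupling degenerates to noise.
- `truth.json` (subgroups, response matrix) is a side channel for tests
  only; nothing in the pipeline reads it.

What passing the planted-recovery check shows: the full pipeline — raw
tables → cleaning → affinity scoring → per-visit similarity → K-NN
ranking — can recover a feature-linked response structure from admission
records alone, beating a 200-replicate label-permutation null on visit-1
MAP@3 and the predict-the-mean baseline on RMSE, and shows no such
separation when the structure is absent. What it does **not** show:
performance levels on real EHR data. The generator's clinician is only
mildly informed (tilt 0.35), its features are far coarser than real
records, prescriptions within a subgroup are exchangeable, and visit-level
confounding (severity, comorbidity-specific prescribing) is absent — so
absolute RMSE/MAP@3 values here are not comparable to values reported on
hospital datasets, and the disagreement analysis can come out with either
sign.

## Problem sizes and numerical choices

Test and reproduction runs are deliberately desk-scale: the leakage-audit
cross-validation uses a 200-patient cohort, CLI-determinism runs 100
patients, the recovery analysis 800 patients with 200 permutation
replicates, and the acceptance script's nested CV 300 patients — all
single-CPU, minutes total. Tolerances: affinity and neighbourhood
predictions are checked against independent oracles at 1e-12, similarity
formulas at 1e-9 (the Euclidean self-similarity is 1/(1+ε), not 1).
Floating-point ties in similarity are resolved by patient id before any
averaging, and all sorts are stable, which is what makes whole-pipeline
re-runs byte-identical.

## Known limitations

- The affinity score is a utilisation proxy, not a clinical outcome; no
  dosage, formulation (LAI vs oral), side-effect or patient-reported
  information enters the model.
- Collaborative filtering estimates correlations in observed outcomes,
  not causal treatment effects; treatment-selection bias in the input
  records propagates to recommendations.
- The ICD-9 mapping table covers the 295.x family only; other psychiatric
  codes raise and their patients are excluded with a logged reason.
- Later-visit strata are small in any cohort with this visit distribution;
  their metrics are noisy and MAP@3 there is frequently 0 because few
  later-visit patients have any received arm above the 0.5 threshold.
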