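# sczrec

Similarity-based antipsychotic treatment recommendation for
schizophrenia-spectrum hospital inpatients, built as a tested, reusable
library plus CLI. It is aimed at methods researchers in clinical decision
support who want to experiment with collaborative-filtering medication
recommenders on EHR-style admission data — including people *without*
access to credentialed hospital databases: a synthetic cohort generator
with a planted drug-response structure makes the entire pipeline runnable
and testable from scratch.

## The model

Every (patient, drug) instance receives a composite **affinity score**
A ∈ [0, 1] built from routine utilisation signals, each min–max normalised
against training-fold bounds and oriented so larger = better:

- *t* — time between admissions (longer gaps → fewer relapses)
- *s* — time between medication switches (longer → greater stability)
- *ℓ* — 1 − norm(length of stay)
- *v* — 1 − norm(number of visits)

```
b = ¼ (t + s + ℓ + v)          A = clip(b − P, 0, 1)
P = −0.05 (no switch, a bonus) | 0.10 (first switch) | 0.20 (second switch)
```

Computation is capped at three visits and two switches. Two sensitivity
variants re-weight the components (stability-heavy; patient-burden-heavy
with halved penalties).

Unseen affinities are predicted by K-nearest-neighbour user-based
collaborative filtering under five similarity engines: cosine and
Euclidean (similarity = 1/(1 + d + ε), ε = 1e-9) on the encoded feature
matrix, Gower similarity with ReliefF attribute weights (DR-RBA), a
Gaussian RBF kernel (DR-RBF), and Euclidean similarity in an NCA-learned
space (DR-NCA). Ranked top-3 lists over 16 treatment arms (15
antipsychotics plus explicit "no medication") are scored with RMSE, MAP@3
(relevant = received arms with affinity > 0.5), overlap and coverage.

Evaluation is leakage-proof by construction: nested patient-grouped
5×5-fold cross-validation selects the neighbourhood size K ∈ {5, …, 60} by
inner-fold RMSE; preprocessing, normalisation bounds and similarity fits
are training-fold-only; and each visit-v prediction uses only information
available at that admission (visit 1: other patients only; visits 2–3:
plus the patient's own earlier visits). An audit log records the evidence.

This is decision-support tooling, not a prescribing system: outputs are
ranked suggestions with neighbour support, never clinical directives.

## Worked example

```bash
# 1. simulate a 300-patient cohort (realistic marginals + planted structure)
printf 'n_patients: 300\nseed: 1\n' > spec.yaml
sczrec simulate --spec spec.yaml --out data/

# 2. nested cross-validation with the CF-cosine engine
cat > cfg.yaml <<EOF
cohort:
  patients: data/patients.csv
  visits: data/visits.csv
  prescriptions: data/prescriptions.csv
method: CF_COSINE
seed: 1
output_dir: run
EOF
sczrec evaluate --config cfg.yaml

# 3. model-vs-clinician disagreement on visit-1 consultations
sczrec disagreement --run run
```

This prints (abridged):

```
wrote 300 patients, 481 visits to data/ (marginals ok, worst |z| = 2.22)
   method stratum  best_K_mean  rmse_mean  map3_mean  overlap_mean  avg_consultations
CF_COSINE overall         18.0   0.287074   0.050234      0.120931               96.2
CF_COSINE visit_1         18.0   0.312872   0.076432      0.190000               60.0
CF_COSINE visit_2         18.0   0.230059   0.000000      0.008000               24.8
CF_COSINE visit_3         18.0   0.246274   0.000000      0.000000               11.4
 n_cases  mean_difference  t_statistic      p_value  cohens_d
     243         0.347148    15.525278 3.460153e-38  0.995947
```

Reading it: on this small synthetic cohort the tuned neighbourhood size
averaged 18 across outer folds; affinity prediction error (RMSE) is ~0.29
overall; recommendation quality (MAP@3, overlap) is concentrated on first
visits and collapses for later visits — the same qualitative pattern seen
on real admission data, because later-visit consultations are scarce. The
disagreement block shows that on consultations where the simulated
clinician's choice fell outside the model's top 3, the model's top
suggestion *predicted* a higher affinity than the clinician *achieved*
(positive mean difference) — the synthetic prescriber is only mildly
informed, unlike real clinicians.

`run/` also contains `recommendations.csv` (full ranked lists with
neighbour support and fallback flags), `predictions.csv`,
`leakage_audit.json` and `exclusions.log`. Other subcommands:
`sczrec sensitivity` (affinity-scheme sweep) and `sczrec external`
(frozen-model validation on a second cohort, no re-tuning).

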