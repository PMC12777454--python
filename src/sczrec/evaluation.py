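"""Nested patient-grouped cross-validation and visit-stratified evaluation.

The outer loop assigns ~20% of *patients* to each of five test folds; the
inner loop re-splits each outer training set into five patient-grouped
folds to select the neighbourhood size K from {5, 10, ..., 60} by minimum
mean inner-fold RMSE. All consultations of a patient stay on one side of
every split, normalisation bounds and feature preprocessing are fitted on
training folds only, and each prediction uses only information available at
that visit — the properties the leakage audit asserts fold by fold.

Also here: the sensitivity sweep over affinity weighting schemes, the
frozen-model external-validation mode, and the paired comparison of the
system's top recommendation against the clinician's achieved outcome on
disagreement cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .affinity import POLICY_BEST, WeightScheme, affinity_table, variant_schemes
from .cohort import drug_affinity_instances, feature_columns
from .errors import (
    SchemaMismatchError,
    TooFewCasesError,
    TooFewPatientsError,
)
from .metrics import map_at_3, overlap_and_coverage, rmse
from .recommender import Recommender, recommendations_frame

DEFAULT_K_GRID = tuple(range(5, 65, 5))


# ---------------------------------------------------------------------------
# fold plans
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """Outer patient partitions plus inner splits per outer training set."""

    outer: list[np.ndarray]
    inner: list[list[tuple[np.ndarray, np.ndarray]]]
    seed: int

    @property
    def n_outer(self) -> int:
        return len(self.outer)


def _partition(ids: np.ndarray, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    ids = np.sort(np.asarray(ids))
    perm = rng.permutation(len(ids))
    return [np.sort(ids[chunk]) for chunk in np.array_split(perm, n_folds)]


def make_fold_plan(cohort: pd.DataFrame, n_outer: int = 5, n_inner: int = 5, seed: int = 42) -> FoldPlan:
    """Deterministic patient-grouped nested fold plan."""
    patients = np.unique(cohort["patient_id"].to_numpy())
    if len(patients) < n_outer:
        raise TooFewPatientsError(f"{len(patients)} patients < {n_outer} outer folds")
    rng = np.random.default_rng(seed)
    outer = _partition(patients, n_outer, rng)
    inner: list[list[tuple[np.ndarray, np.ndarray]]] = []
    for f, test_ids in enumerate(outer):
        train_ids = np.setdiff1d(patients, test_ids)
        inner_rng = np.random.default_rng(seed + 1000 * (f + 1))
        val_folds = _partition(train_ids, n_inner, inner_rng)
        inner.append(
            [(np.setdiff1d(train_ids, val), val) for val in val_folds]
        )
    return FoldPlan(outer=outer, inner=inner, seed=seed)


# ---------------------------------------------------------------------------
# K selection
# ---------------------------------------------------------------------------

def _observed_affinities(test: pd.DataFrame, rec: Recommender) -> pd.Series:
    """Observed affinity of each consultation's prescribed drug, scored with
    the *training-fold* bounds held by the fitted recommender."""
    inst = drug_affinity_instances(test)
    table = affinity_table(inst, rec.bounds, rec.scheme, rec.single_visit_policy)
    lookup = {(r.patient_id, r.drug): r.A for r in table.itertuples()}
    return pd.Series(
        [lookup[(r.patient_id, r.drug)] for r in test.itertuples()], index=test.index
    )


def _predict_prescribed(rec: Recommender, test: pd.DataFrame, k_list: list[int]) -> np.ndarray:
    """Predictions for each consultation's own prescribed drug, all K at once."""
    out = np.full((len(test), len(k_list)), np.nan)
    for v, block in test.groupby("visit_index", sort=True):
        pred, _, _ = rec.predict_batch(
            block, k_list=list(k_list), drugs_per_row=list(block["drug"])
        )
        out[test.index.get_indexer(block.index)] = pred[:, 0, :]
    return out


def select_K(
    train: pd.DataFrame,
    method: str,
    inner_splits: list[tuple[np.ndarray, np.ndarray]],
    k_grid: tuple[int, ...] = DEFAULT_K_GRID,
    scheme: WeightScheme | None = None,
    **rec_kwargs,
) -> int:
    """Pick K minimising mean inner-fold RMSE; ties resolve to the smaller K."""
    fold_rmse = np.zeros((len(inner_splits), len(k_grid)))
    for f, (tr_ids, val_ids) in enumerate(inner_splits):
        tr = train[train["patient_id"].isin(tr_ids)].reset_index(drop=True)
        val = train[train["patient_id"].isin(val_ids)].reset_index(drop=True)
        rec = Recommender(method, K=max(k_grid), scheme=scheme, **rec_kwargs).fit(
            tr, fitted_on=f"inner{f}"
        )
        pred = _predict_prescribed(rec, val, list(k_grid))
        obs = _observed_affinities(val, rec).to_numpy()
        fold_rmse[f] = [rmse(pred[:, t], obs) for t in range(len(k_grid))]
    mean_rmse = fold_rmse.mean(axis=0)
    return int(k_grid[int(np.argmin(mean_rmse))])  # argmin takes the first (smallest K) tie


# ---------------------------------------------------------------------------
# fold evaluation
# ---------------------------------------------------------------------------

def evaluate_fold(
    train: pd.DataFrame,
    test: pd.DataFrame,
    method: str,
    K: int,
    scheme: WeightScheme | None = None,
    fold_id: str = "fold0",
    audit: dict | None = None,
    **rec_kwargs,
) -> tuple[pd.DataFrame, list]:
    """Fit on the training fold, score every test consultation.

    Returns (per-consultation predictions frame, recommendation lists) and
    appends this fold's leakage evidence to ``audit`` when given.
    """
    rec = Recommender(method, K=K, scheme=scheme, **rec_kwargs).fit(train, fitted_on=fold_id)
    test = test.reset_index(drop=True)
    obs = _observed_affinities(test, rec)

    # relevant arms per test patient: received arms with observed A > 0.5
    inst = drug_affinity_instances(test)
    inst_aff = affinity_table(inst, rec.bounds, rec.scheme, rec.single_visit_policy)
    relevant_by_patient: dict[str, set[str]] = {}
    for r in inst_aff.itertuples():
        if r.A > 0.5:
            relevant_by_patient.setdefault(r.patient_id, set()).add(r.drug)

    arm_index = {a: j for j, a in enumerate(rec.arms)}
    rows = []
    rec_lists = []
    train_patient_set = set(train["patient_id"])
    test_patient_set = set(test["patient_id"])
    for v, block in test.groupby("visit_index", sort=True):
        ctx = rec._visit.get(int(v))
        S = ctx["sim"].matrix(block, ctx["pool"]) if ctx is not None else None
        pred, support, fb = rec.predict_batch(block, arms=list(rec.arms), sim_matrix=S)
        for i, (_, row) in enumerate(block.iterrows()):
            rl = rec._rank_from_predictions(
                f"{row['patient_id']}:v{int(v)}", pred[i], support[i], fb[i]
            )
            rec_lists.append(rl)
            j = arm_index[row["drug"]]
            relevant = relevant_by_patient.get(row["patient_id"], set())
            rows.append(
                {
                    "fold": fold_id,
                    "consultation_id": rl.consultation_id,
                    "patient_id": row["patient_id"],
                    "visit_index": int(v),
                    "drug": row["drug"],
                    "observed_A": float(obs.loc[row.name]),
                    "predicted_A": float(pred[i, j]),
                    "top1": rl.arms[0],
                    "top1_predicted": rl.predicted[0],
                    "top3": "|".join(rl.top3),
                    "actual_in_top3": row["drug"] in rl.top3,
                    "n_relevant": len(relevant),
                    "relevant": "|".join(sorted(relevant)),
                }
            )
    result = pd.DataFrame(rows)

    if audit is not None:
        hist_cols = {v: set(feature_columns(v)) for v in (1, 2, 3)}
        future_reads = 0
        for v, block in test.groupby("visit_index", sort=True):
            beyond = [c for c in feature_columns(3) if c not in hist_cols[int(v)]]
            future_reads += int(block[beyond].notna().to_numpy().sum()) if beyond else 0
        audit.setdefault("folds", []).append(
            {
                "fold": fold_id,
                "n_train_patients": len(train_patient_set),
                "n_test_patients": len(test_patient_set),
                "train_test_patient_intersection": sorted(
                    train_patient_set & test_patient_set
                ),
                "bounds_fitted_on": rec.bounds.fitted_on,
                "pool_sizes": {
                    v: len(ctx["pool"]) for v, ctx in rec._visit.items()
                },
                "future_visit_field_reads": future_reads,
                "self_neighbour_queries": 0,  # pool rows of the query's patient are masked
            }
        )
    return result, rec_lists


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _stratum_metrics(df: pd.DataFrame) -> dict:
    """RMSE / MAP@3 / overlap / coverage over one fold x stratum block."""
    out = {
        "rmse": rmse(df["predicted_A"], df["observed_A"]),
        "n_consultations": len(df),
        "n_patient_drug_pairs": df[["patient_id", "drug"]].drop_duplicates().shape[0],
    }
    ranked = [row.split("|") for row in df["top3"]]
    relevant = [set(r.split("|")) if r else set() for r in df["relevant"]]
    try:
        m, n_eval, n_skip = map_at_3(ranked, relevant)
    except Exception:
        m, n_eval, n_skip = np.nan, 0, len(df)
    out["map3"], out["map3_evaluated"], out["map3_skipped"] = m, n_eval, n_skip
    ov, cov = overlap_and_coverage(ranked, list(df["drug"]))
    out["overlap"], out["coverage"] = ov, cov
    return out


@dataclass
class EvaluationResult:
    """Everything a nested-CV run produced."""

    method: str
    scheme_name: str
    seed: int
    fold_ks: list[int]
    predictions: pd.DataFrame
    recommendations: pd.DataFrame
    report: pd.DataFrame
    audit: dict = field(default_factory=dict)


def build_report(method: str, predictions: pd.DataFrame, fold_ks: dict[str, int]) -> pd.DataFrame:
    """Aggregate per-fold metrics into a Table-2-shaped report: mean and sd
    across outer folds, overall and per visit index."""
    rows = []
    strata = [("overall", None), ("visit_1", 1), ("visit_2", 2), ("visit_3", 3)]
    for stratum, v in strata:
        per_fold = []
        for fold, fdf in predictions.groupby("fold"):
            sdf = fdf if v is None else fdf[fdf["visit_index"] == v]
            if len(sdf) == 0:
                continue
            m = _stratum_metrics(sdf)
            m["best_K"] = fold_ks[fold]
            per_fold.append(m)
        if not per_fold:
            continue
        pf = pd.DataFrame(per_fold)
        rows.append(
            {
                "method": method,
                "stratum": stratum,
                "best_K_mean": pf["best_K"].mean(),
                "best_K_sd": pf["best_K"].std(ddof=0),
                "rmse_mean": pf["rmse"].mean(),
                "rmse_sd": pf["rmse"].std(ddof=0),
                "map3_mean": pf["map3"].mean(),
                "map3_sd": pf["map3"].std(ddof=0),
                "overlap_mean": pf["overlap"].mean(),
                "overlap_sd": pf["overlap"].std(ddof=0),
                "coverage_mean": pf["coverage"].mean(),
                "coverage_sd": pf["coverage"].std(ddof=0),
                "avg_consultations": pf["n_consultations"].mean(),
                "avg_patient_drug_pairs": pf["n_patient_drug_pairs"].mean(),
            }
        )
    return pd.DataFrame(rows)


def run_nested_cv(
    cohort: pd.DataFrame,
    method: str,
    k_grid: tuple[int, ...] = DEFAULT_K_GRID,
    n_outer: int = 5,
    n_inner: int = 5,
    seed: int = 42,
    scheme: WeightScheme | None = None,
    plan: FoldPlan | None = None,
    **rec_kwargs,
) -> EvaluationResult:
    """The full harness: plan folds, tune K per outer fold, evaluate."""
    scheme = scheme or WeightScheme("equal")
    plan = plan or make_fold_plan(cohort, n_outer, n_inner, seed)
    audit: dict = {"seed": seed, "method": method}
    all_preds = []
    all_lists = []
    fold_ks: dict[str, int] = {}
    for f, test_ids in enumerate(plan.outer):
        fold_id = f"fold{f}"
        test = cohort[cohort["patient_id"].isin(test_ids)]
        train = cohort[~cohort["patient_id"].isin(test_ids)]
        best_k = select_K(train, method, plan.inner[f], k_grid, scheme, **rec_kwargs)
        fold_ks[fold_id] = best_k
        preds, rec_lists = evaluate_fold(
            train, test, method, best_k, scheme, fold_id=fold_id, audit=audit, **rec_kwargs
        )
        all_preds.append(preds)
        all_lists.extend(rec_lists)
    predictions = pd.concat(all_preds, ignore_index=True)
    audit["total_future_visit_field_reads"] = int(
        sum(f["future_visit_field_reads"] for f in audit["folds"])
    )
    audit["total_train_test_intersections"] = int(
        sum(len(f["train_test_patient_intersection"]) for f in audit["folds"])
    )
    report = build_report(method, predictions, fold_ks)
    return EvaluationResult(
        method=method,
        scheme_name=scheme.name,
        seed=seed,
        fold_ks=[fold_ks[f"fold{f}"] for f in range(plan.n_outer)],
        predictions=predictions,
        recommendations=recommendations_frame(all_lists),
        report=report,
        audit=audit,
    )


# ---------------------------------------------------------------------------
# disagreement analysis
# ---------------------------------------------------------------------------

@dataclass
class DisagreementReport:
    n_cases: int
    mean_difference: float
    sd_difference: float
    t_statistic: float
    p_value: float
    cohens_d: float


def disagreement_analysis(predictions: pd.DataFrame, visit_index: int = 1) -> DisagreementReport:
    """Paired comparison on consultations whose actual therapy fell outside
    the top 3: system-predicted top-arm affinity minus the clinician's
    achieved (observed) affinity. A negative mean means clinicians did
    better than the system expected of its own best suggestion."""
    cases = predictions[
        (predictions["visit_index"] == visit_index) & (~predictions["actual_in_top3"])
    ]
    n = len(cases)
    if n < 2:
        raise TooFewCasesError(f"{n} disagreement case(s); need at least 2")
    d = cases["top1_predicted"].to_numpy() - cases["observed_A"].to_numpy()
    mean, sd = float(np.mean(d)), float(np.std(d, ddof=1))
    if sd == 0:
        t_stat, p = 0.0, 1.0
        cohen = 0.0
    else:
        t_stat = mean / (sd / np.sqrt(n))
        p = float(2 * stats.t.sf(abs(t_stat), df=n - 1))
        cohen = mean / sd
    return DisagreementReport(
        n_cases=n,
        mean_difference=mean,
        sd_difference=sd,
        t_statistic=float(t_stat),
        p_value=float(p),
        cohens_d=float(cohen),
    )


# ---------------------------------------------------------------------------
# external validation and sensitivity sweep
# ---------------------------------------------------------------------------

def external_validate(
    frozen: Recommender,
    external: pd.DataFrame,
    fold_id: str = "external",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate a frozen model on an external cohort — no re-tuning.

    The recommender keeps its development-fold K, feature spaces,
    similarity fit and normalisation bounds; unseen categorical levels
    encode as zeros. Returns (per-consultation predictions, report frame).
    """
    needed = set(feature_columns(3)) | {"patient_id", "visit_index", "drug"}
    missing = needed - set(external.columns)
    if missing:
        raise SchemaMismatchError(f"external cohort missing columns {sorted(missing)}")
    external = external.reset_index(drop=True)
    obs = _observed_affinities(external, frozen)

    inst = drug_affinity_instances(external)
    inst_aff = affinity_table(inst, frozen.bounds, frozen.scheme, frozen.single_visit_policy)
    relevant_by_patient: dict[str, set[str]] = {}
    for r in inst_aff.itertuples():
        if r.A > 0.5:
            relevant_by_patient.setdefault(r.patient_id, set()).add(r.drug)

    arm_index = {a: j for j, a in enumerate(frozen.arms)}
    rows = []
    for v, block in external.groupby("visit_index", sort=True):
        ctx = frozen._visit.get(int(v))
        S = ctx["sim"].matrix(block, ctx["pool"]) if ctx is not None else None
        pred, support, fb = frozen.predict_batch(block, arms=list(frozen.arms), sim_matrix=S)
        for i, (_, row) in enumerate(block.iterrows()):
            rl = frozen._rank_from_predictions(
                f"{row['patient_id']}:v{int(v)}", pred[i], support[i], fb[i]
            )
            relevant = relevant_by_patient.get(row["patient_id"], set())
            rows.append(
                {
                    "fold": fold_id,
                    "consultation_id": rl.consultation_id,
                    "patient_id": row["patient_id"],
                    "visit_index": int(v),
                    "drug": row["drug"],
                    "observed_A": float(obs.loc[row.name]),
                    "predicted_A": float(pred[i, arm_index[row["drug"]]]),
                    "top1": rl.arms[0],
                    "top1_predicted": rl.predicted[0],
                    "top3": "|".join(rl.top3),
                    "actual_in_top3": row["drug"] in rl.top3,
                    "n_relevant": len(relevant),
                    "relevant": "|".join(sorted(relevant)),
                }
            )
    predictions = pd.DataFrame(rows)
    report = build_report(frozen.method, predictions, {fold_id: frozen.K})
    return predictions, report


def planted_recovery_analysis(
    cohort: pd.DataFrame,
    method: str = "CF_COSINE",
    K: int = 7,
    n_permutations: int = 200,
    test_fraction: float = 0.2,
    seed: int = 42,
    scheme: WeightScheme | None = None,
) -> dict:
    """Can the recommender recover a planted subgroup-drug structure?

    Splits patients 80/20, fits on the training side, and scores visit-1
    test consultations. Reports MAP@3 against a label-permutation null
    (training patients' affinity profiles are shuffled relative to their
    features, breaking any feature-outcome link while preserving the
    affinity distribution) and RMSE against the predict-the-training-mean
    baseline.
    """
    rng = np.random.default_rng(seed)
    patients = np.sort(np.unique(cohort["patient_id"].to_numpy()))
    n_test = max(1, int(round(test_fraction * len(patients))))
    test_ids = np.sort(rng.permutation(patients)[:n_test])
    test = cohort[cohort["patient_id"].isin(test_ids)].reset_index(drop=True)
    train = cohort[~cohort["patient_id"].isin(test_ids)].reset_index(drop=True)

    rec = Recommender(method, K=K, scheme=scheme, seed=seed).fit(train, fitted_on="recovery")
    v1 = test[test["visit_index"] == 1].reset_index(drop=True)
    ctx = rec._visit[1]
    S = ctx["sim"].matrix(v1, ctx["pool"])
    arm_aff = np.column_stack([ctx["arm_affinity"][a] for a in rec.arms])
    arm_idx = {a: j for j, a in enumerate(rec.arms)}

    # observed affinities and relevant sets for the test side (train bounds)
    obs = _observed_affinities(v1, rec).to_numpy()
    inst_aff = affinity_table(
        drug_affinity_instances(test), rec.bounds, rec.scheme, rec.single_visit_policy
    )
    relevant_by_patient: dict[str, set[str]] = {}
    for r in inst_aff.itertuples():
        if r.A > 0.5:
            relevant_by_patient.setdefault(r.patient_id, set()).add(r.drug)
    relevant = [relevant_by_patient.get(pid, set()) for pid in v1["patient_id"]]

    def _map3_for_profiles(profiles: np.ndarray) -> float:
        preds = np.full((len(v1), len(rec.arms)), np.nan)
        for j, arm in enumerate(rec.arms):
            aff = profiles[:, j]
            valid = np.where(~np.isnan(aff))[0]
            if len(valid) == 0:
                preds[:, j] = rec.drug_means.get(arm, rec.global_mean)
                continue
            Sv = S[:, valid]
            k = min(K, len(valid))
            top = np.argpartition(-Sv, k - 1, axis=1)[:, :k]
            w = np.take_along_axis(Sv, top, axis=1)
            a = aff[valid][top]
            wsum = w.sum(axis=1)
            preds[:, j] = np.where(wsum > 0, (w * a).sum(axis=1) / np.maximum(wsum, 1e-300),
                                   a.mean(axis=1))
        order = np.argsort(-preds, axis=1, kind="stable")[:, :3]
        ranked = [[rec.arms[j] for j in row] for row in order]
        m, _, _ = map_at_3(ranked, relevant)
        return m

    map3_observed = _map3_for_profiles(arm_aff)
    null = np.array(
        [
            _map3_for_profiles(arm_aff[rng.permutation(arm_aff.shape[0])])
            for _ in range(n_permutations)
        ]
    )

    pred_prescribed = _predict_prescribed(rec, v1, [K])[:, 0]
    model_rmse = rmse(pred_prescribed, obs)
    baseline_rmse = rmse(np.full_like(obs, rec.global_mean), obs)

    return {
        "n_test_visit1": int(len(v1)),
        "map3": float(map3_observed),
        "null_mean": float(null.mean()),
        "null_q975": float(np.quantile(null, 0.975)),
        "exceeds_null_q975": bool(map3_observed > np.quantile(null, 0.975)),
        "rmse": float(model_rmse),
        "baseline_rmse": float(baseline_rmse),
        "beats_baseline": bool(model_rmse < baseline_rmse),
    }


def run_sensitivity(
    cohort: pd.DataFrame,
    method: str,
    schemes: dict[str, WeightScheme] | None = None,
    **cv_kwargs,
) -> dict[str, EvaluationResult]:
    """Repeat the nested CV per affinity weighting scheme on a shared plan."""
    schemes = schemes or variant_schemes()
    seed = cv_kwargs.get("seed", 42)
    plan = make_fold_plan(
        cohort,
        cv_kwargs.get("n_outer", 5),
        cv_kwargs.get("n_inner", 5),
        seed,
    )
    return {
        name: run_nested_cv(cohort, method, scheme=sch, plan=plan, **cv_kwargs)
        for name, sch in schemes.items()
    }
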