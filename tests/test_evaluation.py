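"""Fold plans, K selection, fold evaluation, disagreement, external mode."""

import numpy as np
import pandas as pd
import pytest

from sczrec.affinity import variant_schemes
from sczrec.errors import SchemaMismatchError, TooFewCasesError, TooFewPatientsError
from sczrec.evaluation import (
    build_report,
    disagreement_analysis,
    evaluate_fold,
    external_validate,
    make_fold_plan,
    run_nested_cv,
    run_sensitivity,
    select_K,
)
from sczrec.recommender import Recommender

from conftest import clone_group_cohort


class TestFoldPlan:
    def test_partition_and_grouping(self, small_cohort):
        plan = make_fold_plan(small_cohort, seed=1)
        patients = set(small_cohort["patient_id"])
        seen = [p for fold in plan.outer for p in fold]
        assert sorted(seen) == sorted(patients)  # partition: disjoint + covering
        for f, test_ids in enumerate(plan.outer):
            for tr, val in plan.inner[f]:
                assert not (set(tr) & set(val))
                assert not (set(tr) | set(val)) & set(test_ids)

    def test_even_split(self):
        df = pd.DataFrame({"patient_id": [f"P{i}" for i in range(10)]})
        plan = make_fold_plan(df, n_outer=5, seed=0)
        assert [len(f) for f in plan.outer] == [2] * 5

    def test_deterministic(self, small_cohort):
        p1 = make_fold_plan(small_cohort, seed=5)
        p2 = make_fold_plan(small_cohort, seed=5)
        for a, b in zip(p1.outer, p2.outer):
            np.testing.assert_array_equal(a, b)

    def test_too_few_patients(self):
        df = pd.DataFrame({"patient_id": ["A", "B"]})
        with pytest.raises(TooFewPatientsError):
            make_fold_plan(df, n_outer=5)


class TestSelectK:
    def test_informative_clones_select_smallest_k(self):
        """Each patient's 5 nearest neighbours are exact clones with the
        same outcome; anything beyond is noise, so K = 5 must win in every
        outer fold."""
        cohort = clone_group_cohort(n_groups=8, clones_per_group=15)
        plan = make_fold_plan(cohort, seed=2)
        for f in range(plan.n_outer):
            train = cohort[~cohort["patient_id"].isin(plan.outer[f])]
            best = select_K(train, "CF_EUCLIDEAN", plan.inner[f], k_grid=(5, 10, 20, 40, 60))
            assert best == 5

    def test_exact_ties_resolve_to_smallest(self):
        """With a constant outcome every K predicts identically; the
        tie-break must pick the smallest grid value."""
        cohort = clone_group_cohort(n_groups=4, clones_per_group=10)
        cohort = cohort.assign(util_los_days=5.0)  # constant outcome everywhere
        plan = make_fold_plan(cohort, seed=3)
        best = select_K(cohort[~cohort["patient_id"].isin(plan.outer[0])],
                        "CF_EUCLIDEAN", plan.inner[0], k_grid=(5, 10, 15))
        assert best == 5


class TestEvaluateFold:
    def test_rerun_is_identical_and_test_utils_do_not_leak(self, small_cohort):
        plan = make_fold_plan(small_cohort, seed=4)
        test_ids = set(plan.outer[0])
        train = small_cohort[~small_cohort["patient_id"].isin(test_ids)]
        test = small_cohort[small_cohort["patient_id"].isin(test_ids)]
        r1, _ = evaluate_fold(train, test, "CF_COSINE", K=7, seed=0)
        r2, _ = evaluate_fold(train, test, "CF_COSINE", K=7, seed=0)
        pd.testing.assert_frame_equal(r1, r2)
        # inflating the test fold's raw utilisation cannot move predictions:
        # bounds and pools are training-only
        test_inflated = test.copy()
        test_inflated["util_los_days"] = test_inflated["util_los_days"] * 10
        r3, _ = evaluate_fold(train, test_inflated, "CF_COSINE", K=7, seed=0)
        np.testing.assert_allclose(r1["predicted_A"], r3["predicted_A"], atol=1e-12)


@pytest.fixture(scope="module")
def result(small_cohort):
    return run_nested_cv(small_cohort, "CF_COSINE", k_grid=(5, 10, 15), seed=11)


class TestNestedCv:
    def test_leakage_audit_is_clean(self, result):
        assert result.audit["total_train_test_intersections"] == 0
        assert result.audit["total_future_visit_field_reads"] == 0
        for fold in result.audit["folds"]:
            assert fold["train_test_patient_intersection"] == []

    def test_coverage_complements_overlap_per_stratum(self, result):
        rep = result.report
        np.testing.assert_allclose(
            rep["overlap_mean"] + rep["coverage_mean"], 1.0, atol=1e-12
        )

    def test_report_shape(self, result):
        assert set(result.report["stratum"]) >= {"overall", "visit_1"}
        assert (result.report["rmse_mean"] >= 0).all()
        assert result.predictions["predicted_A"].between(0, 1).all()

    def test_deterministic_rerun(self, small_cohort, result):
        again = run_nested_cv(small_cohort, "CF_COSINE", k_grid=(5, 10, 15), seed=11)
        pd.testing.assert_frame_equal(again.predictions, result.predictions)
        pd.testing.assert_frame_equal(again.report, result.report)


@pytest.mark.parametrize("method", ["CF_EUCLIDEAN", "DR_RBA_GOWER", "DR_RBF", "DR_NCA"])
def test_every_method_survives_the_full_harness(small_cohort, method):
    """All five engines (CF-cosine covered above) run through nested CV with
    a clean leakage audit and bounded predictions."""
    sub_ids = small_cohort["patient_id"].unique()[:60]
    sub = small_cohort[small_cohort["patient_id"].isin(sub_ids)]
    with np.errstate(all="ignore"):
        res = run_nested_cv(sub, method, k_grid=(5,), seed=3)
    assert res.audit["total_train_test_intersections"] == 0
    assert res.predictions["predicted_A"].between(0, 1).all()


class TestDisagreement:
    def _frame(self, diffs, in_top3=False):
        return pd.DataFrame(
            {
                "visit_index": 1,
                "actual_in_top3": in_top3,
                "top1_predicted": 0.5 + np.asarray(diffs),
                "observed_A": 0.5,
            }
        )

    def test_identical_pairs(self):
        rep = disagreement_analysis(self._frame([0.0, 0.0, 0.0]))
        assert rep.mean_difference == 0.0
        assert rep.t_statistic == 0.0 and rep.cohens_d == 0.0

    def test_hand_computed_statistics(self):
        rep = disagreement_analysis(self._frame([-0.1, -0.2, -0.3]))
        assert rep.mean_difference == pytest.approx(-0.2)
        assert rep.cohens_d == pytest.approx(-0.2 / 0.1)
        assert rep.t_statistic == pytest.approx(-0.2 / (0.1 / np.sqrt(3)))
        # negative difference: clinicians outperformed the system
        assert rep.mean_difference < 0

    def test_agreement_cases_are_excluded(self):
        both = pd.concat(
            [self._frame([-0.1, -0.2, -0.3]), self._frame([9.0], in_top3=True)]
        )
        rep = disagreement_analysis(both)
        assert rep.n_cases == 3

    def test_too_few_cases(self):
        with pytest.raises(TooFewCasesError):
            disagreement_analysis(self._frame([0.1]))


class TestExternalValidation:
    def test_frozen_model_runs_without_retuning(self, small_cohort):
        dev_ids = small_cohort["patient_id"].unique()[:80]
        frozen = Recommender("CF_COSINE", K=7, seed=0).fit(
            small_cohort[small_cohort["patient_id"].isin(dev_ids)]
        )
        ext = small_cohort[~small_cohort["patient_id"].isin(dev_ids)]
        preds, report = external_validate(frozen, ext)
        assert frozen.K == 7  # never re-selected
        assert len(preds) == len(ext)
        assert preds["predicted_A"].between(0, 1).all()

    def test_unseen_ethnicity_level_runs(self, small_cohort):
        frozen = Recommender("CF_COSINE", K=5, seed=0).fit(small_cohort)
        ext = small_cohort.head(10).copy()
        ext["patient_id"] = [f"EXT{i}" for i in range(len(ext))]
        ext["ethnicity"] = "Martian"  # unseen level -> zero encoding block
        preds, _ = external_validate(frozen, ext)
        assert len(preds) == len(ext)

    def test_schema_mismatch_raises(self, small_cohort):
        frozen = Recommender("CF_COSINE", K=5, seed=0).fit(small_cohort)
        with pytest.raises(SchemaMismatchError):
            external_validate(frozen, small_cohort.drop(columns=["gender"]))


class TestSensitivity:
    def test_equal_scheme_reproduces_primary_run(self, small_cohort):
        primary = run_nested_cv(small_cohort, "CF_COSINE", k_grid=(5, 10), seed=21)
        sweep = run_sensitivity(
            small_cohort, "CF_COSINE",
            schemes={"equal": variant_schemes()["equal"]},
            k_grid=(5, 10), seed=21,
        )
        pd.testing.assert_frame_equal(sweep["equal"].predictions, primary.predictions)

    def test_three_schemes_share_the_fold_plan(self, small_cohort):
        sweep = run_sensitivity(small_cohort, "CF_COSINE", k_grid=(5,), seed=8)
        assert set(sweep) == {"equal", "stability_heavy", "burden_heavy"}
        folds = {
            name: res.predictions.groupby("fold")["patient_id"].apply(frozenset)
            for name, res in sweep.items()
        }
        pd.testing.assert_series_equal(folds["equal"], folds["stability_heavy"])
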