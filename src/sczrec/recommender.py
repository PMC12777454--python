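"""K-nearest-neighbour affinity prediction and treatment ranking.

For a test consultation at visit v the model compares its feature vector,
encoded in the visit-v feature space, against the training consultations at
the same visit index, and predicts the affinity of each treatment arm as
the similarity-weighted mean of the K most similar training patients with
an observed outcome for that arm. Neighbourhoods are per-drug: the K
nearest are taken among patients who actually have an observed affinity for
the queried arm. When no neighbour exists the prediction falls back to the
arm's training-mean affinity, then to the global training mean; fallbacks
are flagged so cold-arm coverage is auditable.

Ranking is total and deterministic: arms sort by predicted affinity
descending, ties broken by larger neighbour support, then lexicographic arm
name. The no-medication arm competes like any other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .affinity import (
    POLICY_BEST,
    WeightScheme,
    affinity_table,
    fit_bounds,
)
from .arms import TREATMENT_ARMS
from .cohort import HISTORY_FEATURES, MAX_VISITS, drug_affinity_instances
from .errors import NoScorableArmError, NotFittedError, TemporalLeakageError
from .features import FeatureSpace
from .similarity import SimilarityModel, binary_labels

FALLBACK_NONE = "none"
FALLBACK_DRUG_MEAN = "drug_mean"
FALLBACK_GLOBAL_MEAN = "global_mean"


@dataclass
class NeighborSet:
    """The (<= K) most similar training patients for one (query, arm)."""

    patient_ids: list[str]
    similarities: np.ndarray
    affinities: np.ndarray


@dataclass
class RecommendationList:
    consultation_id: str
    arms: list[str]
    predicted: list[float]
    support: list[int]
    fallback: list[str]

    @property
    def top3(self) -> list[str]:
        return self.arms[:3]

    def to_rows(self) -> list[dict]:
        return [
            {
                "consultation_id": self.consultation_id,
                "rank": i + 1,
                "arm": arm,
                "predicted_affinity": self.predicted[i],
                "support": self.support[i],
                "fallback": self.fallback[i],
            }
            for i, arm in enumerate(self.arms)
        ]


class Recommender:
    """A frozen, per-visit-stratified neighbourhood model.

    ``fit`` derives everything from the training consultations alone:
    normalisation bounds and observed affinities, one feature space and one
    similarity engine per visit index, and the per-arm affinity lookup used
    for neighbour retrieval.
    """

    def __init__(
        self,
        method: str,
        K: int,
        scheme: WeightScheme | None = None,
        *,
        weighted: bool = True,
        single_visit_policy: str = POLICY_BEST,
        arms: tuple[str, ...] = TREATMENT_ARMS,
        seed: int = 0,
        relieff_neighbors: int = 10,
        nca_max_iter: int = 200,
        rbf_gamma: float | None = None,
    ):
        if K < 1:
            raise ValueError("K must be >= 1")
        self.method = method
        self.K = K
        self.scheme = scheme or WeightScheme("equal")
        self.weighted = weighted
        self.single_visit_policy = single_visit_policy
        self.arms = tuple(arms)
        self.seed = seed
        self.relieff_neighbors = relieff_neighbors
        self.nca_max_iter = nca_max_iter
        self.rbf_gamma = rbf_gamma
        self._fitted = False

    # -- fitting ------------------------------------------------------------

    def fit(self, train: pd.DataFrame, fitted_on: str = "train") -> "Recommender":
        instances = drug_affinity_instances(train)
        self.bounds = fit_bounds(instances, fitted_on=fitted_on)
        audit = affinity_table(instances, self.bounds, self.scheme, self.single_visit_policy)
        self.affinity_map: dict[tuple[str, str], float] = {
            (r.patient_id, r.drug): r.A for r in audit.itertuples()
        }
        self.drug_means: dict[str, float] = (
            audit.groupby("drug")["A"].mean().to_dict()
        )
        self.global_mean: float = float(audit["A"].mean())
        self.train_patients: set[str] = set(train["patient_id"])

        self._visit: dict[int, dict] = {}
        for v in range(1, MAX_VISITS + 1):
            pool = train[train["visit_index"] == v].reset_index(drop=True)
            if len(pool) == 0:
                continue
            space = FeatureSpace(v).fit(pool, fitted_on=fitted_on)
            pool_aff = np.array(
                [self.affinity_map[(r.patient_id, r.drug)] for r in pool.itertuples()]
            )
            sim = SimilarityModel(
                self.method,
                relieff_neighbors=self.relieff_neighbors,
                nca_max_iter=self.nca_max_iter,
                rbf_gamma=self.rbf_gamma,
                seed=self.seed,
            ).fit(space, pool, binary_labels(pool_aff))
            # per-arm affinity vector aligned with pool rows (NaN = unobserved)
            arm_aff = {
                arm: np.array(
                    [self.affinity_map.get((pid, arm), np.nan) for pid in pool["patient_id"]]
                )
                for arm in self.arms
            }
            self._visit[v] = {
                "pool": pool,
                "space": space,
                "sim": sim,
                "pool_patients": pool["patient_id"].to_numpy(),
                "arm_affinity": arm_aff,
            }
        self._fitted = True
        return self

    def _require_fit(self) -> None:
        if not self._fitted:
            raise NotFittedError("Recommender used before fit")

    # -- prediction ---------------------------------------------------------

    def similarity_rows(self, test: pd.DataFrame) -> np.ndarray:
        """Similarity matrix between test consultations (one visit index) and
        the matching training pool."""
        self._require_fit()
        v = int(test["visit_index"].iloc[0])
        if (test["visit_index"] != v).any():
            raise ValueError("similarity_rows expects a single visit index per call")
        if v not in self._visit:
            raise NotFittedError(f"no training pool for visit {v}")
        ctx = self._visit[v]
        return ctx["sim"].matrix(test, ctx["pool"])

    def _ordered_neighbors(self, sims: np.ndarray, valid: np.ndarray, pids: np.ndarray):
        """Indices of valid pool rows by descending similarity; ties break on
        patient id so predictions are invariant to pool row order."""
        idx = np.where(valid)[0]
        order = np.lexsort((pids[idx], -sims[idx]))
        return idx[order]

    def predict_batch(
        self,
        test: pd.DataFrame,
        arms: list[str] | None = None,
        k_list: list[int] | None = None,
        sim_matrix: np.ndarray | None = None,
        drugs_per_row: list[str] | None = None,
    ):
        """Vectorised prediction core.

        Either score every arm in ``arms`` for every row, or (for RMSE
        evaluation) a single drug per row via ``drugs_per_row``. Returns
        (pred, support, fallback) arrays; with ``k_list`` the prediction
        array gains a trailing K axis, sharing one neighbour sort per query.
        """
        self._require_fit()
        v = int(test["visit_index"].iloc[0])
        ctx = self._visit.get(v)
        ks = k_list or [self.K]
        if drugs_per_row is not None:
            arm_queries = [[d] for d in drugs_per_row]
        else:
            arm_queries = [list(arms or self.arms)] * len(test)

        n = len(test)
        width = max(len(a) for a in arm_queries)
        pred = np.full((n, width, len(ks)), np.nan)
        support = np.zeros((n, width), dtype=int)
        fallback = np.full((n, width), FALLBACK_NONE, dtype=object)

        S = None
        if ctx is not None:
            S = sim_matrix if sim_matrix is not None else ctx["sim"].matrix(test, ctx["pool"])
        test_pids = test["patient_id"].to_numpy()

        for i in range(n):
            for j, arm in enumerate(arm_queries[i]):
                if ctx is not None:
                    aff = ctx["arm_affinity"][arm]
                    valid = ~np.isnan(aff) & (ctx["pool_patients"] != test_pids[i])
                else:
                    valid = np.zeros(0, dtype=bool)
                if valid.any():
                    nb = self._ordered_neighbors(S[i], valid, ctx["pool_patients"])
                    support[i, j] = min(max(ks), len(nb))
                    for t, k in enumerate(ks):
                        sel = nb[:k]
                        w = S[i, sel]
                        a = aff[sel]
                        if self.weighted and w.sum() > 0:
                            pred[i, j, t] = float(np.dot(w, a) / w.sum())
                        else:
                            pred[i, j, t] = float(a.mean())
                elif arm in self.drug_means:
                    pred[i, j, :] = self.drug_means[arm]
                    fallback[i, j] = FALLBACK_DRUG_MEAN
                else:
                    pred[i, j, :] = self.global_mean
                    fallback[i, j] = FALLBACK_GLOBAL_MEAN
        if k_list is None:
            pred = pred[:, :, 0]
        return pred, support, fallback

    def predict_affinity(self, consultation: pd.Series | pd.DataFrame, drug: str, K: int | None = None) -> float:
        """Predicted affinity of one arm for one consultation."""
        row = consultation.to_frame().T if isinstance(consultation, pd.Series) else consultation
        pred, _, _ = self.predict_batch(row, arms=[drug], k_list=[K or self.K])
        return float(pred[0, 0, 0])

    def neighbor_set(self, consultation: pd.DataFrame, drug: str) -> NeighborSet:
        """The neighbours behind one prediction, for interpretability output."""
        self._require_fit()
        v = int(consultation["visit_index"].iloc[0])
        ctx = self._visit.get(v)
        if ctx is None:
            return NeighborSet([], np.array([]), np.array([]))
        S = ctx["sim"].matrix(consultation, ctx["pool"])
        aff = ctx["arm_affinity"][drug]
        valid = ~np.isnan(aff) & (ctx["pool_patients"] != consultation["patient_id"].iloc[0])
        nb = self._ordered_neighbors(S[0], valid, ctx["pool_patients"])[: self.K]
        return NeighborSet(list(ctx["pool_patients"][nb]), S[0, nb], aff[nb])

    # -- ranking ------------------------------------------------------------

    def rank_treatments(
        self,
        consultation: pd.DataFrame,
        sim_matrix: np.ndarray | None = None,
    ) -> RecommendationList:
        """Rank all arms for one consultation (single-row frame)."""
        pred, support, fb = self.predict_batch(
            consultation, arms=list(self.arms), sim_matrix=sim_matrix
        )
        return self._rank_from_predictions(
            _consultation_id(consultation.iloc[0]), pred[0], support[0], fb[0]
        )

    def _rank_from_predictions(self, cid, pred, support, fb) -> RecommendationList:
        scorable = [j for j in range(len(self.arms)) if not np.isnan(pred[j])]
        if not scorable:
            raise NoScorableArmError(f"no scorable arm for consultation {cid}")
        order = sorted(scorable, key=lambda j: (-pred[j], -support[j], self.arms[j]))
        return RecommendationList(
            consultation_id=cid,
            arms=[self.arms[j] for j in order],
            predicted=[float(pred[j]) for j in order],
            support=[int(support[j]) for j in order],
            fallback=[str(fb[j]) for j in order],
        )

    def recommend_for_visit(self, consultation: pd.DataFrame) -> RecommendationList:
        """Guarded entry point for one prescribing decision.

        The consultation row must not carry history fields from its own or
        later visits: visit-v features may reference visits < v only.
        """
        row = consultation.iloc[0]
        v = int(row["visit_index"])
        for k, cols in HISTORY_FEATURES.items():
            if k > v:
                for c in cols:
                    if c in row.index and not pd.isna(row[c]):
                        raise TemporalLeakageError(
                            f"visit-{v} consultation carries future field {c!r}"
                        )
        return self.rank_treatments(consultation)

    def recommend_many(self, test: pd.DataFrame) -> list[RecommendationList]:
        """Recommendation lists for a block of same-visit consultations."""
        self._require_fit()
        v = int(test["visit_index"].iloc[0])
        ctx = self._visit.get(v)
        S = ctx["sim"].matrix(test, ctx["pool"]) if ctx is not None else None
        pred, support, fb = self.predict_batch(test, arms=list(self.arms), sim_matrix=S)
        return [
            self._rank_from_predictions(
                _consultation_id(test.iloc[i]), pred[i], support[i], fb[i]
            )
            for i in range(len(test))
        ]


def _consultation_id(row: pd.Series) -> str:
    return f"{row['patient_id']}:v{int(row['visit_index'])}"


def recommendations_frame(lists: list[RecommendationList]) -> pd.DataFrame:
    """Flatten recommendation lists into the recommendations.csv layout."""
    rows: list[dict] = []
    for rl in lists:
        rows.extend(rl.to_rows())
    return pd.DataFrame(
        rows,
        columns=["consultation_id", "rank", "arm", "predicted_affinity", "support", "fallback"],
    )
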