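"""The five patient-similarity engines.

Two collaborative-filtering similarities on the encoded feature matrix —
cosine, and Euclidean distance converted via 1/(1 + d + eps) with
eps = 1e-9 — and three distance-based-representation methods: the Gower
coefficient on raw mixed-type records with ReliefF attribute weights
(DR-RBA), a Gaussian RBF kernel exp(-gamma * d^2) (DR-RBF), and Euclidean
similarity in a space learned by Neighborhood Components Analysis (DR-NCA).
ReliefF and NCA binarise the training outcome at affinity > 0.5.

All engines emit symmetric similarities in [0, 1]; cosine values that dip
negative after standardisation are clipped at 0 so downstream neighbour
weighting stays non-negative.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.metrics.pairwise import cosine_similarity as _sk_cosine
from sklearn.neighbors import NeighborhoodComponentsAnalysis

from .errors import AllMissingError, NotFittedError, SingleClassError
from .features import FeatureSpace

EPSILON = 1e-9

CF_COSINE = "CF_COSINE"
CF_EUCLIDEAN = "CF_EUCLIDEAN"
DR_RBA_GOWER = "DR_RBA_GOWER"
DR_RBF = "DR_RBF"
DR_NCA = "DR_NCA"

METHODS = (CF_COSINE, CF_EUCLIDEAN, DR_RBA_GOWER, DR_RBF, DR_NCA)

BINARY_LABEL_THRESHOLD = 0.5


# ---------------------------------------------------------------------------
# elementary similarity functions
# ---------------------------------------------------------------------------

def cosine_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """dot(x, y) / (||x|| ||y||); zero vectors return 0 with a warning."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        warnings.warn("cosine similarity of a zero vector defined as 0", stacklevel=2)
        return 0.0
    return float(np.dot(x, y) / (nx * ny))


def euclidean_similarity(x: np.ndarray, y: np.ndarray, epsilon: float = EPSILON) -> float:
    """1 / (1 + ||x - y|| + eps), strictly decreasing in the distance."""
    d = float(np.linalg.norm(np.asarray(x, dtype=float) - np.asarray(y, dtype=float)))
    return 1.0 / (1.0 + d + epsilon)


def rbf_transform(x: np.ndarray, y: np.ndarray, gamma: float) -> float:
    """exp(-gamma * ||x - y||^2)."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    d2 = float(np.sum((np.asarray(x, dtype=float) - np.asarray(y, dtype=float)) ** 2))
    return float(np.exp(-gamma * d2))


def gower_similarity(
    u: dict | pd.Series,
    v: dict | pd.Series,
    categorical: list[str],
    numeric: list[str],
    ranges: dict[str, float],
    weights: dict[str, float] | None = None,
) -> float:
    """Weighted Gower coefficient between two mixed-type records.

    Categorical features contribute 1 iff equal; numeric features contribute
    1 - |u - v| / range with the range taken from the training fold. Missing
    values and zero-range numerics are skipped; the result is the weighted
    mean over comparable features. Raises AllMissingError when nothing is
    comparable.
    """
    weights = weights or {}
    num, den = 0.0, 0.0
    for col in categorical:
        a, b = u[col], v[col]
        if _missing(a) or _missing(b):
            continue
        w = weights.get(col, 1.0)
        num += w * (1.0 if a == b else 0.0)
        den += w
    for col in numeric:
        a, b = u[col], v[col]
        if _missing(a) or _missing(b):
            continue
        rng = ranges.get(col, 0.0)
        if rng <= 0:
            continue
        w = weights.get(col, 1.0)
        num += w * max(0.0, 1.0 - abs(float(a) - float(b)) / rng)
        den += w
    if den == 0:
        raise AllMissingError("no comparable feature between records")
    return num / den


def gower_matrix(
    A: pd.DataFrame,
    B: pd.DataFrame,
    categorical: list[str],
    numeric: list[str],
    ranges: dict[str, float],
    weights: dict[str, float] | None = None,
) -> np.ndarray:
    """Vectorised pairwise Gower similarities between two record frames."""
    weights = weights or {}
    num = np.zeros((len(A), len(B)))
    den = np.zeros((len(A), len(B)))
    for col in categorical:
        a = A[col].to_numpy(dtype=object)[:, None]
        b = B[col].to_numpy(dtype=object)[None, :]
        valid = ~(pd.isna(a) | pd.isna(b))
        w = weights.get(col, 1.0)
        num += w * ((a == b) & valid)
        den += w * valid
    for col in numeric:
        rng = ranges.get(col, 0.0)
        if rng <= 0:
            continue
        a = A[col].to_numpy(dtype=float)[:, None]
        b = B[col].to_numpy(dtype=float)[None, :]
        valid = ~(np.isnan(a) | np.isnan(b))
        w = weights.get(col, 1.0)
        part = np.clip(1.0 - np.abs(np.where(valid, a - b, 0.0)) / rng, 0.0, 1.0)
        num += w * np.where(valid, part, 0.0)
        den += w * valid
    if (den == 0).any():
        raise AllMissingError("some record pair shares no comparable feature")
    return num / den


# ---------------------------------------------------------------------------
# ReliefF attribute weighting
# ---------------------------------------------------------------------------

def relieff_weights(
    X: np.ndarray,
    labels: np.ndarray,
    n_neighbors: int = 10,
) -> np.ndarray:
    """ReliefF feature weights for a binary-labelled numeric matrix.

    For every instance the algorithm finds its ``n_neighbors`` nearest hits
    (same class) and misses (other class) under Manhattan distance on
    range-scaled features, rewarding features that differ across classes and
    penalising ones that differ within a class. Scores are floored at 0 and
    rescaled to mean 1 so they can weight a Gower average directly.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels).astype(int)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise SingleClassError("ReliefF needs at least two instances of each class")

    n, p = X.shape
    rng_feat = X.max(axis=0) - X.min(axis=0)
    rng_feat[rng_feat == 0] = 1.0  # constant features: diffs are 0 anyway
    Z = X / rng_feat

    # full pairwise Manhattan distances; folds here are small enough
    D = np.abs(Z[:, None, :] - Z[None, :, :]).sum(axis=2)
    np.fill_diagonal(D, np.inf)

    W = np.zeros(p)
    for i in range(n):
        same = labels == labels[i]
        same[i] = False
        hits = np.where(same)[0]
        misses = np.where(labels != labels[i])[0]
        k_h = min(n_neighbors, len(hits))
        k_m = min(n_neighbors, len(misses))
        hit_idx = hits[np.argsort(D[i, hits], kind="stable")[:k_h]]
        miss_idx = misses[np.argsort(D[i, misses], kind="stable")[:k_m]]
        diff_hit = np.abs(Z[i] - Z[hit_idx]).mean(axis=0)
        diff_miss = np.abs(Z[i] - Z[miss_idx]).mean(axis=0)
        W += diff_miss - diff_hit
    W /= n
    W = np.maximum(W, 0.0)
    if W.sum() == 0:
        warnings.warn("ReliefF produced all-zero weights; using uniform weights", stacklevel=2)
        return np.ones(p)
    return W / W.mean()


def nca_transform(
    X: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    max_iter: int = 200,
    n_components: int | None = None,
) -> NeighborhoodComponentsAnalysis:
    """Fit an NCA linear map on the training fold (binary labels).

    Output dimension defaults to the input dimension. Convergence warnings
    are surfaced to the caller, not swallowed; a single-class fold raises
    SingleClassError.
    """
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise SingleClassError("NCA needs two label classes")
    nca = NeighborhoodComponentsAnalysis(
        n_components=n_components, max_iter=max_iter, random_state=seed
    )
    nca.fit(np.asarray(X, dtype=float), labels)
    return nca


# ---------------------------------------------------------------------------
# unified engine
# ---------------------------------------------------------------------------

class SimilarityModel:
    """One of the five engines, fitted on a training fold's feature space.

    DR-RBA and DR-NCA need binary training labels (observed affinity > 0.5);
    when an inner fold is degenerate (single class) they fall back to
    uniform Gower weights / the identity map with a warning rather than
    aborting the cross-validation run.
    """

    def __init__(
        self,
        method: str,
        *,
        relieff_neighbors: int = 10,
        nca_max_iter: int = 200,
        rbf_gamma: float | None = None,
        seed: int = 0,
        epsilon: float = EPSILON,
    ):
        if method not in METHODS:
            raise ValueError(f"unknown similarity method {method!r}")
        self.method = method
        self.relieff_neighbors = relieff_neighbors
        self.nca_max_iter = nca_max_iter
        self.rbf_gamma = rbf_gamma
        self.seed = seed
        self.epsilon = epsilon
        self.space: FeatureSpace | None = None
        self.gower_weights: dict[str, float] | None = None
        self._nca: NeighborhoodComponentsAnalysis | None = None
        self._gamma: float | None = None

    def fit(
        self,
        space: FeatureSpace,
        train: pd.DataFrame,
        labels: np.ndarray | None = None,
    ) -> "SimilarityModel":
        self.space = space
        X = space.transform(train)
        self._gamma = self.rbf_gamma if self.rbf_gamma is not None else 1.0 / X.shape[1]
        if self.method == DR_RBA_GOWER:
            try:
                if labels is None:
                    raise SingleClassError("DR-RBA requires binary training labels")
                w_enc = relieff_weights(X, labels, self.relieff_neighbors)
                names = space.encoded_feature_names()
                agg: dict[str, float] = {}
                for name, w in zip(names, w_enc):
                    agg[name] = agg.get(name, 0.0) + float(w)
                self.gower_weights = agg
            except SingleClassError:
                warnings.warn(
                    "single-class training labels; DR-RBA falls back to uniform Gower weights",
                    stacklevel=2,
                )
                self.gower_weights = {c: 1.0 for c in space.columns}
        elif self.method == DR_NCA:
            try:
                if labels is None:
                    raise SingleClassError("DR-NCA requires binary training labels")
                self._nca = nca_transform(
                    X, labels, seed=self.seed, max_iter=self.nca_max_iter
                )
            except SingleClassError:
                warnings.warn(
                    "single-class training labels; DR-NCA falls back to the identity map",
                    stacklevel=2,
                )
                self._nca = None
        return self

    @property
    def is_fitted(self) -> bool:
        return self.space is not None

    def matrix(self, query: pd.DataFrame, pool: pd.DataFrame) -> np.ndarray:
        """Pairwise similarities (n_query x n_pool), all in [0, 1]."""
        if not self.is_fitted:
            raise NotFittedError("SimilarityModel.matrix before fit")
        if self.method == DR_RBA_GOWER:
            sp = self.space
            return gower_matrix(
                query, pool, sp.categorical, sp.numeric, sp.numeric_ranges,
                self.gower_weights,
            )
        Xq = self.space.transform(query)
        Xp = self.space.transform(pool)
        if self.method == CF_COSINE:
            return np.clip(_sk_cosine(Xq, Xp), 0.0, 1.0)
        if self.method == CF_EUCLIDEAN:
            return 1.0 / (1.0 + cdist(Xq, Xp) + self.epsilon)
        if self.method == DR_RBF:
            return np.exp(-self._gamma * cdist(Xq, Xp, "sqeuclidean"))
        if self.method == DR_NCA:
            if self._nca is not None:
                Xq = self._nca.transform(Xq)
                Xp = self._nca.transform(Xp)
            return 1.0 / (1.0 + cdist(Xq, Xp) + self.epsilon)
        raise AssertionError(self.method)

    def similarity(self, u: pd.DataFrame, v: pd.DataFrame) -> float:
        """Similarity between two single-row consultation frames."""
        return float(self.matrix(u, v)[0, 0])

    def params(self) -> dict:
        """Hyperparameters for the audit sidecar."""
        return {
            "method": self.method,
            "epsilon": self.epsilon,
            "relieff_neighbors": self.relieff_neighbors,
            "nca_max_iter": self.nca_max_iter,
            "rbf_gamma": self._gamma,
            "seed": self.seed,
        }


def binary_labels(affinities: np.ndarray, threshold: float = BINARY_LABEL_THRESHOLD) -> np.ndarray:
    """Good/poor outcome labels: 1 where observed affinity exceeds 0.5."""
    return (np.asarray(affinities, dtype=float) > threshold).astype(int)


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x)) or (pd.isna(x) if not isinstance(x, (list, tuple)) else False)
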