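"""The five similarity engines and the shared feature preprocessing."""

import numpy as np
import pandas as pd
import pytest

from sczrec.errors import AllMissingError, EmptyTrainingError, SingleClassError
from sczrec.features import FeatureSpace
from sczrec.similarity import (
    CF_COSINE,
    CF_EUCLIDEAN,
    DR_NCA,
    DR_RBA_GOWER,
    DR_RBF,
    METHODS,
    SimilarityModel,
    binary_labels,
    cosine_similarity,
    euclidean_similarity,
    gower_matrix,
    gower_similarity,
    nca_transform,
    rbf_transform,
    relieff_weights,
)


class TestElementaryFormulas:
    def test_cosine(self):
        assert cosine_similarity([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)
        assert cosine_similarity([1, 0], [1, 1]) == pytest.approx(0.70710678, abs=1e-8)

    def test_cosine_zero_vector_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert cosine_similarity([0, 0], [1, 1]) == 0.0

    def test_euclidean_conversion(self):
        assert euclidean_similarity([1, 2], [1, 2]) == pytest.approx(1 / (1 + 1e-9))
        assert euclidean_similarity([0, 0], [1, 0]) == pytest.approx(0.5, abs=1e-8)
        d_small = euclidean_similarity([0], [1])
        d_big = euclidean_similarity([0], [5])
        assert d_big < d_small

    def test_rbf(self):
        assert rbf_transform([1, 1], [1, 1], gamma=0.7) == pytest.approx(1.0)
        assert rbf_transform([0], [1], gamma=1.0) == pytest.approx(np.exp(-1), abs=1e-9)
        # gamma -> 0 limit: similarity -> 1 for any pair
        assert rbf_transform([0], [100], gamma=1e-12) == pytest.approx(1.0, abs=1e-6)

    def test_gower_scalar(self):
        cats, nums = ["color"], ["x"]
        ranges = {"x": 10.0}
        a = {"color": "red", "x": 0.0}
        b = {"color": "red", "x": 5.0}
        assert gower_similarity(a, a, cats, nums, ranges) == pytest.approx(1.0)
        assert gower_similarity(a, b, cats, nums, ranges) == pytest.approx(0.75)
        c = {"color": "blue", "x": np.nan}
        assert gower_similarity(a, c, cats, nums, ranges) == 0.0  # only colour comparable
        with pytest.raises(AllMissingError):
            gower_similarity(
                {"color": np.nan, "x": np.nan}, a, cats, nums, ranges
            )


class TestReliefF:
    def test_informative_feature_outweighs_noise(self):
        rng = np.random.default_rng(0)
        n = 120
        y = rng.integers(0, 2, n)
        signal = y * 2.0 + rng.normal(0, 0.3, n)
        noise = rng.normal(0, 1.0, n)
        w = relieff_weights(np.column_stack([signal, noise]), y)
        assert w[0] > w[1]

    def test_permuted_labels_destroy_signal_weight(self):
        # permutation oracle: the signal feature's advantage must vanish
        # once labels are shuffled
        rng = np.random.default_rng(1)
        n = 150
        y = np.repeat([0, 1], n // 2)
        X = np.column_stack([y * 2.0 + rng.normal(0, 0.3, n), rng.normal(0, 1.0, n)])
        w_true = relieff_weights(X, y)
        perm_margins = []
        for _ in range(5):
            w_perm = relieff_weights(X, rng.permutation(y))
            perm_margins.append(w_perm[0] - w_perm[1])
        assert w_true[0] - w_true[1] > max(perm_margins)

    def test_constant_feature_scores_zero(self):
        rng = np.random.default_rng(2)
        n = 80
        y = rng.integers(0, 2, n)
        X = np.column_stack([y + rng.normal(0, 0.2, n), np.full(n, 3.0)])
        w = relieff_weights(X, y)
        assert w[1] == 0.0

    def test_single_class_raises(self):
        with pytest.raises(SingleClassError):
            relieff_weights(np.ones((5, 2)), np.zeros(5))


class TestNCA:
    def _blobs(self, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal([0, 0, 0], 0.5, size=(30, 3))
        b = rng.normal([4, 4, 0], 0.5, size=(30, 3))
        X = np.vstack([a, b])
        y = np.repeat([0, 1], 30)
        return X, y

    def test_separates_planted_clusters(self):
        X, y = self._blobs()
        nca = nca_transform(X, y, seed=0)
        Z = nca.transform(X)
        within = np.linalg.norm(Z[:30] - Z[:30].mean(0), axis=1).mean()
        between = np.linalg.norm(Z[:30].mean(0) - Z[30:].mean(0))
        assert within < between

    def test_same_seed_is_bit_exact(self):
        X, y = self._blobs(3)
        t1 = nca_transform(X, y, seed=42).components_
        t2 = nca_transform(X, y, seed=42).components_
        np.testing.assert_array_equal(t1, t2)

    def test_single_class_raises(self):
        with pytest.raises(SingleClassError):
            nca_transform(np.ones((5, 2)), np.ones(5))


class TestFeatureSpace:
    def _frame(self, eths):
        return pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(len(eths))],
                "visit_index": 1,
                "gender": ["M", "F"] * (len(eths) // 2),
                "ethnicity": eths,
                "age": np.linspace(20, 38, len(eths)),
                "comorbidity_count": np.arange(len(eths), dtype=float),
            }
        )

    def test_unseen_level_encodes_as_zeros(self):
        train = self._frame(["White", "Black/African American"] * 3)
        space = FeatureSpace(1).fit(train)
        test = self._frame(["Asian"] * 2)
        X = space.transform(test)
        names = space.encoded_feature_names()
        eth_block = [i for i, n in enumerate(names) if n == "ethnicity"]
        assert (X[:, eth_block] == 0).all()

    def test_standardisation_identity(self):
        train = self._frame(["White"] * 6)
        space = FeatureSpace(1).fit(train)
        X = space.transform(train)
        age_col = space.encoded_feature_names().index("age")
        assert X[:, age_col].mean() == pytest.approx(0.0, abs=1e-12)
        assert X[:, age_col].std() == pytest.approx(1.0)

    def test_transform_is_pure_and_refit_idempotent(self):
        train = self._frame(["White", "Asian"] * 3)
        s1 = FeatureSpace(1).fit(train)
        s2 = FeatureSpace(1).fit(train)
        np.testing.assert_array_equal(s1.transform(train), s2.transform(train))
        np.testing.assert_array_equal(s1.transform(train), s1.transform(train))

    def test_empty_training_raises(self):
        with pytest.raises(EmptyTrainingError):
            FeatureSpace(1).fit(self._frame(["White"] * 2).iloc[0:0])


def brute_force_matrix(method, space, A, B, model):
    """Independent per-pair evaluation of each engine's formula."""
    out = np.zeros((len(A), len(B)))
    Xa, Xb = space.transform(A), space.transform(B)
    if method == DR_NCA and model._nca is not None:
        Xa, Xb = model._nca.transform(Xa), model._nca.transform(Xb)
    for i in range(len(A)):
        for j in range(len(B)):
            if method == CF_COSINE:
                x, y = Xa[i], Xb[j]
                denom = np.sqrt((x * x).sum()) * np.sqrt((y * y).sum())
                out[i, j] = max(0.0, (x * y).sum() / denom) if denom else 0.0
            elif method in (CF_EUCLIDEAN, DR_NCA):
                d = np.sqrt(((Xa[i] - Xb[j]) ** 2).sum())
                out[i, j] = 1.0 / (1.0 + d + 1e-9)
            elif method == DR_RBF:
                d2 = ((Xa[i] - Xb[j]) ** 2).sum()
                out[i, j] = np.exp(-model._gamma * d2)
            elif method == DR_RBA_GOWER:
                out[i, j] = gower_similarity(
                    A.iloc[i], B.iloc[j], space.categorical, space.numeric,
                    space.numeric_ranges, model.gower_weights,
                )
    return out


@pytest.mark.parametrize("method", METHODS)
class TestEngines:
    def _fitted(self, method, small_cohort):
        train = small_cohort[small_cohort["visit_index"] == 1].head(40).reset_index(drop=True)
        space = FeatureSpace(1).fit(train)
        aff = np.linspace(0, 1, len(train))
        model = SimilarityModel(method, seed=5).fit(space, train, binary_labels(aff))
        return model, space, train

    def test_matches_brute_force(self, method, small_cohort):
        model, space, train = self._fitted(method, small_cohort)
        A, B = train.head(8), train.tail(8).reset_index(drop=True)
        fast = model.matrix(A, B)
        slow = brute_force_matrix(method, space, A, B, model)
        np.testing.assert_allclose(fast, slow, atol=1e-9)

    def test_symmetry_range_and_self_similarity(self, method, small_cohort):
        model, _, train = self._fitted(method, small_cohort)
        A = train.head(10)
        S = model.matrix(A, A)
        np.testing.assert_allclose(S, S.T, atol=1e-9)
        assert (S >= 0).all() and (S <= 1 + 1e-12).all()
        if method != CF_EUCLIDEAN and method != DR_NCA:
            np.testing.assert_allclose(np.diag(S), 1.0, atol=1e-9)
        else:  # euclidean conversion: self-similarity is 1/(1 + eps)
            np.testing.assert_allclose(np.diag(S), 1 / (1 + 1e-9), atol=1e-9)

    def test_single_class_fold_degrades_gracefully(self, method, small_cohort):
        train = small_cohort[small_cohort["visit_index"] == 1].head(20).reset_index(drop=True)
        space = FeatureSpace(1).fit(train)
        labels = np.zeros(len(train))
        if method in (DR_RBA_GOWER, DR_NCA):
            with pytest.warns(UserWarning):
                model = SimilarityModel(method).fit(space, train, labels)
        else:
            model = SimilarityModel(method).fit(space, train, labels)
        S = model.matrix(train.head(3), train.head(5))
        assert S.shape == (3, 5)
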