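"""Train-fitted feature preprocessing shared by all similarity engines.

One-hot encoders and standard scalers are fitted exclusively on training
consultations and then applied, frozen, to test data. Categorical levels
unseen at fit time encode as an all-zero block (external cohorts introduce
new dialect levels). The space also records per-numeric training ranges for
the Gower coefficient, which operates on the raw mixed-type records.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.preprocessing import OneHotEncoder, StandardScaler

from .cohort import CATEGORICAL_FEATURES, feature_columns
from .errors import EmptyTrainingError, NotFittedError


class FeatureSpace:
    """Encoder/scaler state for one visit index's feature schema."""

    def __init__(self, visit_index: int):
        self.visit_index = visit_index
        self.columns = feature_columns(visit_index)
        self.categorical = [c for c in self.columns if c in CATEGORICAL_FEATURES]
        self.numeric = [c for c in self.columns if c not in CATEGORICAL_FEATURES]
        self._encoder: OneHotEncoder | None = None
        self._scaler: StandardScaler | None = None
        self.numeric_ranges: dict[str, float] = {}
        self.fitted_on: str | None = None

    def fit(self, train: pd.DataFrame, fitted_on: str = "train") -> "FeatureSpace":
        if len(train) == 0:
            raise EmptyTrainingError("cannot fit a feature space on zero consultations")
        self._encoder = OneHotEncoder(handle_unknown="ignore", sparse_output=False)
        self._encoder.fit(train[self.categorical].astype(str))
        self._scaler = StandardScaler()
        self._scaler.fit(train[self.numeric].astype(float))
        self.numeric_ranges = {
            c: float(train[c].astype(float).max() - train[c].astype(float).min())
            for c in self.numeric
        }
        self.fitted_on = fitted_on
        return self

    @property
    def is_fitted(self) -> bool:
        return self._encoder is not None

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        """Encode a consultation frame into the dense numeric matrix."""
        if not self.is_fitted:
            raise NotFittedError("FeatureSpace.transform before fit")
        cat = self._encoder.transform(df[self.categorical].astype(str))
        num = self._scaler.transform(df[self.numeric].astype(float))
        return np.hstack([cat, num])

    def encoded_feature_names(self) -> list[str]:
        """Original feature name backing each encoded column, in order."""
        if not self.is_fitted:
            raise NotFittedError("feature names unavailable before fit")
        names: list[str] = []
        for col, cats in zip(self.categorical, self._encoder.categories_):
            names.extend([col] * len(cats))
        names.extend(self.numeric)
        return names

    def n_encoded_features(self) -> int:
        return len(self.encoded_feature_names())
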