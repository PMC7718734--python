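"""Random Forest comparison model over whole-transcriptome features.

A bagged ensemble of regression trees, each grown on a bootstrap resample
with a random subset of transcripts considered at every split; predictions
are the plain average over trees, so they always lie inside the range of the
training responses. Defaults mirror the classic regression-forest settings:
1000 trees, m/3 features tried per split, minimum node size 5. The ensemble
is backed by scikit-learn's RandomForestRegressor; features are addressed by
id (columns sorted internally), so predictions are invariant to input column
order at a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor


@dataclass
class ForestModel:
    estimator: RandomForestRegressor
    feature_ids: list[str]
    n_trees: int
    m_try: int
    seed: int
    y_range: tuple[float, float]


def _as_frame(X, name: str) -> pd.DataFrame:
    if not isinstance(X, pd.DataFrame):
        raise TypeError(f"{name} must be a DataFrame with gene ids as columns")
    return X


def fit_forest(
    y_train: np.ndarray,
    X_train: pd.DataFrame,
    n_trees: int = 1000,
    m_try: int | None = None,
    seed: int = 0,
) -> ForestModel:
    """Grow ``n_trees`` regression trees on bootstrap resamples of the lines."""
    X_train = _as_frame(X_train, "X_train")
    y = np.asarray(y_train, dtype=float)
    if len(y) < 10:
        raise ValueError("forest fitting requires at least 10 training lines")
    cols = sorted(str(c) for c in X_train.columns)
    Xs = X_train[cols]
    m = len(cols)
    if m_try is None:
        m_try = max(1, m // 3)
    est = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=m_try,
        min_samples_leaf=5,
        bootstrap=True,
        random_state=int(seed),
        n_jobs=1,
    )
    est.fit(Xs.to_numpy(), y)
    return ForestModel(
        estimator=est,
        feature_ids=cols,
        n_trees=n_trees,
        m_try=m_try,
        seed=int(seed),
        y_range=(float(y.min()), float(y.max())),
    )


def predict_forest(model: ForestModel, X_test: pd.DataFrame) -> np.ndarray:
    """Average of the trees' predictions; feature columns matched by id."""
    X_test = _as_frame(X_test, "X_test")
    have = {str(c) for c in X_test.columns}
    missing = [c for c in model.feature_ids if c not in have]
    if missing:
        raise KeyError(f"missing feature columns (first few): {missing[:5]}")
    Xs = X_test[model.feature_ids]
    return model.estimator.predict(Xs.to_numpy())
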