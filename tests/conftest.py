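import numpy as np
import pandas as pd
import pytest

import skinsens as sk

#: single-point grid: keeps grid-search cost trivial where the search itself
#: is not under test
SMALL_GRID = {
    "learning_rate": [0.1],
    "n_estimators": [50],
    "max_depth": [3],
    "subsample": [0.8],
    "scale_pos_weight": [1.0],
}

#: two-point grid for tests that need a non-degenerate search
TWO_POINT_GRID = {
    "learning_rate": [0.1],
    "n_estimators": [50, 100],
    "max_depth": [3],
    "subsample": [0.8],
    "scale_pos_weight": [1.0],
}


def make_blobs_xy(n=200, d=5, separation=6.0, seed=0):
    """Two Gaussian blobs separated by `separation` standard deviations."""
    rng = np.random.default_rng(seed)
    half = n // 2
    X0 = rng.normal(0, 1, (half, d))
    X1 = rng.normal(separation, 1, (n - half, d))
    X = pd.DataFrame(np.vstack([X0, X1]), columns=[f"f{j}" for j in range(d)])
    y = np.array([0] * half + [1] * (n - half))
    perm = rng.permutation(n)
    return X.iloc[perm].reset_index(drop=True), y[perm]


@pytest.fixture(scope="session")
def blobs():
    return make_blobs_xy(seed=0)


@pytest.fixture(scope="session")
def fitted_bagged(blobs):
    X, y = blobs
    return sk.BaggedXGBClassifier(param_grid=SMALL_GRID, random_state=5).fit(X, y)


@pytest.fixture(scope="session")
def strong_dataset():
    """Synthetic battery with a strong effect (clearly learnable)."""
    return sk.generate(n=200, effect=2.0, seed=11)


@pytest.fixture(scope="session")
def strong_features(strong_dataset):
    X = sk.build_features(strong_dataset)
    y = pd.Series(
        [r.potency_category for r in strong_dataset], index=X.index, name="potency_category"
    )
    return X, y
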