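import numpy as np
import pandas as pd
import pytest

from shadowvimp import PermutationImportanceForest


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def informative_regression():
    """Small regression problem where column 0 drives the outcome."""
    rng = np.random.default_rng(7)
    X = rng.random((60, 5))
    y = 3.0 * X[:, 0] + rng.normal(0, 0.2, 60)
    return X, y


@pytest.fixture(scope="session")
def small_forest(informative_regression):
    X, y = informative_regression
    return PermutationImportanceForest(
        n_trees=60, mtry=2, task="regression", random_state=11
    ).fit(X, y)


def predict_tree(tv, X):
    """Pure-Python traversal of a TreeView (reference implementation)."""
    out = np.empty((X.shape[0], tv.value.shape[1]))
    for r in range(X.shape[0]):
        node = 0
        while tv.feature[node] >= 0:
            if X[r, tv.feature[node]] <= tv.threshold[node]:
                node = tv.children_left[node]
            else:
                node = tv.children_right[node]
        out[r] = tv.value[node]
    return out
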