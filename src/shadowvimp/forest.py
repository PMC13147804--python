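"""Random forests with explicit out-of-bag bookkeeping and permutation importance.

This module provides the tree-ensemble engine behind shadowVIMP.  It grows
CART trees on bootstrap samples (with replacement, sample fraction 1.0) and
records, for every tree ``l``, the in-bag index multiset and the out-of-bag
(OOB) set ``B_l``.  The permutation variable importance (VIMP) of column
``x_j`` in tree ``l`` is the increase in that tree's OOB error when ``x_j``
is permuted *within* ``B_l``:

    VI_l(x_j) = err(tree_l on B_l with x_j permuted) - err(tree_l on B_l)

with squared error for regression and misclassification rate (on per-tree
majority votes) for binary classification.  The forest-level importance is
the mean over the ``q`` trees, and the scaled importance ("z-score") is
``mean / (sd / sqrt(q))`` where ``sd`` is the sample standard deviation of
the per-tree values.

Categorical predictors are handled by target ordering: before any tree is
grown, each categorical column's categories are ranked once on the full
data by their mean outcome (regression) or positive-class rate (binary
classification), and the column is treated as ordered numeric thereafter --
both for splitting and for OOB permutation.  This mirrors the 'ordered'
factor handling of standard RF implementations and deliberately carries its
known cardinality bias into the shadow-variable null (see the selection
module).

Trees are grown and evaluated by compiled kernels (see ``_kernels``)
because a single shadowVIMP analysis fits hundreds of thousands of small
forests; the estimator class here owns validation, encoding and bookkeeping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._kernels import grow_forest, per_tree_vimp_kernel, predict_forest

__all__ = [
    "RFConfig",
    "VimpVector",
    "TreeView",
    "PermutationImportanceForest",
    "order_categories",
    "fit_forest",
    "per_tree_vimp",
    "aggregate_vimp",
    "DegenerateImportanceError",
]


class DegenerateImportanceError(ValueError):
    """Raised when per-tree importances have zero spread but nonzero mean."""


@dataclass(frozen=True)
class RFConfig:
    """Forest configuration (benchmark defaults: many trees, mtry = sqrt p)."""

    num_trees: int = 10_000
    mtry: int | str = "sqrt"
    task: str = "regression"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.num_trees < 2:
            raise ValueError("num_trees must be >= 2")
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")
        if not (self.mtry == "sqrt" or (isinstance(self.mtry, (int, np.integer)) and self.mtry >= 1)):
            raise ValueError("mtry must be a positive integer or 'sqrt'")


@dataclass
class VimpVector:
    """Per-tree permutation importances of one column and their aggregate."""

    per_tree: np.ndarray
    mean: float
    sd: float
    z: float


@dataclass
class TreeView:
    """Read-only view of one fitted tree's structure.

    ``feature`` is -2 at leaves; ``value`` holds the weighted in-bag mean
    (regression) or weighted class counts (classification) per node.
    Children indices are local to this tree.
    """

    feature: np.ndarray
    threshold: np.ndarray
    children_left: np.ndarray
    children_right: np.ndarray
    value: np.ndarray

    @property
    def node_count(self) -> int:
        return self.feature.shape[0]


def _resolve_mtry(mtry: int | str, p: int) -> int:
    if mtry == "sqrt":
        return max(1, int(np.floor(np.sqrt(p))))
    mtry = int(mtry)
    if not 1 <= mtry <= p:
        raise ValueError(f"mtry={mtry} outside [1, {p}]")
    return mtry


def order_categories(column, y, task: str) -> dict:
    """Rank the categories of one column by their association with the outcome.

    Regression orders categories by ascending mean outcome, binary
    classification by ascending positive-class proportion (the positive
    class being the larger label).  Ties are broken by ascending category
    label so the ordering is a deterministic strict total order.  Returns a
    ``{category: rank}`` map with ranks 1..K; the column is treated as
    ordered numeric (these ranks) for both splitting and permutation.
    """
    column = np.asarray(column)
    y = np.asarray(y)
    if column.shape[0] != y.shape[0]:
        raise ValueError("column and y must have the same length")
    if column.shape[0] == 0:
        raise ValueError("column must contain at least one value")
    if task == "classification":
        classes = np.unique(y)
        if classes.size > 2:
            raise ValueError(
                "category ordering supports binary classification only; "
                f"got {classes.size} outcome classes"
            )
        signal = (y == classes[-1]).astype(float)
    elif task == "regression":
        signal = y.astype(float)
    else:
        raise ValueError(f"unknown task {task!r}")
    means = pd.Series(signal).groupby(pd.Series(column), sort=True).mean()
    # stable sort on the score; the groupby index is already label-sorted,
    # so equal scores fall back to label order
    ordered = means.sort_values(kind="stable").index
    return {cat: rank for rank, cat in enumerate(ordered, start=1)}


def _order_codes(codes: np.ndarray, signal: np.ndarray, n_cats: int) -> np.ndarray:
    """Vectorised target ordering for integer-coded categories.

    Returns an array mapping code -> rank (1..K), ranking observed codes by
    ascending mean of ``signal`` with ties broken by ascending code.
    Unobserved codes keep rank 0 (they never occur in the column).
    """
    counts = np.bincount(codes, minlength=n_cats)
    sums = np.bincount(codes, weights=signal, minlength=n_cats)
    observed = np.flatnonzero(counts)
    means = sums[observed] / counts[observed]
    order = observed[np.lexsort((observed, means))]
    ranks = np.zeros(n_cats, dtype=np.float64)
    ranks[order] = np.arange(1, order.size + 1, dtype=np.float64)
    return ranks


def aggregate_vimp(per_tree: np.ndarray, valid: np.ndarray | None = None) -> VimpVector:
    """Aggregate per-tree importances into mean, sample sd and z-score.

    ``valid`` masks trees whose OOB set was non-empty; invalid trees
    contribute 0 to the mean (over all q trees) but are excluded from the
    sd.  The z-score is mean / (sd / sqrt(q)); an all-degenerate case
    (sd = 0, mean != 0) is an error because the scaled importance is then
    undefined.
    """
    per_tree = np.asarray(per_tree, dtype=float)
    q = per_tree.shape[0]
    if q < 2:
        raise ValueError("need at least 2 trees to aggregate")
    mean = float(per_tree.mean())
    vals = per_tree if valid is None else per_tree[valid]
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    if sd > 0.0:
        z = mean / (sd / np.sqrt(q))
    elif mean == 0.0:
        z = 0.0
    else:
        raise DegenerateImportanceError(
            f"zero spread with nonzero mean importance ({mean})"
        )
    return VimpVector(per_tree=per_tree, mean=mean, sd=sd, z=float(z))


class PermutationImportanceForest(BaseEstimator):
    """Random forest with per-tree OOB bookkeeping and permutation VIMP.

    Parameters
    ----------
    n_trees : int
        Number of bootstrap trees ``q``.
    mtry : int or "sqrt"
        Candidate columns per split; "sqrt" means floor(sqrt(p)) of the
        matrix actually fitted.
    task : {"regression", "classification"}
        Classification is restricted to binary outcomes.
    min_samples_split : int or None
        Minimum (bootstrap-weighted) node size eligible for splitting;
        defaults to 5 for regression and 2 for classification.
    categorical : sequence or None
        Column names/indices to treat as categorical (target-ordered).
        Non-numeric pandas columns are treated as categorical automatically.
    random_state : int, RandomState or None
        Drives bootstrap draws and split-candidate subsampling.

    Attributes
    ----------
    trees_ : list of :class:`TreeView`
    inbag_counts_ : (q, n) int array, bootstrap multiplicity per tree
    oob_ : list of index arrays, ``B_l = {1..n} \\ support(inbag_l)``
    column_kinds_ : list of {"continuous", "categorical-ordered"}
    category_orderings_ : dict column -> {category: rank}
    mtry_ : resolved mtry
    """

    def __init__(
        self,
        n_trees: int = 10_000,
        mtry: int | str = "sqrt",
        task: str = "regression",
        min_samples_split: int | None = None,
        categorical=None,
        random_state=None,
    ):
        self.n_trees = n_trees
        self.mtry = mtry
        self.task = task
        self.min_samples_split = min_samples_split
        self.categorical = categorical
        self.random_state = random_state

    # -- fitting ---------------------------------------------------------

    def _encode_X(self, X, y):
        """Return float32 design matrix with categoricals target-ordered."""
        self.category_orderings_ = {}
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            if len(set(names)) != len(names):
                raise ValueError("duplicate column names")
            cat_cols = set(self.categorical or [])
            for c in names:
                if not pd.api.types.is_numeric_dtype(X[c]):
                    cat_cols.add(c)
            self.feature_names_in_ = np.asarray(names, dtype=object)
            cols = np.empty((X.shape[0], X.shape[1]), dtype=np.float64)
            kinds = []
            for i, c in enumerate(names):
                col = X[c]
                if c in cat_cols or i in cat_cols:
                    mapping = order_categories(np.asarray(col), y, self.task)
                    self.category_orderings_[c] = mapping
                    cols[:, i] = pd.Series(col).map(mapping).to_numpy(dtype=np.float64)
                    kinds.append("categorical-ordered")
                else:
                    cols[:, i] = col.to_numpy(dtype=np.float64)
                    kinds.append("continuous")
            self.column_kinds_ = kinds
            return np.ascontiguousarray(cols, dtype=np.float32)
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        kinds = ["continuous"] * X.shape[1]
        if self.categorical:
            X = X.copy()
            for i in self.categorical:
                mapping = order_categories(X[:, i], y, self.task)
                self.category_orderings_[int(i)] = mapping
                X[:, i] = pd.Series(X[:, i]).map(mapping).to_numpy(dtype=np.float64)
                kinds[int(i)] = "categorical-ordered"
        self.column_kinds_ = kinds
        return np.ascontiguousarray(X, dtype=np.float32)

    def fit(self, X, y):
        config = RFConfig(num_trees=self.n_trees, mtry=self.mtry, task=self.task)
        y = np.asarray(y)
        n = y.shape[0]
        if np.asarray(X).shape[0] != n:
            raise ValueError("X and y have inconsistent lengths")
        if n < 10:
            raise ValueError("need at least 10 samples")

        if config.task == "classification":
            self.classes_ = np.unique(y)
            if self.classes_.size > 2:
                raise ValueError("only binary classification is supported")
            y_enc = np.searchsorted(self.classes_, y).astype(np.float64)
            min_split = self.min_samples_split or 2
        else:
            y_enc = y.astype(np.float64)
            min_split = self.min_samples_split or 5

        X32 = self._encode_X(X, y)
        if np.isnan(X32).any() or np.isnan(y_enc).any():
            raise ValueError("missing values are not supported")
        p = X32.shape[1]
        self.mtry_ = _resolve_mtry(config.mtry, p)

        rs = self._check_rs(self.random_state)
        q = config.num_trees
        inbag = np.empty((q, n), dtype=np.int64)
        for l in range(q):
            inbag[l] = np.bincount(rs.randint(0, n, n), minlength=n)
        seeds = rs.randint(0, 2**31 - 1, size=q).astype(np.int64)
        feat, thresh, left, right, value, node_off = grow_forest(
            X32, y_enc, inbag, seeds, self.mtry_, float(min_split),
            config.task == "classification",
        )
        self._feat, self._thresh = feat, thresh
        self._left, self._right = left, right
        self._value, self._node_off = value, node_off
        self.inbag_counts_ = inbag
        self.oob_ = [np.flatnonzero(inbag[l] == 0) for l in range(q)]
        self._oob_flat = np.concatenate(self.oob_) if q else np.empty(0, dtype=np.int64)
        self._oob_off = np.zeros(q + 1, dtype=np.int64)
        self._oob_off[1:] = np.cumsum([o.size for o in self.oob_])
        self._X32 = X32
        self._y_enc = y_enc
        self.n_features_in_ = p
        return self

    @property
    def trees_(self) -> list[TreeView]:
        off = self._node_off
        out = []
        for l in range(off.shape[0] - 1):
            sl = slice(off[l], off[l + 1])
            base = off[l]
            left = self._left[sl].copy()
            right = self._right[sl].copy()
            internal = self._feat[sl] >= 0
            left[internal] -= base
            right[internal] -= base
            out.append(
                TreeView(self._feat[sl], self._thresh[sl], left, right, self._value[sl])
            )
        return out

    @staticmethod
    def _check_rs(random_state) -> np.random.RandomState:
        if isinstance(random_state, np.random.RandomState):
            return random_state
        return np.random.RandomState(random_state)

    # -- prediction ------------------------------------------------------

    def predict(self, X):
        X32 = np.ascontiguousarray(np.asarray(X, dtype=np.float32))
        agg = predict_forest(
            X32, self._feat, self._thresh, self._left, self._right,
            self._value, self._node_off, self.task == "classification",
        )
        if self.task == "classification":
            return self.classes_[(agg >= 0.5).astype(int)]
        return agg

    # -- permutation importance ------------------------------------------

    def per_tree_importance(self, j: int | None = None, random_state=None) -> np.ndarray:
        """Per-tree OOB permutation importance.

        With ``j`` given, returns the q-vector for column j; otherwise the
        full (q, p) matrix.  A fresh within-OOB permutation is drawn per
        tree and column from ``random_state``.  Trees with an empty OOB set
        contribute 0 (with a warning); a single-element OOB set only admits
        the identity permutation, so such trees contribute 0 as well.
        """
        rng = np.random.default_rng(random_state)
        seeds = rng.integers(0, 2**31 - 1, size=self._node_off.shape[0] - 1)
        per_tree, valid = per_tree_vimp_kernel(
            self._X32,
            self._y_enc,
            self._oob_flat,
            self._oob_off,
            self._feat,
            self._thresh,
            self._left,
            self._right,
            self._value,
            self._node_off,
            seeds,
            self.task == "classification",
        )
        if not valid.all():
            warnings.warn(
                f"{int((~valid).sum())} tree(s) have an empty OOB set; contributing 0"
            )
        self._valid_trees = valid
        if j is not None:
            return per_tree[:, j]
        return per_tree

    def importance(self, random_state=None) -> list[VimpVector]:
        """Aggregate permutation importance for every column."""
        per_tree = self.per_tree_importance(random_state=random_state)
        valid = self._valid_trees
        return [aggregate_vimp(per_tree[:, j], valid) for j in range(per_tree.shape[1])]

    def zscores(self, random_state=None) -> np.ndarray:
        """Scaled importances mean/(sd/sqrt(q)) for all columns (fast path)."""
        per_tree = self.per_tree_importance(random_state=random_state)
        valid = self._valid_trees
        q = per_tree.shape[0]
        mean = per_tree.mean(axis=0)
        sd = per_tree[valid].std(axis=0, ddof=1) if valid.sum() > 1 else np.zeros(per_tree.shape[1])
        z = np.zeros(per_tree.shape[1])
        pos = sd > 0
        z[pos] = mean[pos] / (sd[pos] / np.sqrt(q))
        bad = (~pos) & (mean != 0)
        if bad.any():
            raise DegenerateImportanceError(
                f"zero-spread nonzero-mean importance in columns {np.flatnonzero(bad)}"
            )
        return z


def fit_forest(X, y, config: RFConfig, categorical=None) -> PermutationImportanceForest:
    """Fit a forest under ``config`` (functional wrapper over the estimator)."""
    return PermutationImportanceForest(
        n_trees=config.num_trees,
        mtry=config.mtry,
        task=config.task,
        categorical=categorical,
        random_state=config.seed,
    ).fit(X, y)


def per_tree_vimp(forest: PermutationImportanceForest, j: int, perm_seed=None) -> np.ndarray:
    """q-vector of per-tree OOB permutation importances for column j."""
    return forest.per_tree_importance(j=j, random_state=perm_seed)
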