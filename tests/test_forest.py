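"""Forest engine: OOB bookkeeping, category ordering, permutation VIMP."""

import numpy as np
import pandas as pd
import pytest

from shadowvimp import (
    PermutationImportanceForest,
    RFConfig,
    aggregate_vimp,
    fit_forest,
    order_categories,
    per_tree_vimp,
)
from shadowvimp.forest import DegenerateImportanceError

from conftest import predict_tree


class TestOrderCategories:
    @pytest.mark.parametrize(
        "cats, outcomes, expected",
        [
            # ascending per-category mean outcome
            (["A", "B", "C"], {"A": 0.1, "B": 0.9, "C": 0.5}, {"A": 1, "C": 2, "B": 3}),
            (["A"], {"A": 0.3}, {"A": 1}),
            # equal means -> label order breaks the tie
            (["B", "A"], {"B": 0.5, "A": 0.5}, {"A": 1, "B": 2}),
        ],
    )
    def test_regression_ordering(self, cats, outcomes, expected):
        column = np.repeat(cats, 4)
        y = np.array([outcomes[c] for c in column])
        assert order_categories(column, y, "regression") == expected

    def test_binary_classification_orders_by_positive_rate(self):
        column = np.array(["a"] * 10 + ["b"] * 10)
        y = np.array([1] * 8 + [0] * 2 + [1] * 2 + [0] * 8)
        assert order_categories(column, y, "classification") == {"b": 1, "a": 2}

    def test_multiclass_outcome_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            order_categories(["a", "b", "c"], [0, 1, 2], "classification")


class TestBookkeeping:
    def test_oob_complements_inbag(self):
        rng = np.random.default_rng(0)
        X, y = rng.random((100, 10)), rng.random(100)
        f = PermutationImportanceForest(n_trees=50, task="regression", random_state=3).fit(X, y)
        assert len(f.trees_) == 50
        for l in range(50):
            assert f.inbag_counts_[l].sum() == 100
            support = np.flatnonzero(f.inbag_counts_[l] > 0)
            oob = f.oob_[l]
            assert np.array_equal(np.sort(np.concatenate([support, oob])), np.arange(100))
            assert np.intersect1d(support, oob).size == 0

    def test_fixed_seed_reproduces_forest_and_vimp(self, informative_regression):
        X, y = informative_regression
        z = []
        for _ in range(2):
            f = PermutationImportanceForest(n_trees=40, task="regression", random_state=9).fit(X, y)
            z.append(f.zscores(random_state=5))
        assert np.array_equal(z[0], z[1])

    def test_mtry_sqrt_floor_and_bounds(self):
        rng = np.random.default_rng(1)
        X, y = rng.random((30, 10)), rng.random(30)
        f = PermutationImportanceForest(n_trees=5, task="regression", random_state=0).fit(X, y)
        assert f.mtry_ == 3  # floor(sqrt(10))
        with pytest.raises(ValueError, match="mtry"):
            PermutationImportanceForest(n_trees=5, mtry=11, random_state=0).fit(X, y)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            RFConfig(num_trees=1)
        with pytest.raises(ValueError):
            RFConfig(task="ranking")


class TestSplits:
    """The grower must pick loss-optimal splits (brute-force oracle)."""

    @staticmethod
    def _assert_optimal(forest, X32, y, task):
        for l, tv in enumerate(forest.trees_):
            w = forest.inbag_counts_[l].astype(float)
            idx = np.flatnonzero(w > 0)
            self_check = 0

            def walk(node, rows):
                nonlocal self_check
                if tv.feature[node] < 0:
                    return
                ww = w[rows]
                yy = y[rows]
                best = -np.inf
                for f in range(X32.shape[1]):
                    order = np.argsort(X32[rows, f], kind="stable")
                    v = X32[rows, f][order]
                    wo, yo = ww[order], yy[order]
                    for a in range(rows.size - 1):
                        if v[a + 1] <= v[a]:
                            continue
                        wl = wo[: a + 1].sum()
                        wr = wo[a + 1 :].sum()
                        if task == "classification":
                            c1l = (wo[: a + 1] * yo[: a + 1]).sum()
                            c1r = (wo[a + 1 :] * yo[a + 1 :]).sum()
                            proxy = ((wl - c1l) ** 2 + c1l**2) / wl + ((wr - c1r) ** 2 + c1r**2) / wr
                        else:
                            sl = (wo[: a + 1] * yo[: a + 1]).sum()
                            sr = (wo[a + 1 :] * yo[a + 1 :]).sum()
                            proxy = sl * sl / wl + sr * sr / wr
                        best = max(best, proxy)
                # realized proxy of the chosen split
                f = tv.feature[node]
                lmask = X32[rows, f] <= tv.threshold[node]
                wl = ww[lmask].sum()
                wr = ww[~lmask].sum()
                if task == "classification":
                    c1l = (ww[lmask] * yy[lmask]).sum()
                    c1r = (ww[~lmask] * yy[~lmask]).sum()
                    realized = ((wl - c1l) ** 2 + c1l**2) / wl + ((wr - c1r) ** 2 + c1r**2) / wr
                else:
                    sl = (ww[lmask] * yy[lmask]).sum()
                    sr = (ww[~lmask] * yy[~lmask]).sum()
                    realized = sl * sl / wl + sr * sr / wr
                assert realized >= best - 1e-6 * max(1.0, abs(best))
                self_check += 1
                walk(tv.children_left[node], rows[lmask])
                walk(tv.children_right[node], rows[~lmask])

            walk(0, idx)
            assert self_check > 0  # at least the root split was checked

    def test_regression_splits_are_optimal(self):
        rng = np.random.default_rng(5)
        X = rng.random((40, 3))
        y = 2 * X[:, 0] + rng.normal(0, 0.3, 40)
        f = PermutationImportanceForest(n_trees=3, mtry=3, task="regression", random_state=2).fit(X, y)
        self._assert_optimal(f, f._X32, f._y_enc, "regression")

    def test_classification_splits_are_optimal(self):
        rng = np.random.default_rng(6)
        X = rng.random((40, 3))
        y = (X[:, 1] + rng.normal(0, 0.3, 40) > 0.5).astype(int)
        f = PermutationImportanceForest(n_trees=3, mtry=3, task="classification", random_state=2).fit(X, y)
        self._assert_optimal(f, f._X32, f._y_enc, "classification")

    def test_matches_sklearn_tree_without_randomness(self):
        """With mtry=p and unit weights the grower is deterministic CART and
        must agree with an independently implemented CART on tie-free data."""
        from sklearn.tree import DecisionTreeRegressor

        rng = np.random.default_rng(42)
        X = rng.random((60, 4))
        y = rng.random(60)
        from shadowvimp._kernels import grow_forest, predict_forest

        counts = np.ones((1, 60), dtype=np.int64)
        X32 = np.ascontiguousarray(X, dtype=np.float32)
        out = grow_forest(X32, y, counts, np.array([7], np.int64), 4, 5.0, False)
        sk = DecisionTreeRegressor(min_samples_split=5).fit(X32, y)
        # ulp-level proxy ties may cascade into different but equally optimal
        # subtrees: require matching size, equal-quality training fit, and
        # near-total pointwise agreement
        assert out[5][1] == sk.tree_.node_count
        mine_train = predict_forest(X32, *out, False)
        sse_mine = ((mine_train - y) ** 2).sum()
        sse_sk = ((sk.predict(X32) - y) ** 2).sum()
        assert sse_mine == pytest.approx(sse_sk, rel=1e-2)
        Xt = np.ascontiguousarray(rng.random((150, 4), dtype=np.float32))
        assert np.mean(np.isclose(predict_forest(Xt, *out, False), sk.predict(Xt))) > 0.8


class TestPermutationImportance:
    def test_constant_outcome_gives_all_zero_vimp(self):
        rng = np.random.default_rng(2)
        X = rng.random((50, 4))
        y = np.full(50, 3.14)
        f = PermutationImportanceForest(n_trees=20, task="regression", random_state=1).fit(X, y)
        assert np.all(f.per_tree_importance(random_state=0) == 0)
        assert np.all(f.zscores(random_state=0) == 0)

    def test_unused_column_scores_exact_zero(self, informative_regression):
        X, y = informative_regression
        Xc = np.column_stack([X, np.full(X.shape[0], 2.0)])  # constant: never split
        f = PermutationImportanceForest(n_trees=30, task="regression", random_state=4).fit(Xc, y)
        assert np.all(f.per_tree_importance(j=Xc.shape[1] - 1, random_state=0) == 0.0)

    def test_kernel_matches_pure_python_reference(self):
        """Exact agreement with a from-scratch traversal + seeded Fisher-Yates."""
        for task in ("regression", "classification"):
            rng = np.random.default_rng(3)
            X = rng.random((40, 5))
            signal = 2 * X[:, 0] + rng.normal(0, 0.1, 40)
            y = signal if task == "regression" else (signal > 1.0).astype(int)
            f = PermutationImportanceForest(n_trees=25, mtry=2, task=task, random_state=1).fit(X, y)
            pt = f.per_tree_importance(random_state=123)
            seeds = np.random.default_rng(123).integers(0, 2**31 - 1, size=25)
            ref = np.zeros_like(pt)
            y_enc = f._y_enc
            for l, tv in enumerate(f.trees_):
                oob = f.oob_[l]
                if oob.size <= 1:
                    continue
                Xo = f._X32[oob]
                yo = y_enc[oob]
                used = []
                for ft in tv.feature:
                    if ft >= 0 and ft not in used:
                        used.append(ft)

                def err(Xm):
                    val = predict_tree(tv, Xm)
                    if task == "classification":
                        return np.mean(val.argmax(axis=1) != yo)
                    return np.mean((val[:, 0] - yo) ** 2)

                base = err(Xo)
                np.random.seed(seeds[l])
                for u in used:
                    perm = np.arange(oob.size)
                    for r in range(oob.size - 1, 0, -1):
                        s = np.random.randint(0, r + 1)
                        perm[r], perm[s] = perm[s], perm[r]
                    Xp = Xo.copy()
                    Xp[:, u] = Xo[perm, u]
                    ref[l, u] = err(Xp) - base
            assert np.allclose(pt, ref, atol=1e-12)

    def test_two_point_oob_swap_scores_zero_or_full_error(self, informative_regression):
        """With |B_l| = 2 the only permutations are identity (VI = 0) and the
        swap; both must occur across seeds and VI is never negative for a
        perfectly predictive tree."""
        X = np.array([[0.0], [1.0]] * 5)
        y = X[:, 0].copy()
        f = PermutationImportanceForest(n_trees=12, mtry=1, task="regression",
                                        min_samples_split=2, random_state=8).fit(X, y)
        vals = set()
        for seed in range(40):
            vi = per_tree_vimp(f, 0, perm_seed=seed)
            vals.update(np.round(vi, 12))
        assert 0.0 in vals  # identity permutation happens
        assert max(vals) > 0  # some swap strictly degrades a perfect tree

    def test_null_columns_have_near_zero_mean_z(self):
        """Across many refits on a pure-noise design, mean z per column ~ 0."""
        rng = np.random.default_rng(10)
        zs = []
        for i in range(80):
            X = rng.random((60, 4))
            y = rng.random(60)
            f = PermutationImportanceForest(n_trees=50, task="regression",
                                            random_state=int(rng.integers(2**31))).fit(X, y)
            zs.append(f.zscores(random_state=int(rng.integers(2**31))))
        zs = np.asarray(zs)
        # columns are exchangeable under the null: the pooled mean is the
        # sharp check; per-column means carry the full refit-level spread
        # of null z-scores (sd well above 1), so allow 3 standard errors
        assert abs(zs.mean()) < 0.2
        se = zs.std(axis=0, ddof=1) / np.sqrt(zs.shape[0])
        assert np.all(np.abs(zs.mean(axis=0)) < 3 * se + 0.2)


class TestAggregate:
    def test_zscore_arithmetic(self):
        v = aggregate_vimp(np.array([1.0, 2.0, 3.0]))
        assert v.mean == 2.0 and v.sd == 1.0
        assert np.isclose(v.z, 2 * np.sqrt(3))

    def test_all_zero_gives_zero_z(self):
        assert aggregate_vimp(np.zeros(4)).z == 0.0

    def test_degenerate_nonzero_mean_errors(self):
        with pytest.raises(DegenerateImportanceError):
            aggregate_vimp(np.full(5, 1.0))

    def test_iid_normal_z_is_order_one(self):
        rng = np.random.default_rng(0)
        v = aggregate_vimp(rng.normal(0, 1, 10_000))
        assert abs(v.z) < 4


class TestEstimatorInterface:
    def test_predict_learns_signal(self, informative_regression):
        X, y = informative_regression
        f = PermutationImportanceForest(n_trees=80, task="regression", random_state=0).fit(X, y)
        resid = f.predict(X) - y
        assert resid.var() < y.var() * 0.5

    def test_classification_predicts_labels(self):
        rng = np.random.default_rng(4)
        X = rng.random((80, 3))
        y = np.where(X[:, 0] > 0.5, "hi", "lo")
        f = PermutationImportanceForest(n_trees=50, task="classification", random_state=0).fit(X, y)
        pred = f.predict(X)
        assert set(pred) <= {"hi", "lo"}
        assert (pred == y).mean() > 0.9

    def test_categorical_columns_are_rank_encoded(self):
        rng = np.random.default_rng(5)
        frame = pd.DataFrame({
            "cont": rng.random(40),
            "cat": pd.Categorical(rng.integers(0, 3, 40)),
        })
        y = rng.random(40)
        f = PermutationImportanceForest(n_trees=10, task="regression", random_state=0).fit(frame, y)
        assert f.column_kinds_ == ["continuous", "categorical-ordered"]
        mapping = f.category_orderings_["cat"]
        assert sorted(mapping.values()) == [1, 2, 3]

    def test_functional_wrapper(self, informative_regression):
        X, y = informative_regression
        f = fit_forest(X, y, RFConfig(num_trees=10, seed=1))
        assert len(f.trees_) == 10
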