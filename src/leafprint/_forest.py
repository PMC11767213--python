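"""Internal bagged-tree engine used by :mod:`leafprint.rf_models`.

Permutation testing refits a fresh forest for every label permutation
(thousands of fits per analysis), and the margin / proximity machinery needs
out-of-bag hard votes and out-of-bag leaf co-occupancy, which scikit-learn's
forest classes do not expose.  This module therefore drives scikit-learn's
Cython tree primitives (Gini / MSE criterion, BestSplitter,
DepthFirstTreeBuilder) directly: the split-search logic is scikit-learn's
own, but the per-fit Python overhead drops by roughly an order of magnitude
and the bootstrap membership of every tree is retained.

A unit test pins these trees against ``DecisionTreeClassifier`` /
``DecisionTreeRegressor`` fitted with the same RandomState and parameters.
"""

from __future__ import annotations

import numpy as np
from sklearn.tree._criterion import MSE, Gini
from sklearn.tree._splitter import BestSplitter
from sklearn.tree._tree import DepthFirstTreeBuilder, Tree

_MAX_DEPTH = np.iinfo(np.int32).max


def _as_x(X: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(X, dtype=np.float32)


def build_tree(X32: np.ndarray, y2d: np.ndarray, sample_weight: np.ndarray | None,
               criterion, max_features: int, splitter_seed: int,
               n_classes: np.ndarray | None = None) -> Tree:
    """Build one CART tree with sklearn's depth-first builder."""
    n_features = X32.shape[1]
    splitter = BestSplitter(criterion, max_features, 1, 0.0,
                            np.random.RandomState(splitter_seed), None)
    tree = Tree(n_features,
                n_classes if n_classes is not None
                else np.array([1], dtype=np.intp), 1)
    builder = DepthFirstTreeBuilder(splitter, 2, 1, 0.0, _MAX_DEPTH, 0.0)
    builder.build(tree, X32, y2d, sample_weight)
    return tree


class _BaseForest:
    """Bootstrap bagging over sklearn CART trees with retained OOB masks."""

    def __init__(self, n_trees: int = 1000, max_features: int | str = "sqrt",
                 seed: int = 0):
        self.n_trees = int(n_trees)
        self.max_features = max_features
        self.seed = int(seed)
        self.trees: list[Tree] = []
        self.oob: np.ndarray | None = None      # (n_trees, n) bool
        self.leaves: np.ndarray | None = None   # (n, n_trees) leaf ids

    def _resolve_mtry(self, p: int) -> int:
        if self.max_features == "sqrt":
            return max(1, int(np.sqrt(p)))
        if self.max_features == "third":
            return max(1, p // 3)
        return max(1, min(int(self.max_features), p))

    def _fit_bagging(self, X: np.ndarray, y2d: np.ndarray,
                     make_criterion, n_classes: np.ndarray | None) -> np.ndarray:
        X32 = _as_x(X)
        n, p = X32.shape
        mtry = self._resolve_mtry(p)
        rs = np.random.RandomState(self.seed)
        self.trees = []
        self.oob = np.empty((self.n_trees, n), dtype=bool)
        self.leaves = np.empty((n, self.n_trees), dtype=np.intp)
        for t in range(self.n_trees):
            counts = np.bincount(rs.randint(0, n, n), minlength=n).astype(np.float64)
            tree = build_tree(X32, y2d, counts, make_criterion(),
                              mtry, rs.randint(np.iinfo(np.int32).max),
                              n_classes)
            self.trees.append(tree)
            self.oob[t] = counts == 0
            self.leaves[:, t] = tree.apply(X32)
        return X32

    # -- OOB proximity ------------------------------------------------------
    def proximity(self) -> np.ndarray:
        """prox(i, j) = #{trees: i, j both OOB, same leaf} / #{both OOB}."""
        n = self.leaves.shape[0]
        num = np.zeros((n, n))
        den = np.zeros((n, n))
        for t in range(self.n_trees):
            m = self.oob[t]
            both = np.outer(m, m)
            same = self.leaves[:, t][:, None] == self.leaves[None, :, t]
            num += same & both
            den += both
        with np.errstate(invalid="ignore", divide="ignore"):
            prox = np.where(den > 0, num / np.maximum(den, 1), 0.0)
        np.fill_diagonal(prox, 1.0)
        return prox


class ClassificationForest(_BaseForest):
    """Bagged Gini trees with OOB hard votes."""

    def fit(self, X: np.ndarray, y_codes: np.ndarray,
            n_classes: int) -> "ClassificationForest":
        y_codes = np.asarray(y_codes)
        self.n_classes = int(n_classes)
        nc = np.array([self.n_classes], dtype=np.intp)
        y2d = np.ascontiguousarray(y_codes, dtype=np.float64).reshape(-1, 1)
        X32 = self._fit_bagging(X, y2d, lambda: Gini(1, nc), nc)
        n = X32.shape[0]
        # per-tree predicted class per sample (leaf-node majority)
        self._pred = np.empty((n, self.n_trees), dtype=np.intp)
        for t, tree in enumerate(self.trees):
            node_pred = tree.value[:, 0, :].argmax(axis=1)
            self._pred[:, t] = node_pred[self.leaves[:, t]]
        return self

    def oob_vote_counts(self) -> np.ndarray:
        """(n, n_classes) counts of OOB trees voting each class."""
        n = self._pred.shape[0]
        votes = np.zeros((n, self.n_classes))
        for t in range(self.n_trees):
            m = self.oob[t]
            np.add.at(votes, (np.where(m)[0], self._pred[m, t]), 1.0)
        return votes

    def oob_vote_fractions(self) -> np.ndarray:
        """Row-normalised OOB votes; rows never OOB are NaN."""
        counts = self.oob_vote_counts()
        total = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = counts / total
        frac[total[:, 0] == 0] = np.nan
        return frac


class RegressionForest(_BaseForest):
    """Bagged MSE trees with OOB predictions and %IncMSE importance."""

    def __init__(self, n_trees: int = 1000, max_features: int | str = "third",
                 seed: int = 0):
        super().__init__(n_trees, max_features, seed)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RegressionForest":
        y = np.asarray(y, dtype=np.float64)
        self._y = y
        y2d = np.ascontiguousarray(y).reshape(-1, 1)
        n = len(y)
        self._X32 = self._fit_bagging(X, y2d, lambda: MSE(1, n), None)
        self._node_values = [tree.value[:, 0, 0].copy() for tree in self.trees]
        # per-tree OOB contributions to the aggregated prediction
        self._oob_sum = np.zeros(n)
        self._oob_cnt = np.zeros(n)
        for t in range(self.n_trees):
            m = self.oob[t]
            self._oob_sum[m] += self._node_values[t][self.leaves[m, t]]
            self._oob_cnt[m] += 1
        return self

    def oob_prediction(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            pred = self._oob_sum / self._oob_cnt
        return pred

    def oob_r2(self) -> float:
        """R^2 = 1 - MSE_oob / var(y), over samples with >= 1 OOB tree."""
        have = self._oob_cnt > 0
        pred = self.oob_prediction()[have]
        y = self._y[have]
        mse = float(np.mean((y - pred) ** 2))
        var = float(np.var(self._y))
        return 1.0 - mse / var

    def importance_inc_mse(self, seed: int = 0) -> np.ndarray:
        """%IncMSE: relative rise of forest OOB MSE when a feature's OOB
        values are permuted within each tree (features a tree never splits on
        contribute nothing for that tree)."""
        n, p = self._X32.shape
        rng = np.random.default_rng(seed)
        have = self._oob_cnt > 0
        y_have = self._y[have]
        base_pred = self.oob_prediction()[have]
        mse_base = float(np.mean((y_have - base_pred) ** 2))

        # which trees use which features
        trees_using: dict[int, list[int]] = {}
        tree_oob_idx = []
        tree_oob_X = []
        for t, tree in enumerate(self.trees):
            idx = np.where(self.oob[t])[0]
            tree_oob_idx.append(idx)
            tree_oob_X.append(np.ascontiguousarray(self._X32[idx]))
            for f in np.unique(tree.feature[tree.feature >= 0]):
                trees_using.setdefault(int(f), []).append(t)

        imp = np.zeros(p)
        if mse_base == 0:
            return imp
        for j, tlist in trees_using.items():
            sum_j = self._oob_sum.copy()
            for t in tlist:
                idx = tree_oob_idx[t]
                if idx.size < 2:
                    continue
                Xp = tree_oob_X[t].copy()
                Xp[:, j] = Xp[rng.permutation(idx.size), j]
                new_vals = self._node_values[t][self.trees[t].apply(Xp)]
                old_vals = self._node_values[t][self.leaves[idx, t]]
                sum_j[idx] += new_vals - old_vals
            with np.errstate(invalid="ignore", divide="ignore"):
                pred_j = (sum_j / self._oob_cnt)[have]
            mse_j = float(np.mean((y_have - pred_j) ** 2))
            imp[j] = 100.0 * (mse_j - mse_base) / mse_base
        return imp
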