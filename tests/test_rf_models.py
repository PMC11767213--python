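"""Forest statistics: engine pinning, margins, permutation p, geometry."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster

import leafprint as lp
from leafprint._forest import ClassificationForest, RegressionForest, build_tree
from leafprint.rf_models import PermutationResult, _margin_from_fractions


# ---------------------------------------------------------------------------
# engine correctness: tree-for-tree identical to the public sklearn trees
# ---------------------------------------------------------------------------

class TestEngine:
    def test_classification_tree_matches_sklearn(self, rng):
        from sklearn.tree import DecisionTreeClassifier
        from sklearn.tree._criterion import Gini
        X = np.ascontiguousarray(rng.normal(size=(50, 30)).astype(np.float32))
        y = rng.integers(0, 3, 50)
        w = np.bincount(rng.integers(0, 50, 50), minlength=50).astype(float)
        nc = np.array([3], dtype=np.intp)
        for seed in (0, 1, 2):
            mine = build_tree(X, y.astype(np.float64).reshape(-1, 1), w,
                              Gini(1, nc), 5, seed, nc)
            ref = DecisionTreeClassifier(max_features=5, random_state=seed) \
                .fit(X, y, sample_weight=w)
            assert np.array_equal(mine.apply(X), ref.tree_.apply(X))

    def test_regression_tree_matches_sklearn(self, rng):
        from sklearn.tree import DecisionTreeRegressor
        from sklearn.tree._criterion import MSE
        X = np.ascontiguousarray(rng.normal(size=(40, 25)).astype(np.float32))
        t = rng.normal(size=40)
        w = np.bincount(rng.integers(0, 40, 40), minlength=40).astype(float)
        for seed in (3, 4):
            mine = build_tree(X, t.reshape(-1, 1), w, MSE(1, 40), 8, seed, None)
            ref = DecisionTreeRegressor(max_features=8, random_state=seed) \
                .fit(X, t, sample_weight=w)
            assert np.array_equal(mine.apply(X), ref.tree_.apply(X))

    def test_oob_votes_are_fractions(self, rng):
        X = rng.normal(size=(30, 20))
        y = np.repeat([0, 1], 15)
        f = ClassificationForest(n_trees=60, seed=0).fit(X, y, 2)
        frac = f.oob_vote_fractions()
        valid = ~np.isnan(frac[:, 0])
        assert np.allclose(frac[valid].sum(axis=1), 1.0)

    def test_regression_oob_r2_below_one(self, rng):
        X = rng.normal(size=(30, 20))
        t = rng.normal(size=30)
        f = RegressionForest(n_trees=60, seed=0).fit(X, t)
        assert f.oob_r2() <= 1.0


# ---------------------------------------------------------------------------
# classification results
# ---------------------------------------------------------------------------

class TestClassifier:
    def test_planted_feature_gives_large_margin(self, rng):
        """One feature separating the classes by 4 noise s.d. dominates."""
        X = rng.normal(size=(40, 10))
        X[:20, 0] += 4.0
        y = ["A"] * 20 + ["B"] * 20
        res = lp.fit_rf_classifier(X, y, n_trees=300, seed=1)
        assert res.margin > 0.5

    def test_null_margin_near_zero(self, rng):
        X = rng.normal(size=(40, 50))
        y = list(rng.permutation(["A"] * 20 + ["B"] * 20))
        res = lp.fit_rf_classifier(X, y, n_trees=300, seed=2)
        assert abs(res.margin) < 0.1

    def test_margin_bounds_and_proximity_invariants(self, small_study):
        fm, _, meta = small_study
        bio = meta[meta["role"] == "sample"]
        X = np.log2(fm.data.loc[bio["sample_id"]] + 1)
        res = lp.fit_rf_classifier(X, bio["group"], n_trees=100, seed=0)
        assert -1.0 <= res.margin <= 1.0
        P = res.proximity.to_numpy()
        assert np.allclose(P, P.T)
        assert np.allclose(np.diag(P), 1.0)
        assert P.min() >= 0.0 and P.max() <= 1.0

    def test_duplicate_sample_has_top_proximity(self, rng):
        X = rng.normal(size=(20, 15))
        X[1] = X[0]  # exact duplicate
        y = ["A"] * 10 + ["B"] * 10
        res = lp.fit_rf_classifier(X, y, n_trees=200, seed=3)
        row = res.proximity.iloc[0].drop(res.proximity.index[0])
        assert row.idxmax() == res.proximity.index[1]

    def test_single_class_errors(self, rng):
        with pytest.raises(ValueError, match="2 classes"):
            lp.fit_rf_classifier(rng.normal(size=(6, 4)), ["A"] * 6)

    def test_tiny_class_errors(self, rng):
        with pytest.raises(ValueError, match=">= 2 samples"):
            lp.fit_rf_classifier(rng.normal(size=(5, 4)),
                                 ["A", "A", "A", "A", "B"])


class TestMarginStatistic:
    def test_unanimous_votes(self):
        votes = pd.DataFrame({"A": [1.0, 0.0], "B": [0.0, 1.0]})
        assert lp.margin_statistic(votes, ["A", "B"]) == 1.0

    def test_split_votes(self):
        votes = pd.DataFrame({"A": [0.5, 0.5], "B": [0.5, 0.5]})
        assert lp.margin_statistic(votes, ["A", "B"]) == 0.0

    def test_minority_vote_negative(self):
        votes = pd.DataFrame({"A": [0.4], "B": [0.6]})
        assert np.isclose(lp.margin_statistic(votes, ["A"]), -0.2)

    def test_fast_path_agrees_with_public(self, rng):
        frac = rng.dirichlet(np.ones(3), size=12)
        codes = rng.integers(0, 3, 12)
        votes = pd.DataFrame(frac, columns=["A", "B", "C"])
        labels = [["A", "B", "C"][c] for c in codes]
        assert np.isclose(_margin_from_fractions(frac, codes),
                          lp.margin_statistic(votes, labels))


class TestPermutationTest:
    def test_add_one_rule(self):
        res = PermutationResult("margin", observed=0.9,
                                null=np.linspace(-0.1, 0.1, 99),
                                n_permutations=99)
        assert res.p_value == 1 / 100

    def test_median_observed_gives_half(self):
        null = np.linspace(-1, 1, 99)
        res = PermutationResult("margin", observed=0.0, null=null,
                                n_permutations=99)
        assert abs(res.p_value - 0.5) < 0.02

    def test_planted_effect_significant(self, rng):
        X = rng.normal(size=(30, 40))
        X[:15, :5] += 1.5
        y = ["A"] * 15 + ["B"] * 15
        res = lp.permutation_test(X, y, "margin", n_perm=99, n_trees=50, seed=1)
        assert res.p_value <= 0.05
        assert res.p_value > 0.0

    def test_reproducible_given_seed(self, rng):
        X = rng.normal(size=(20, 20))
        y = ["A"] * 10 + ["B"] * 10
        a = lp.permutation_test(X, y, "margin", n_perm=20, n_trees=30, seed=9)
        b = lp.permutation_test(X, y, "margin", n_perm=20, n_trees=30, seed=9)
        assert a.observed == b.observed
        np.testing.assert_array_equal(a.null, b.null)


# ---------------------------------------------------------------------------
# proximity geometry
# ---------------------------------------------------------------------------

class TestGeometry:
    def test_distance_convention(self):
        P = np.array([[1.0, 0.344], [0.344, 1.0]])
        D = lp.proximity_to_distance(P).to_numpy()
        assert np.isclose(D[0, 1], 0.656)
        assert D[0, 0] == 0.0

    def test_asymmetric_proximity_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            lp.proximity_to_distance(np.array([[1.0, 0.2], [0.4, 1.0]]))

    def test_mds_equilateral_triangle(self):
        D = np.ones((3, 3)) - np.eye(3)
        coords = lp.classical_mds(D).coordinates.to_numpy()
        dists = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.allclose(dists + np.eye(3), np.ones((3, 3)), atol=1e-9)

    def test_mds_two_points_on_first_axis(self):
        D = np.array([[0.0, 3.0], [3.0, 0.0]])
        res = lp.classical_mds(D, dims=1)
        x = res.coordinates.to_numpy()[:, 0]
        assert np.allclose(sorted(x), [-1.5, 1.5])

    def test_mds_rank_error(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="rank"):
            lp.classical_mds(D, dims=2)

    def test_mds_matches_pcoa_oracle(self, rng):
        """Embedded distances reproduce scikit-bio's PCoA optimum."""
        from skbio.stats.ordination import pcoa
        pts = rng.normal(size=(8, 4))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        mine = lp.classical_mds(D).coordinates.to_numpy()
        ref = pcoa(D, number_of_dimensions=2).samples.to_numpy()
        for j in range(2):  # sign of each axis is arbitrary
            assert np.allclose(np.abs(mine[:, j]), np.abs(ref[:, j]), atol=1e-8)

    def test_ellipse_centre_and_scaling(self, rng):
        theta = np.linspace(0, 2 * np.pi, 36, endpoint=False)
        pts = np.c_[np.cos(theta), np.sin(theta)]
        e = lp.confidence_ellipse(pts)
        assert np.allclose(e.centre, 0.0, atol=1e-12)
        e2 = lp.confidence_ellipse(2 * pts)
        assert np.allclose(e2.axes, 2 * e.axes)

    def test_ellipse_needs_three_points(self):
        with pytest.raises(ValueError, match="3 points"):
            lp.confidence_ellipse(np.zeros((2, 2)))

    def test_intraclass_distances(self):
        ids = ["a", "b", "c", "d"]
        D = pd.DataFrame(0.3, index=ids, columns=ids)
        np.fill_diagonal(D.values, 0.0)
        cls = pd.Series(["X", "X", "X", "Y"], index=ids)
        table = lp.intraclass_distance_summary(D, cls)
        x = table[table["class"] == "X"].iloc[0]
        assert x["n_pairs"] == 3 and np.isclose(x["median"], 0.3)
        y = table[table["class"] == "Y"].iloc[0]
        assert y["n_pairs"] == 0 and np.isnan(y["median"])

    def test_intraclass_order_invariant(self, rng):
        ids = [f"s{i}" for i in range(6)]
        M = rng.uniform(0, 1, (6, 6))
        D = pd.DataFrame((M + M.T) / 2, index=ids, columns=ids)
        np.fill_diagonal(D.values, 0.0)
        cls = pd.Series(["A", "A", "A", "B", "B", "B"], index=ids)
        t1 = lp.intraclass_distance_summary(D, cls)
        perm = list(rng.permutation(ids))
        t2 = lp.intraclass_distance_summary(D.loc[perm, perm], cls)
        assert dict(zip(t1["class"], t1["median"])) == \
            dict(zip(t2["class"], t2["median"]))


class TestPairwiseDendrogram:
    def test_identical_classes_merge_first(self, rng):
        X = rng.normal(size=(36, 20))
        X[24:, :4] += 3.0  # class C shifted; A and B identically distributed
        y = ["A"] * 12 + ["B"] * 12 + ["C"] * 12
        res = lp.pairwise_margin_dendrogram(X, y, n_trees=200, seed=0)
        groups = fcluster(res.linkage, t=2, criterion="maxclust")
        by = dict(zip(res.labels, groups))
        assert by["A"] == by["B"] != by["C"]
        assert res.margins.loc["A", "C"] > res.margins.loc["A", "B"]

    def test_small_class_excluded(self, rng):
        X = rng.normal(size=(13, 10))
        y = ["A"] * 6 + ["B"] * 6 + ["D"]
        with pytest.raises(ValueError, match="3 usable"):
            lp.pairwise_margin_dendrogram(X, y, n_trees=50, seed=0)


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------

class TestRegressor:
    def test_perfectly_encoded_response(self, rng):
        t = rng.uniform(0, 15, 150)
        X = rng.normal(size=(150, 10)) * 0.1
        X[:, 0] = t + rng.normal(0, 0.05, 150)
        res = lp.fit_rf_regressor(X, t, n_trees=300, seed=1)
        assert res.r2 > 0.9
        assert res.importance.idxmax() == "0"

    def test_pure_noise_r2_nonpositive_on_average(self, rng):
        r2s = [lp.fit_rf_regressor(rng.normal(size=(30, 40)),
                                   rng.normal(size=30),
                                   n_trees=100, seed=s).r2
               for s in range(4)]
        assert np.mean(r2s) <= 0.05

    def test_constant_response_errors(self, rng):
        with pytest.raises(ValueError, match="constant"):
            lp.fit_rf_regressor(rng.normal(size=(10, 5)), np.ones(10))

    def test_explanatory_selection_reproducible(self, rng):
        t = np.repeat([0.0, 3.0, 9.0, 15.0], 6)
        X = rng.normal(size=(24, 20))
        X[:, :3] += np.array([0, 1, 2, -1])[np.repeat(np.arange(4), 6)][:, None]
        res = lp.regression_significance(X, t, n_perm=40, n_trees=100, seed=5)
        # selection rule recomputable from stored p-values and threshold
        assert res.explanatory == [f for f, p in res.importance_p.items()
                                   if p < 0.05]
        assert res.p_value > 0.0
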