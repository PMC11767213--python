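"""Random-forest classification / regression with permutation significance.

The central statistic for class separation is the random-forest *margin*:
for each sample, the fraction of out-of-bag (OOB) trees voting its true
class minus the largest OOB vote fraction for any other class, averaged over
samples.  A margin near zero means the forest separates the classes no
better than chance; significance is assessed by refitting the forest under
random label permutations and taking the add-one tail probability

    p = (1 + #{null >= observed}) / (1 + n_perm).

Sample similarity is summarised by the OOB proximity matrix (fraction of
trees in which two samples share a terminal node among trees where both are
OOB); 1 - proximity is the dissimilarity used for classical multidimensional
scaling and intraclass distance distributions.  Note 1 - proximity is not
guaranteed to satisfy the triangle inequality.

For temporal (regression) analysis, the forest predicts the sampling hour;
model strength is the OOB R^2 = 1 - MSE_oob / var(t) and feature relevance
is the %IncMSE permutation importance, with per-feature significance from a
response-permutation null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.linalg import eigh
from scipy.spatial.distance import squareform
from scipy.stats import chi2

from ._forest import ClassificationForest, RegressionForest

logger = logging.getLogger("leafprint")

DEFAULT_N_TREES = 1000
DEFAULT_N_PERM = 3000


def _as_matrix(X) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.index.astype(str)), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [str(i) for i in range(X.shape[0])], [str(j) for j in range(X.shape[1])]


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass
class RFClassResult:
    classes: list[str]
    votes: pd.DataFrame              # samples x classes, OOB vote fractions
    margin: float
    proximity: pd.DataFrame
    n_trees: int
    seed: int
    p_value: float | None = None
    n_permutations: int | None = None
    null_margins: np.ndarray | None = None


def fit_rf_classifier(X, y, n_trees: int = DEFAULT_N_TREES,
                      seed: int = 0,
                      compute_proximity: bool = True) -> RFClassResult:
    """Fit a bagged classification forest and summarise OOB votes/proximity."""
    Xm, sample_ids, _ = _as_matrix(X)
    y = pd.Series(list(y)).astype(str)
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise ValueError("classification needs at least 2 classes")
    counts = y.value_counts()
    if (counts < 2).any():
        raise ValueError(f"every class needs >= 2 samples; got {dict(counts)}")
    if np.allclose(Xm.std(axis=0), 0):
        warnings.warn("feature matrix is constant; votes will be uninformative")
    codes = y.map({c: i for i, c in enumerate(classes)}).to_numpy()

    forest = ClassificationForest(n_trees=n_trees, seed=seed).fit(
        Xm, codes, len(classes))
    frac = forest.oob_vote_fractions()
    votes = pd.DataFrame(frac, index=sample_ids, columns=classes)
    margin = margin_statistic(votes, list(y))
    prox = pd.DataFrame(forest.proximity(), index=sample_ids,
                        columns=sample_ids) if compute_proximity else \
        pd.DataFrame(np.eye(len(sample_ids)), index=sample_ids, columns=sample_ids)
    return RFClassResult(classes=classes, votes=votes, margin=margin,
                         proximity=prox, n_trees=n_trees, seed=seed)


def margin_statistic(votes: pd.DataFrame, y) -> float:
    """Mean over samples of (true-class vote) - (best other-class vote).

    Samples with no OOB votes (NaN rows) are excluded.
    """
    V = votes.to_numpy(dtype=float)
    sums = np.nansum(V, axis=1)
    if not np.all(np.isnan(V).all(axis=1) | np.isclose(sums, 1.0)):
        raise ValueError("vote fractions must sum to 1 per sample")
    cls_index = {c: i for i, c in enumerate(votes.columns)}
    margins = []
    for i, label in enumerate(y):
        row = V[i]
        if np.isnan(row).all():
            continue
        true = row[cls_index[str(label)]]
        other = np.delete(row, cls_index[str(label)])
        margins.append(true - (other.max() if other.size else 0.0))
    if not margins:
        raise ValueError("no sample had out-of-bag votes")
    return float(np.mean(margins))


# ---------------------------------------------------------------------------
# permutation testing
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    statistic: str
    observed: float
    null: np.ndarray
    n_permutations: int

    @property
    def p_value(self) -> float:
        return (1 + int(np.sum(self.null >= self.observed))) / (1 + len(self.null))


def _margin_from_fractions(frac: np.ndarray, codes: np.ndarray) -> float:
    """Vectorised margin: true-class fraction minus best other fraction."""
    n = frac.shape[0]
    rows = np.arange(n)
    true = frac[rows, codes]
    other = frac.copy()
    other[rows, codes] = -np.inf
    margins = true - other.max(axis=1)
    valid = ~np.isnan(true)
    if not valid.any():
        raise ValueError("no sample had out-of-bag votes")
    return float(margins[valid].mean())


def _margin_once(Xm: np.ndarray, codes: np.ndarray, n_classes: int,
                 n_trees: int, seed: int) -> float:
    forest = ClassificationForest(n_trees=n_trees, seed=seed).fit(
        Xm, codes, n_classes)
    return _margin_from_fractions(forest.oob_vote_fractions(), codes)


def permutation_test(X, y_or_t, statistic: str = "margin",
                     n_perm: int = DEFAULT_N_PERM,
                     n_trees: int = DEFAULT_N_TREES,
                     seed: int = 0) -> PermutationResult:
    """Permutation null for the forest margin (classification) or OOB R^2
    (regression): labels/response are permuted ``n_perm`` times and the
    statistic recomputed with a freshly seeded forest each time."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if statistic not in ("margin", "r2"):
        raise ValueError(f"unknown statistic {statistic!r}")
    Xm, _, _ = _as_matrix(X)
    ss = np.random.SeedSequence(seed)
    perm_rng = np.random.default_rng(ss.spawn(1)[0])
    fit_seeds = ss.generate_state(n_perm + 1) % (2 ** 31)

    if statistic == "margin":
        y = pd.Series(list(y_or_t)).astype(str)
        classes = sorted(y.unique())
        codes = y.map({c: i for i, c in enumerate(classes)}).to_numpy()
        observed = _margin_once(Xm, codes, len(classes), n_trees,
                                int(fit_seeds[0]))
        null = np.empty(n_perm)
        for k in range(n_perm):
            pcodes = perm_rng.permutation(codes)
            null[k] = _margin_once(Xm, pcodes, len(classes), n_trees,
                                   int(fit_seeds[k + 1]))
    else:
        t = np.asarray(y_or_t, dtype=float)
        observed = RegressionForest(n_trees=n_trees,
                                    seed=int(fit_seeds[0])).fit(Xm, t).oob_r2()
        null = np.empty(n_perm)
        for k in range(n_perm):
            null[k] = RegressionForest(
                n_trees=n_trees, seed=int(fit_seeds[k + 1])
            ).fit(Xm, perm_rng.permutation(t)).oob_r2()
    return PermutationResult(statistic=statistic, observed=float(observed),
                             null=null, n_permutations=n_perm)


# ---------------------------------------------------------------------------
# proximity geometry
# ---------------------------------------------------------------------------

def proximity_to_distance(proximity: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """d = 1 - proximity, with an exactly zero diagonal."""
    P = proximity.to_numpy() if isinstance(proximity, pd.DataFrame) else np.asarray(proximity)
    if P.shape[0] != P.shape[1] or not np.allclose(P, P.T, atol=1e-12):
        raise ValueError("proximity matrix must be square and symmetric")
    D = 1.0 - P
    np.fill_diagonal(D, 0.0)
    if isinstance(proximity, pd.DataFrame):
        return pd.DataFrame(D, index=proximity.index, columns=proximity.columns)
    return pd.DataFrame(D)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame        # samples x 2
    eigenvalues: np.ndarray
    ellipses: dict[str, "ConfidenceEllipse"] = field(default_factory=dict)


def classical_mds(distances: pd.DataFrame | np.ndarray,
                  dims: int = 2) -> OrdinationResult:
    """Classical (Torgerson) scaling of a distance matrix.

    Double-centres -0.5 * D^2 and embeds on the top ``dims`` eigenpairs.
    Deterministic up to axis sign.  Negative eigenvalues (non-Euclidean
    distances) are truncated with a logged warning.
    """
    D = distances.to_numpy() if isinstance(distances, pd.DataFrame) else np.asarray(distances, float)
    ids = list(distances.index) if isinstance(distances, pd.DataFrame) else \
        [str(i) for i in range(D.shape[0])]
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if (vals < -1e-9 * max(abs(vals[0]), 1)).any():
        logger.warning("classical_mds: negative eigenvalues truncated "
                       "(non-Euclidean distances)")
    n_pos = int(np.sum(vals > 1e-12))
    if dims > n_pos:
        raise ValueError(f"requested {dims} dimensions but the Gram matrix "
                         f"has rank {n_pos}")
    coords = vecs[:, :dims] * np.sqrt(vals[:dims])
    cols = [f"MDS{i + 1}" for i in range(dims)]
    return OrdinationResult(coordinates=pd.DataFrame(coords, index=ids, columns=cols),
                            eigenvalues=vals)


@dataclass
class ConfidenceEllipse:
    """Multivariate-normal confidence ellipse for one class in 2-D."""

    centre: np.ndarray
    covariance: np.ndarray
    level: float

    @property
    def quantile_radius2(self) -> float:
        return float(chi2.ppf(self.level, df=2))

    def mahalanobis2(self, points: np.ndarray) -> np.ndarray:
        diff = np.atleast_2d(points) - self.centre
        inv = np.linalg.pinv(self.covariance)
        return np.einsum("ij,jk,ik->i", diff, inv, diff)

    def contains(self, points: np.ndarray) -> np.ndarray:
        return self.mahalanobis2(points) <= self.quantile_radius2

    @property
    def axes(self) -> np.ndarray:
        """Semi-axis lengths at the confidence boundary."""
        vals = np.linalg.eigvalsh(self.covariance)
        return np.sqrt(np.clip(vals, 0, None) * self.quantile_radius2)


def confidence_ellipse(coords: np.ndarray | pd.DataFrame,
                       level: float = 0.95) -> ConfidenceEllipse:
    """Mean/covariance ellipse at the chi-square(2) quantile of ``level``."""
    P = coords.to_numpy() if isinstance(coords, pd.DataFrame) else np.asarray(coords, float)
    if P.ndim != 2 or P.shape[1] != 2:
        raise ValueError("coordinates must be n x 2")
    if P.shape[0] < 3:
        raise ValueError("confidence ellipse needs >= 3 points")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    centre = P.mean(axis=0)
    cov = np.cov(P, rowvar=False)
    return ConfidenceEllipse(centre=centre, covariance=cov, level=level)


def intraclass_distance_summary(distances: pd.DataFrame,
                                classes: pd.Series | dict) -> pd.DataFrame:
    """Within-class pairwise distance multisets and their medians.

    Returns one row per class: n_samples, n_pairs, median, distances list.
    Classes of size 1 yield an empty multiset (flagged by n_pairs = 0).
    """
    cls = pd.Series(classes)
    rows = []
    for c in sorted(cls.unique()):
        ids = [i for i in cls.index[cls == c] if i in distances.index]
        sub = distances.loc[ids, ids].to_numpy()
        iu = np.triu_indices(len(ids), k=1)
        vals = sub[iu]
        rows.append({"class": c, "n_samples": len(ids), "n_pairs": len(vals),
                     "median": float(np.median(vals)) if len(vals) else np.nan,
                     "distances": vals})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pairwise binary margins and dendrogram
# ---------------------------------------------------------------------------

@dataclass
class PairwiseMarginResult:
    margins: pd.DataFrame            # classes x classes, symmetric
    p_values: pd.DataFrame | None
    linkage: np.ndarray
    labels: list[str]


def pairwise_margin_dendrogram(X, y, n_trees: int = DEFAULT_N_TREES,
                               seed: int = 0,
                               n_perm: int = 0) -> PairwiseMarginResult:
    """Binary RF margins between every class pair, clustered hierarchically.

    The margin matrix is treated as a dissimilarity (a larger margin means
    the pair is easier to separate, i.e. chemically farther apart) and
    average-linkage clustering is applied; class label order breaks ties.
    With ``n_perm > 0`` each pairwise margin also gets a permutation p.
    """
    Xm, _, _ = _as_matrix(X)
    y = pd.Series(list(y)).astype(str)
    labels = sorted(y.unique())
    usable = [c for c in labels if (y == c).sum() >= 2]
    dropped = set(labels) - set(usable)
    if dropped:
        logger.warning("pairwise margins: classes with < 2 samples excluded: %s",
                       sorted(dropped))
    if len(usable) < 3:
        raise ValueError("pairwise dendrogram needs >= 3 usable classes")
    k = len(usable)
    M = np.zeros((k, k))
    P = np.full((k, k), np.nan)
    for a in range(k):
        for b in range(a + 1, k):
            mask = y.isin([usable[a], usable[b]]).to_numpy()
            ss = np.random.SeedSequence([seed, a, b])
            sub_seed = int(ss.generate_state(1)[0] % (2 ** 31))
            if n_perm > 0:
                res = permutation_test(Xm[mask], y[mask], "margin",
                                       n_perm=n_perm, n_trees=n_trees,
                                       seed=sub_seed)
                M[a, b] = M[b, a] = res.observed
                P[a, b] = P[b, a] = res.p_value
            else:
                fit = fit_rf_classifier(Xm[mask], y[mask], n_trees=n_trees,
                                        seed=sub_seed, compute_proximity=False)
                M[a, b] = M[b, a] = fit.margin
    margins = pd.DataFrame(M, index=usable, columns=usable)
    # margins can be slightly negative; shift to a valid dissimilarity
    dis = M - min(0.0, M.min())
    np.fill_diagonal(dis, 0.0)
    Z = linkage(squareform(dis, checks=False), method="average")
    pvals = pd.DataFrame(P, index=usable, columns=usable) if n_perm > 0 else None
    return PairwiseMarginResult(margins=margins, p_values=pvals,
                                linkage=Z, labels=usable)


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------

@dataclass
class RFRegResult:
    r2: float
    oob_prediction: pd.Series
    importance: pd.Series            # %IncMSE per feature
    n_trees: int
    seed: int
    p_value: float | None = None
    n_permutations: int | None = None
    importance_p: pd.Series | None = None
    explanatory: list[str] = field(default_factory=list)


def fit_rf_regressor(X, t, n_trees: int = DEFAULT_N_TREES,
                     seed: int = 0) -> RFRegResult:
    """Fit a bagged regression forest; report OOB R^2 and %IncMSE."""
    Xm, sample_ids, feat_ids = _as_matrix(X)
    t = np.asarray(t, dtype=float)
    n_distinct = np.unique(t).size
    if n_distinct < 2:
        raise ValueError("regression response is constant")
    if n_distinct < 3:
        warnings.warn("regression response has only 2 distinct values; "
                      "OOB R2 will behave like a classification margin")
    forest = RegressionForest(n_trees=n_trees, seed=seed).fit(Xm, t)
    imp = forest.importance_inc_mse(seed=seed)
    return RFRegResult(r2=forest.oob_r2(),
                       oob_prediction=pd.Series(forest.oob_prediction(),
                                                index=sample_ids),
                       importance=pd.Series(imp, index=feat_ids),
                       n_trees=n_trees, seed=seed)


def regression_significance(X, t, n_perm: int = DEFAULT_N_PERM,
                            n_trees: int = DEFAULT_N_TREES,
                            seed: int = 0,
                            alpha: float = 0.05) -> RFRegResult:
    """Regression fit plus a single response-permutation null that serves
    both the model R^2 and the per-feature %IncMSE p-values; explanatory
    features are those with importance p < ``alpha`` (no multiplicity
    adjustment, matching the raw-p selection rule)."""
    Xm, _, feat_ids = _as_matrix(X)
    t = np.asarray(t, dtype=float)
    result = fit_rf_regressor(X, t, n_trees=n_trees, seed=seed)
    ss = np.random.SeedSequence(seed)
    perm_rng = np.random.default_rng(ss.spawn(1)[0])
    fit_seeds = ss.generate_state(n_perm) % (2 ** 31)
    null_r2 = np.empty(n_perm)
    null_imp = np.empty((n_perm, len(feat_ids)))
    for k in range(n_perm):
        tp = perm_rng.permutation(t)
        forest = RegressionForest(n_trees=n_trees, seed=int(fit_seeds[k])).fit(Xm, tp)
        null_r2[k] = forest.oob_r2()
        null_imp[k] = forest.importance_inc_mse(seed=int(fit_seeds[k]))
    obs_imp = result.importance.to_numpy()
    imp_p = (1 + (null_imp >= obs_imp[None, :]).sum(axis=0)) / (1 + n_perm)
    result.p_value = (1 + int((null_r2 >= result.r2).sum())) / (1 + n_perm)
    result.n_permutations = n_perm
    result.importance_p = pd.Series(imp_p, index=feat_ids)
    result.explanatory = [f for f, p in zip(feat_ids, imp_p) if p < alpha]
    logger.info("regression: R2=%.3f (p=%.4g), %d explanatory features",
                result.r2, result.p_value, len(result.explanatory))
    return result
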