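"""Temporal trend clustering of explanatory features.

Each explanatory feature's diurnal behaviour is summarised as a log2
abundance-ratio profile: the median log2 intensity per timepoint minus the
median at the baseline timepoint (09:00), so the baseline entry is zero by
construction and a difference of log2 medians is the log2 of the median
abundance ratio.  Profiles are grouped with Euclidean k-means (default
k = 5, restarted and seeded); the centroid profiles are the per-cluster
trend shapes.  A per-feature box-plot summary (quartiles, 1.5 IQR whiskers,
outliers) supports single-metabolite diurnal displays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

logger = logging.getLogger("leafprint")

DEFAULT_K = 5
DEFAULT_RESTARTS = 10


# ---------------------------------------------------------------------------
# log2 ratio profiles
# ---------------------------------------------------------------------------

def log2_ratio_profiles(matrix, samples: pd.DataFrame,
                        features: list[str] | None = None,
                        baseline: str = "09:00",
                        timepoint_key: str = "timepoint") -> pd.DataFrame:
    """Per-feature log2 abundance ratios relative to the baseline timepoint.

    For every feature and timepoint, the median log2 value over that
    timepoint's biological samples minus the baseline median.  Timepoints
    are ordered by their ``hour`` column when present.  The matrix must be
    at the log2 stage.
    """
    if getattr(matrix, "stage", "log2") != "log2":
        raise ValueError("log2_ratio_profiles expects a log2-stage matrix")
    data = matrix.data if hasattr(matrix, "data") else matrix
    if features is None:
        features = list(data.columns)
    missing = [f for f in features if f not in data.columns]
    if missing:
        raise ValueError(f"features not in matrix: {missing[:5]}")
    bio = samples[samples["role"] == "sample"]
    if "hour" in bio.columns:
        order = (bio.drop_duplicates(timepoint_key)
                 .sort_values("hour")[timepoint_key].tolist())
    else:
        order = list(dict.fromkeys(bio[timepoint_key]))
    if baseline not in order:
        raise ValueError(f"baseline timepoint {baseline!r} absent from samples")

    medians = {}
    for tp in order:
        ids = [s for s in bio.loc[bio[timepoint_key] == tp, "sample_id"]
               if s in data.index]
        if not ids:
            raise ValueError(f"timepoint {tp!r} has zero samples in the matrix")
        medians[tp] = data.loc[ids, features].median(axis=0)
    prof = pd.DataFrame(medians)[order]
    prof = prof.sub(prof[baseline], axis=0)
    return prof


# ---------------------------------------------------------------------------
# k-means clustering
# ---------------------------------------------------------------------------

@dataclass
class TrendClusters:
    assignments: pd.Series           # feature id -> cluster id (1-based)
    centroids: pd.DataFrame          # cluster id x timepoints
    inertia: float
    k: int
    seed: int


def kmeans_trends(profiles: pd.DataFrame, k: int = DEFAULT_K,
                  n_restarts: int = DEFAULT_RESTARTS,
                  seed: int = 0) -> TrendClusters:
    """Euclidean k-means on ratio profiles, best of ``n_restarts`` restarts.

    Cluster ids are 1-based and ordered by decreasing cluster size (ties by
    first feature) so that numbering is reproducible.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds the {len(profiles)} features")
    if not np.isfinite(profiles.to_numpy()).all():
        raise ValueError("profiles contain non-finite values")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed,
                algorithm="lloyd").fit(profiles.to_numpy())
    raw_labels = km.labels_
    # relabel clusters by decreasing size for stable, readable numbering
    sizes = pd.Series(raw_labels).value_counts()
    order = list(sizes.sort_values(ascending=False, kind="stable").index)
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([relabel[c] for c in raw_labels], index=profiles.index,
                       name="cluster")
    centroids = pd.DataFrame(km.cluster_centers_, columns=profiles.columns)
    centroids.index = [relabel[i] for i in range(k)]
    centroids = centroids.sort_index()
    logger.info("k-means: k=%d, inertia=%.4g, cluster sizes=%s",
                k, km.inertia_, labels.value_counts().sort_index().to_dict())
    return TrendClusters(assignments=labels, centroids=centroids,
                         inertia=float(km.inertia_), k=k, seed=seed)


def cluster_quality_report(profiles: pd.DataFrame,
                           k_range: tuple[int, int] = (2, 8),
                           n_restarts: int = DEFAULT_RESTARTS,
                           seed: int = 0) -> pd.DataFrame:
    """Elbow / silhouette report over a range of k, to justify the choice."""
    rows = []
    for k in range(k_range[0], min(k_range[1], len(profiles) - 1) + 1):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed,
                    algorithm="lloyd").fit(profiles.to_numpy())
        sil = silhouette_score(profiles.to_numpy(), km.labels_) \
            if k >= 2 and len(set(km.labels_)) > 1 else np.nan
        rows.append({"k": k, "inertia": km.inertia_, "silhouette": sil})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# box-plot summaries
# ---------------------------------------------------------------------------

def feature_boxplot_summary(matrix, samples: pd.DataFrame, feature: str,
                            group_key: str = "timepoint") -> pd.DataFrame:
    """Per-group quartiles, 1.5 IQR whiskers (clipped to data) and outliers."""
    data = matrix.data if hasattr(matrix, "data") else matrix
    if feature not in data.columns:
        raise ValueError(f"feature {feature!r} not in matrix")
    bio = samples[samples["role"] == "sample"]
    rows = []
    groups = (bio.drop_duplicates(group_key).sort_values("hour")[group_key]
              if "hour" in bio.columns and group_key == "timepoint"
              else pd.Series(sorted(bio[group_key].unique())))
    for grp in groups:
        ids = [s for s in bio.loc[bio[group_key] == grp, "sample_id"]
               if s in data.index]
        if not ids:
            raise ValueError(f"group {grp!r} is empty")
        vals = data.loc[ids, feature].to_numpy()
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
        outliers = vals[(vals < lo_fence) | (vals > hi_fence)]
        rows.append({group_key: grp, "n": len(vals), "q1": q1, "median": med,
                     "q3": q3, "whisker_low": float(inside.min()),
                     "whisker_high": float(inside.max()),
                     "outliers": sorted(float(v) for v in outliers)})
    return pd.DataFrame(rows)
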