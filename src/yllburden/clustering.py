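"""Development-level classification of locations by K-means.

Locations are clustered on three socioeconomic features — percent urban
dwellers, average years of education, and GDP per capita — after
z-standardisation (GDP's scale would otherwise dominate the Euclidean
distance).  The cluster count is chosen by majority vote over a panel of
internal validity indices; with two clusters the one with the higher mean
percent-urban is labelled the high-development region (HDR), the other the
low-development region (LDR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

__all__ = ["ClusterResult", "standardize_features", "kmeans", "select_k",
           "classify_development"]

FEATURES = ["pct_urban", "edu_years", "gdp_per_capita"]


@dataclass
class ClusterResult:
    labels: np.ndarray
    centers: np.ndarray
    k: int
    inertia: float
    index_table: pd.DataFrame | None = None


def standardize_features(features: pd.DataFrame | np.ndarray):
    """Z-standardise each feature (sample SD, ddof=1).

    Returns ``(standardized, means, sds)`` so the transform can be
    inverted.  A zero-variance feature is an error: it carries no
    clustering information but would produce NaNs.
    """
    arr = np.asarray(features, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need a 2-D feature table with >= 2 locations")
    if np.any(~np.isfinite(arr)):
        raise ValueError("missing values in features")
    means = arr.mean(axis=0)
    sds = arr.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = np.where(sds == 0)[0]
        raise ValueError(f"zero-variance feature column(s): {bad.tolist()}")
    z = (arr - means) / sds
    if isinstance(features, pd.DataFrame):
        z = pd.DataFrame(z, index=features.index, columns=features.columns)
    return z, means, sds


def kmeans(features, k: int, seed: int, n_init: int = 25) -> ClusterResult:
    """Lloyd's algorithm from ``n_init`` random starts; best inertia kept."""
    arr = np.asarray(features, dtype=float)
    n_distinct = np.unique(arr, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct points")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(arr)
    return ClusterResult(
        labels=km.labels_.copy(),
        centers=km.cluster_centers_.copy(),
        k=k,
        inertia=float(km.inertia_),
    )


def select_k(features, k_range=range(2, 8), seed: int = 0,
             n_init: int = 25) -> tuple[int, pd.DataFrame]:
    """Choose the cluster count by majority vote of validity indices.

    For every candidate k the silhouette (higher better),
    Calinski-Harabasz (higher better) and Davies-Bouldin (lower better)
    indices are computed on the best-of-``n_init`` K-means solution; each
    index votes for its optimal k and ties break toward the smaller k.
    """
    ks = sorted(k_range)
    arr = np.asarray(features, dtype=float)
    n = arr.shape[0]
    if ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError("k_range must lie within [2, n_locations - 1]")
    if len(ks) == 1:
        return ks[0], pd.DataFrame({"k": ks})

    rows = []
    for k in ks:
        res = kmeans(arr, k, seed=seed, n_init=n_init)
        rows.append(
            {
                "k": k,
                "inertia": res.inertia,
                "silhouette": silhouette_score(arr, res.labels),
                "calinski_harabasz": calinski_harabasz_score(arr, res.labels),
                "davies_bouldin": davies_bouldin_score(arr, res.labels),
            }
        )
    table = pd.DataFrame(rows)
    votes = [
        int(table.loc[table["silhouette"].idxmax(), "k"]),
        int(table.loc[table["calinski_harabasz"].idxmax(), "k"]),
        int(table.loc[table["davies_bouldin"].idxmin(), "k"]),
    ]
    counts = pd.Series(votes).value_counts()
    best = int(min(counts[counts == counts.max()].index))
    return best, table


def classify_development(socio: pd.DataFrame, seed: int = 0,
                         k_range=range(2, 8), n_init: int = 25) -> pd.DataFrame:
    """End-to-end development classification of a socio metadata table.

    Standardises the three features, selects k, runs K-means, and appends
    a ``development_level`` column; when k == 2 the labels are "HDR"
    (higher mean percent-urban cluster) and "LDR", otherwise "C0".."Ck".
    """
    z, _, _ = standardize_features(socio[FEATURES])
    best_k, table = select_k(z, k_range=k_range, seed=seed, n_init=n_init)
    res = kmeans(np.asarray(z), best_k, seed=seed, n_init=n_init)
    out = socio.copy()
    if best_k == 2:
        urban_means = [
            socio.loc[res.labels == c, "pct_urban"].mean() for c in (0, 1)
        ]
        hdr_label = int(np.argmax(urban_means))
        out["development_level"] = np.where(res.labels == hdr_label, "HDR", "LDR")
    else:
        out["development_level"] = [f"C{c}" for c in res.labels]
    out.attrs["cluster_index_table"] = table
    out.attrs["cluster_k"] = best_k
    return out
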