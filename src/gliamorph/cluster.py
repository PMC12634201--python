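"""Unsupervised structure in morphometric space.

Ward hierarchical clustering (Euclidean distance) on the strongly bimodal
features (MMI at or above a threshold), with the number of clusters chosen
by the maximal mean silhouette over a scanned range, and a centred PCA
embedding whose first two components are expected to carry most of the
variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from sklearn.utils.validation import check_is_fitted

from .classify import validate_mmi_table


def select_features(mmi_table: pd.DataFrame, threshold: float = 0.5) -> list[str]:
    """Features whose MMI meets the threshold, in table order.

    Strong bimodality across the population is what makes a feature
    informative for separating discrete morphological states.
    """
    table = validate_mmi_table(mmi_table)
    chosen = [f for f, m in zip(table["feature"], table["mmi"]) if m >= threshold]
    if not chosen:
        raise ValueError(f"no features reach MMI threshold {threshold}")
    return chosen


def _normalize(X: np.ndarray, how: str) -> np.ndarray:
    if how == "zscore":
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        return (X - X.mean(axis=0)) / sd
    if how == "minmax":
        rng = np.ptp(X, axis=0)
        rng[rng == 0] = 1.0
        return (X - X.min(axis=0)) / rng
    if how in (None, "none"):
        return X
    raise ValueError("scale must be 'zscore', 'minmax' or 'none'")


class WardSilhouetteClusterer(ClusterMixin, BaseEstimator):
    """Agglomerative Ward clustering with silhouette-selected cluster count.

    ``fit`` builds the Ward merge tree on (by default z-scored) features,
    cuts it at every k in ``k_range``, scores each cut by mean silhouette,
    and keeps the labels at the maximizing k.

    Fitted attributes
    -----------------
    linkage_ : (n−1, 4) array — the merge tree (scipy linkage format).
    silhouette_by_k_ : dict k -> mean silhouette.
    k_ : selected number of clusters.
    labels_ : cluster ids in 1..k_.
    """

    def __init__(self, k_range: tuple[int, int] = (2, 8), scale: str = "zscore"):
        self.k_range = k_range
        self.scale = scale

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float) if not isinstance(X, pd.DataFrame) else X.to_numpy(float)
        n = X.shape[0]
        kmin, kmax = self.k_range
        if not (2 <= kmin <= kmax <= n - 1):
            raise ValueError(f"k_range {self.k_range} outside [2, {n - 1}]")
        Z = _normalize(X, self.scale)
        self.linkage_ = linkage(Z, method="ward", metric="euclidean")
        self.silhouette_by_k_ = {}
        best = None
        for k in range(kmin, kmax + 1):
            labels = fcluster(self.linkage_, t=k, criterion="maxclust")
            if len(np.unique(labels)) < 2:
                continue
            s = float(silhouette_score(Z, labels, metric="euclidean"))
            self.silhouette_by_k_[k] = s
            if best is None or s > best[0]:
                best = (s, k, labels)
        if best is None:
            raise ValueError("no valid cut in the scanned k range")
        self.silhouette_, self.k_, self.labels_ = best
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def cluster_cells(
    features: pd.DataFrame,
    k_range: tuple[int, int] = (2, 8),
    scale: str = "zscore",
) -> WardSilhouetteClusterer:
    """Thin functional wrapper over :class:`WardSilhouetteClusterer`."""
    return WardSilhouetteClusterer(k_range=k_range, scale=scale).fit(features)


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray

    def __post_init__(self):
        evr = np.asarray(self.explained_variance_ratio, dtype=float)
        if np.any(evr < -1e-12) or np.any(np.diff(evr) > 1e-12):
            raise ValueError("explained variance ratios must be nonnegative, non-increasing")
        object.__setattr__(self, "explained_variance_ratio", evr)


def pca_embed(
    features: pd.DataFrame,
    n_components: int | None = None,
    variance_floor: float = 0.70,
) -> PCAResult:
    """Centred PCA of the feature table.

    Warns when PC1+PC2 explain less than ``variance_floor`` of the
    variance, the adequacy bar for a two-component morphology map. Loading
    signs follow the convention that each component's largest-magnitude
    loading is positive, so embeddings are reproducible across runs.
    """
    if isinstance(features, pd.DataFrame):
        cols = list(features.columns)
        X = features.to_numpy(dtype=float)
        index = features.index
    else:
        X = np.asarray(features, dtype=float)
        cols = [f"feature_{i + 1}" for i in range(X.shape[1])]
        index = pd.RangeIndex(X.shape[0])
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 cells and 2 features")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate input: zero-rank data")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    comps = pca.components_
    # sign convention: largest-magnitude loading of each component positive
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
            scores[:, i] = -scores[:, i]
    evr = pca.explained_variance_ratio_
    if evr[: min(2, evr.size)].sum() < variance_floor:
        warnings.warn(
            f"first two components explain {evr[:2].sum():.2f} < {variance_floor:.2f} "
            "of the variance; a 2D embedding may be inadequate"
        )
    pc_names = [f"PC{i + 1}" for i in range(comps.shape[0])]
    return PCAResult(
        scores=pd.DataFrame(scores, columns=pc_names, index=index),
        loadings=pd.DataFrame(comps.T, columns=pc_names, index=cols),
        explained_variance_ratio=evr,
    )


def cluster_centroids(result: WardSilhouetteClusterer, scores: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster centroids in the PCA score space."""
    check_is_fitted(result, "labels_")
    df = scores.copy()
    df["cluster"] = result.labels_
    return df.groupby("cluster").mean()
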