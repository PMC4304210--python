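"""Chromatin-state clustering of region profiles and enhancer selection.

Regions are clustered into four states from their 21-bin x feature profiles
(log-transformed, per-feature max-normalized so no track dominates the
Euclidean metric).  Centroids are then named from their feature content:
the state with the strongest transcription-initiation + H3K4me3 signal is
the active promoter, the strongest remaining H3K4me1 centroid the enhancer,
and the two H3K27me3-marked states are split by their residual
H3K4me1/H3K4me3 levels.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

from enhdyn._constants import CHROMATIN_STATES, FEATURES

logger = logging.getLogger(__name__)


class ChromatinStateClassifier(ClusterMixin, BaseEstimator):
    """K-means over region profiles with semantic state labels.

    Parameters
    ----------
    n_clusters : int, default 4
        Number of chromatin states.
    n_init : int, default 50
        K-means restarts; the best inertia wins.
    random_state : int, default 17
        Seed for k-means++ initialization.
    features : tuple of str
        Feature names for the last profile axis, used by the labeling rules.

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (k, window_bins * n_features)
        Centroids in the transformed feature space.
    labels_ : ndarray of int
        Cluster index per training region.
    state_names_ : dict int -> str
        Semantic name per cluster (only when ``n_clusters == 4``).
    state_labels_ : ndarray of str
        Semantic label per training region.
    """

    def __init__(self, n_clusters=4, n_init=50, random_state=17, features=FEATURES):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.random_state = random_state
        self.features = features

    # -- internal ----------------------------------------------------------
    def _as_3d(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] % len(self.features):
                raise ValueError("flat profile width not divisible by feature count")
            X = X.reshape(X.shape[0], -1, len(self.features))
        if X.ndim != 3 or X.shape[2] != len(self.features):
            raise ValueError("expected profiles of shape (n, window_bins, n_features)")
        if np.any(X < 0):
            raise ValueError("profiles must be non-negative")
        return X

    def _transform(self, X3: np.ndarray, fit: bool) -> np.ndarray:
        Z = np.log2(1.0 + X3)
        if fit:
            scale = Z.reshape(-1, Z.shape[2]).max(axis=0)
            scale[scale == 0] = 1.0
            self.feature_scale_ = scale
        Z = Z / self.feature_scale_
        return Z.reshape(Z.shape[0], -1)

    # -- estimator API ------------------------------------------------------
    def fit(self, X, y=None):
        X3 = self._as_3d(X)
        if X3.shape[0] < self.n_clusters:
            raise ValueError(
                f"need at least {self.n_clusters} regions, got {X3.shape[0]}"
            )
        self.window_bins_ = X3.shape[1]
        Z = self._transform(X3, fit=True)
        km = KMeans(
            n_clusters=self.n_clusters,
            n_init=self.n_init,
            random_state=self.random_state,
        ).fit(Z)
        self.kmeans_ = km
        self.cluster_centers_ = km.cluster_centers_
        self.labels_ = km.labels_
        self.inertia_ = km.inertia_
        if self.n_clusters == len(CHROMATIN_STATES):
            self.state_names_ = label_state_clusters(
                self.cluster_centers_, self.window_bins_, self.features
            )
            self.state_labels_ = np.array(
                [self.state_names_[i] for i in self.labels_], dtype=object
            )
        return self

    def predict(self, X):
        check_is_fitted(self, "kmeans_")
        Z = self._transform(self._as_3d(X), fit=False)
        return self.kmeans_.predict(Z)

    def predict_states(self, X) -> np.ndarray:
        check_is_fitted(self, "state_names_")
        return np.array([self.state_names_[i] for i in self.predict(X)], dtype=object)


def _centroid_feature_means(
    centers: np.ndarray, window_bins: int, features
) -> np.ndarray:
    # k x n_features mean signal per feature over the window
    return centers.reshape(len(centers), window_bins, len(features)).mean(axis=1)


def label_state_clusters(
    centers: np.ndarray, window_bins: int, features=FEATURES
) -> dict[int, str]:
    """Name four centroids by their feature content.

    active_promoter: largest mean(TSS) + mean(H3K4me3); enhancer: largest
    mean(H3K4me1) among the rest; of the remaining two, the one with the
    higher residual H3K4me1 + H3K4me3 is repressed_1, the other (H3K27me3
    alone) repressed_2.  Ties break deterministically toward the lower
    centroid index.
    """
    if len(centers) != 4:
        raise ValueError("state labeling requires exactly 4 centroids")
    fm = _centroid_feature_means(centers, window_bins, features)
    col = {f: i for i, f in enumerate(features)}
    names: dict[int, str] = {}
    remaining = list(range(4))

    def take(score_vec: np.ndarray, label: str) -> None:
        scores = [score_vec[i] for i in remaining]
        if len(scores) > 1 and np.isclose(max(scores), sorted(scores)[-2]):
            warnings.warn(f"tie while labeling {label}; lower centroid index wins")
        idx = remaining[int(np.argmax(scores))]  # argmax -> lowest index on ties
        names[idx] = label
        remaining.remove(idx)

    take(fm[:, col["TSS"]] + fm[:, col["H3K4me3"]], "active_promoter")
    take(fm[:, col["H3K4me1"]], "enhancer")
    take(fm[:, col["H3K4me1"]] + fm[:, col["H3K4me3"]], "repressed_1")
    names[remaining.pop()] = "repressed_2"
    return names


def cluster_chromatin_states(
    profiles, k: int = 4, seed: int = 17, restarts: int = 50
) -> tuple[ChromatinStateClassifier, np.ndarray]:
    """Fit the chromatin-state model and return it with the assignments."""
    model = ChromatinStateClassifier(n_clusters=k, n_init=restarts, random_state=seed)
    model.fit(profiles)
    return model, model.labels_


def select_enhancers(regions, state_labels) -> np.ndarray:
    """Indices of regions labeled 'enhancer'; errors when none exist."""
    state_labels = np.asarray(state_labels, dtype=object)
    idx = np.flatnonzero(state_labels == "enhancer")
    if len(idx) == 0:
        raise ValueError("no regions labeled 'enhancer'; downstream analysis undefined")
    return idx
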