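"""Combinatorial TF-binding classes of enhancers and their dynamics.

Each enhancer gets, per principal TF and time point, the highest ChIP-seq
peak score whose peak center falls in the central 11 bins (+/-1.1 kb around
the region center); scores are capped at the binding threshold 26.9 and
scaled to [0, 1].  The pre-stimulation (0 h) vectors are clustered with
k-means, the number of classes chosen by the Gap statistic, classes named
H/M/L/C by how many TFs their centroid binds, and later time points are
re-assigned to the nearest 0 h centroid so class transitions can be
tabulated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

from enhdyn._constants import PRINCIPAL_TFS, SCORE_CAP

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# scoring


def enhancer_tf_score(
    center: int,
    peak_centers: np.ndarray,
    peak_scores: np.ndarray,
    bin_size: int = 200,
    n_central_bins: int = 11,
    cap: float = SCORE_CAP,
    scaled: bool = True,
) -> float:
    """Best peak score within the central bins of one enhancer.

    Peaks whose centers fall within ``n_central_bins * bin_size`` bases
    centered on the region center contribute; the maximum is capped at
    ``cap`` and, when ``scaled``, divided by it.  No peak in the window
    scores 0.
    """
    half = n_central_bins * bin_size / 2  # 1,100 bp for 11 x 200 bp
    peak_centers = np.asarray(peak_centers)
    peak_scores = np.asarray(peak_scores, dtype=float)
    inside = (peak_centers >= center - half) & (peak_centers < center + half)
    if not inside.any():
        return 0.0
    s = min(float(peak_scores[inside].max()), cap)
    return s / cap if scaled else s


def build_binding_vectors(
    enhancers: pd.DataFrame,
    peaks: pd.DataFrame,
    time: float,
    tfs=PRINCIPAL_TFS,
    bin_size: int = 200,
    n_central_bins: int = 11,
    cap: float = SCORE_CAP,
) -> tuple[np.ndarray, np.ndarray]:
    """Capped binding vectors for every enhancer at one time point.

    Returns ``(scaled, raw)``: scaled scores in [0, 1] for clustering and the
    capped raw scores (0-26.9) for binding-fraction summaries.  ``enhancers``
    needs ``chrom`` and ``center`` columns; ``peaks`` needs ``chrom``,
    ``center``, ``score``, ``tf`` and ``time``.
    """
    sub = peaks[peaks["time"] == time]
    raw = np.zeros((len(enhancers), len(tfs)))
    half = n_central_bins * bin_size / 2
    for j, tf in enumerate(tfs):
        ptf = sub[sub["tf"] == tf]
        for chrom, grp in ptf.groupby("chrom"):
            mask = enhancers["chrom"].to_numpy() == chrom
            if not mask.any():
                continue
            pc = np.sort(grp["center"].to_numpy())
            order = np.argsort(grp["center"].to_numpy(), kind="stable")
            ps = grp["score"].to_numpy()[order]
            # best score per window via cumulative max over sorted peaks
            centers = enhancers["center"].to_numpy()[mask]
            lo = np.searchsorted(pc, centers - half, side="left")
            hi = np.searchsorted(pc, centers + half, side="left")
            best = np.zeros(len(centers))
            for i, (a, b) in enumerate(zip(lo, hi)):
                if b > a:
                    best[i] = ps[a:b].max()
            raw[mask, j] = np.maximum(raw[mask, j], best)
    raw = np.minimum(raw, cap)
    return raw / cap, raw


# ---------------------------------------------------------------------------
# Gap statistic


@dataclass
class GapResult:
    k: int
    gaps: np.ndarray
    s_k: np.ndarray
    log_wk: np.ndarray


def gap_statistic_k(
    X,
    k_max: int = 20,
    B_refs: int = 50,
    seed: int = 0,
    n_init: int = 10,
) -> GapResult:
    """Choose k with the Gap statistic against uniform reference data.

    For each candidate k, ``Gap(k) = mean_b log(W_kb*) - log(W_k)`` where the
    B reference sets are drawn uniformly over the observed per-feature
    ranges.  The chosen k is the smallest with
    ``Gap(k) >= Gap(k+1) - s_{k+1}``, where ``s`` is the reference standard
    deviation inflated by ``sqrt(1 + 1/B)``.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) < k_max + 1:
        raise ValueError("need a 2-D matrix with more rows than k_max")
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)

    def log_wk(data: np.ndarray, k: int, rs: int) -> float:
        if k == 1:
            centroid = data.mean(axis=0)
            w = float(((data - centroid) ** 2).sum())
        else:
            km = KMeans(n_clusters=k, n_init=n_init, random_state=rs).fit(data)
            w = float(km.inertia_)
        return np.log(max(w, np.finfo(float).tiny))

    ks = np.arange(1, k_max + 2)  # one extra k for the stopping rule
    obs = np.array([log_wk(X, k, int(rng.integers(2**31))) for k in ks])
    ref = np.empty((B_refs, len(ks)))
    for b in range(B_refs):
        Xb = rng.uniform(lo, hi, size=X.shape)
        ref[b] = [log_wk(Xb, k, int(rng.integers(2**31))) for k in ks]
    gaps = ref.mean(axis=0) - obs
    s_k = ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B_refs)
    chosen = int(ks[-1])
    for i in range(len(ks) - 1):
        if gaps[i] >= gaps[i + 1] - s_k[i + 1]:
            chosen = int(ks[i])
            break
    return GapResult(k=chosen, gaps=gaps[:k_max], s_k=s_k[:k_max], log_wk=obs[:k_max])


# ---------------------------------------------------------------------------
# class model


class TFBindingClassifier(ClusterMixin, BaseEstimator):
    """K-means over 6-D capped/scaled TF-binding vectors at 0 h.

    With ``n_clusters=None`` the Gap statistic picks k (13 on the source
    study's data).  ``predict`` assigns any time point's vectors to the
    nearest 0 h centroid (Euclidean; ties to the lowest class index), so the
    0 h training partition is reproduced exactly.

    Attributes
    ----------
    cluster_centers_ : ndarray (k, n_tfs)
    labels_ : ndarray of int, nearest-centroid assignment of the training set
    class_names_ : list of str, e.g. ``H_1`` ... ``L_4`` / ``C_1``
    class_sizes_ : ndarray of int, training members per class
    gap_result_ : GapResult, present when k was chosen by the Gap statistic
    """

    def __init__(
        self,
        n_clusters: int | None = None,
        k_max: int = 20,
        gap_refs: int = 50,
        n_init: int = 50,
        random_state: int = 17,
        tfs=PRINCIPAL_TFS,
    ):
        self.n_clusters = n_clusters
        self.k_max = k_max
        self.gap_refs = gap_refs
        self.n_init = n_init
        self.random_state = random_state
        self.tfs = tfs

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.tfs):
            raise ValueError(f"expected (n, {len(self.tfs)}) binding vectors")
        if np.all(X == X[0]):
            raise ValueError("all binding vectors identical; clustering undefined")
        k = self.n_clusters
        if k is None:
            self.gap_result_ = gap_statistic_k(
                X, k_max=self.k_max, B_refs=self.gap_refs, seed=self.random_state
            )
            k = self.gap_result_.k
        km = KMeans(n_clusters=k, n_init=self.n_init, random_state=self.random_state)
        km.fit(X)
        self.kmeans_ = km
        self.cluster_centers_ = km.cluster_centers_
        # nearest-centroid partition of the training set (== converged k-means)
        self.labels_ = self.predict(X)
        self.class_sizes_ = np.bincount(self.labels_, minlength=k)
        self.class_names_ = name_classes(
            self.cluster_centers_, self.class_sizes_, self.tfs
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.cluster_centers_.shape[1]:
            raise ValueError("binding-vector dimension mismatch with fitted model")
        d2 = ((X[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)  # argmin -> lowest index on ties

    def predict_names(self, X) -> np.ndarray:
        check_is_fitted(self, "class_names_")
        return np.array([self.class_names_[i] for i in self.predict(X)], dtype=object)


def name_classes(centroids: np.ndarray, sizes, tfs=PRINCIPAL_TFS) -> list[str]:
    """Name classes by bound-TF count: H (>=4), M (2-3), L (<=1), C (CTCF).

    A TF is bound in a class when its centroid coordinate is >= 0.5 on the
    scaled [0, 1] axis (raw 13.45).  CTCF-bound classes form group C
    regardless of count.  Numeric suffixes run by descending class size
    within each group (ties by centroid index).
    """
    centroids = np.asarray(centroids, dtype=float)
    sizes = np.asarray(sizes)
    ctcf = list(tfs).index("CTCF") if "CTCF" in tfs else None
    groups = []
    for c in centroids:
        bound = c >= 0.5
        if ctcf is not None and bound[ctcf]:
            groups.append("C")
        else:
            n = int(bound.sum())
            groups.append("H" if n >= 4 else ("M" if n >= 2 else "L"))
    names = [""] * len(centroids)
    for g in sorted(set(groups)):
        members = [i for i, gg in enumerate(groups) if gg == g]
        members.sort(key=lambda i: (-int(sizes[i]), i))
        for rank, i in enumerate(members, start=1):
            names[i] = f"{g}_{rank}"
    return names


def fit_tf_classes(
    vectors, k: int | None = None, seed: int = 17, **kwargs
) -> TFBindingClassifier:
    """Fit the 0 h TF-class model (k from the Gap statistic when None)."""
    return TFBindingClassifier(n_clusters=k, random_state=seed, **kwargs).fit(vectors)


def assign_to_nearest_class(vectors, model: TFBindingClassifier) -> np.ndarray:
    """Assign vectors (any time point) to the nearest fitted 0 h centroid."""
    return model.predict(vectors)


# ---------------------------------------------------------------------------
# transitions and binding fractions


def class_transition_table(
    assign_from,
    assign_to,
    class_names: list[str] | None = None,
) -> pd.DataFrame:
    """K x K counts of class membership changes between consecutive times.

    Rows are the earlier class, columns the later; row sums equal the class
    sizes at the earlier time point and the grand total the enhancer count.
    """
    a, b = np.asarray(assign_from), np.asarray(assign_to)
    if a.shape != b.shape:
        raise ValueError("assignment arrays must cover the same enhancer universe")
    if class_names is None:
        k = int(max(a.max(initial=-1), b.max(initial=-1))) + 1
        class_names = [str(i) for i in range(k)]
        ai, bi = a, b
    else:
        lut = {n: i for i, n in enumerate(class_names)}
        ai = np.array([lut[x] for x in a]) if a.dtype == object else a
        bi = np.array([lut[x] for x in b]) if b.dtype == object else b
        k = len(class_names)
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (ai, bi), 1)
    return pd.DataFrame(counts, index=class_names, columns=class_names)


def fraction_bound(
    assignments,
    raw_scores,
    class_name: str,
    threshold: float = SCORE_CAP,
) -> float:
    """Percentage of class members with raw (capped) score >= threshold.

    Reported to one decimal, e.g. 2,026 bound of 4,470 -> 45.3.  An empty
    class yields NaN with a warning.
    """
    assignments = np.asarray(assignments, dtype=object)
    raw_scores = np.asarray(raw_scores, dtype=float)
    members = assignments == class_name
    n = int(members.sum())
    if n == 0:
        warnings.warn(f"class {class_name!r} is empty; fraction bound undefined")
        return float("nan")
    bound = int((raw_scores[members] >= threshold).sum())
    return round(100.0 * bound / n, 1)
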