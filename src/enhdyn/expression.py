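"""Gene expression processing: RPKM, quantile normalization, gene sets.

RPKM values per time point (0, 1, 4 h) are quantile-normalized; genes with
>= 3-fold change across the time points (and at least one time point above
1 RPKM) are clustered into four expression sets -- early induction, late
induction, gradual induction and repression -- by hierarchical clustering of
their z-scored log2 RPKM profiles, and a fixed-size "no change" control set
collects the genes with the smallest fold changes.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

EXPRESSION_SETS = (
    "early_induction",
    "late_induction",
    "gradual_induction",
    "repression",
)

#: Idealized z-scored log-expression shapes over (0 h, 1 h, 4 h) used to name
#: the four clusters: early = peak at 1 h sustained, late = rise only at 4 h,
#: gradual = monotone rise, repression = monotone fall.
_ARCHETYPES = {
    "early_induction": (0.0, 1.0, 0.8),
    "late_induction": (0.0, 0.0, 1.0),
    "gradual_induction": (0.0, 0.5, 1.0),
    "repression": (1.0, 0.5, 0.0),
}


def compute_rpkm(counts: pd.DataFrame, gene_lengths, total_reads=None) -> pd.DataFrame:
    """Reads per kilobase of gene model per million mapped reads.

    ``rpkm = count / (length/1e3) / (total/1e6)`` with totals defaulting to
    the column sums.  Zero or negative gene lengths are an error.
    """
    lengths = pd.Series(gene_lengths).reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("gene lengths missing for some genes")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    totals = counts.sum(axis=0) if total_reads is None else pd.Series(total_reads)
    if (totals <= 0).any():
        raise ValueError("total mapped reads must be positive")
    return counts.div(lengths / 1e3, axis=0).div(totals / 1e6, axis=1)


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Map every column onto the mean-of-order-statistics reference.

    After transformation all columns share an identical sorted value
    distribution while within-column ranks are preserved (ordinal rank for
    ties, making the transform idempotent).  Missing values are rejected.
    """

    def fit(self, X, y=None):
        X = self._check(X)
        self.reference_ = np.sort(X, axis=0).mean(axis=1)
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_")
        Xv = self._check(X)
        if Xv.shape[0] != len(self.reference_):
            raise ValueError("row count differs from the fitted reference")
        ranks = np.argsort(np.argsort(Xv, axis=0, kind="stable"), axis=0, kind="stable")
        out = self.reference_[ranks]
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out

    @staticmethod
    def _check(X) -> np.ndarray:
        Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        if Xv.ndim != 2 or Xv.shape[1] < 2:
            raise ValueError("need a matrix with at least two columns")
        if np.isnan(Xv).any():
            raise ValueError("missing values are not supported")
        return Xv


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    return QuantileNormalizer().fit_transform(matrix)


def _fold_ratio(matrix: pd.DataFrame, floor: float) -> pd.Series:
    vals = matrix.clip(lower=floor)
    return vals.max(axis=1) / vals.min(axis=1)


def differential_genes(
    matrix: pd.DataFrame, fold: float = 3.0, min_rpkm: float = 1.0, floor: float = 0.1
) -> pd.Index:
    """Genes with >= ``fold`` max/min ratio and a time point above ``min_rpkm``.

    Values are floored at ``floor`` RPKM so the ratio is defined at zero.
    """
    ratio = _fold_ratio(matrix, floor)
    keep = (ratio >= fold) & (matrix.max(axis=1) > min_rpkm)
    return matrix.index[keep]


def no_change_set(matrix: pd.DataFrame, n: int = 5000, floor: float = 0.1) -> pd.Index:
    """The ``n`` genes with the smallest fold changes (ties by gene id)."""
    ratio = _fold_ratio(matrix, floor)
    if len(matrix) < n:
        warnings.warn(f"only {len(matrix)} genes available; taking all")
        n = len(matrix)
    order = sorted(matrix.index, key=lambda g: (ratio.loc[g], str(g)))
    return pd.Index(order[:n])


def transient_1h_flags(matrix: pd.DataFrame) -> pd.Series:
    """Genes with > 2-fold higher RPKM at 1 h than at both 0 h and 4 h."""
    r0, r1, r4 = (matrix.iloc[:, i] for i in range(3))
    return (r1 > 2 * r0) & (r1 > 2 * r4)


class ExpressionSetClusterer(BaseEstimator):
    """Hierarchical clustering of differential genes into 4 labeled sets.

    Profiles are log2(RPKM + offset), z-scored per gene, clustered with
    average-linkage Euclidean hierarchical clustering and cut at 4 clusters.
    Cluster labels are assigned by maximal correlation of the cluster mean
    profile with the four archetype shapes under a bijective (Hungarian)
    matching, which is deterministic under ties.
    """

    def __init__(self, n_clusters: int = 4, offset: float = 0.1, linkage_method: str = "average"):
        self.n_clusters = n_clusters
        self.offset = offset
        self.linkage_method = linkage_method

    def fit(self, X, y=None):
        M = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        if M.ndim != 2 or len(M) < self.n_clusters:
            raise ValueError(f"need at least {self.n_clusters} gene profiles")
        L = np.log2(M + self.offset)
        sd = L.std(axis=1)
        if np.all(sd == 0):
            raise ValueError("all gene profiles are flat; expression sets undefined")
        Z = (L - L.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1.0, sd)[:, None]
        tree = linkage(Z, method=self.linkage_method, metric="euclidean")
        raw = fcluster(tree, t=self.n_clusters, criterion="maxclust") - 1
        if len(np.unique(raw)) < self.n_clusters:
            raise ValueError("degenerate profiles: fewer distinct clusters than requested")
        centers = np.stack([Z[raw == c].mean(axis=0) for c in range(self.n_clusters)])
        self.cluster_centers_ = centers
        self.set_names_ = self._match_archetypes(centers)
        self.raw_labels_ = raw
        self.labels_ = np.array([self.set_names_[c] for c in raw], dtype=object)
        return self

    @staticmethod
    def _match_archetypes(centers: np.ndarray) -> dict[int, str]:
        def z(v):
            v = np.asarray(v, dtype=float)
            s = v.std()
            return (v - v.mean()) / (s if s > 0 else 1.0)

        arch = {name: z(shape) for name, shape in _ARCHETYPES.items()}
        names = list(arch)
        corr = np.zeros((len(centers), len(names)))
        for i, c in enumerate(centers):
            zc = z(c)
            for j, name in enumerate(names):
                corr[i, j] = float(zc @ arch[name]) / len(zc)
        rows, cols = linear_sum_assignment(-corr)
        return {int(r): names[c] for r, c in zip(rows, cols)}


def cluster_expression_sets(log_matrix_input: pd.DataFrame) -> pd.Series:
    """Label differential genes with their expression set (RPKM input)."""
    model = ExpressionSetClusterer().fit(log_matrix_input)
    return pd.Series(model.labels_, index=log_matrix_input.index, name="set_label")


def average_probe_expression(
    intensities: pd.DataFrame,
    replicate_map: dict[str, str],
    probe_gene_map: dict[str, str],
    baseline: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Collapse probe x sample intensities to gene x condition means.

    Pre-normalized intensities are averaged over replicate samples of the
    same condition, then over probes of the same gene.  When ``baseline`` is
    given, a second table of ratios relative to that condition is returned
    (baseline column identically 1).  Genes without probes are absent.
    """
    cond = intensities.T.groupby(lambda s: replicate_map[s]).mean().T
    gene = cond.groupby(lambda p: probe_gene_map.get(p)).mean()
    gene = gene[gene.index.notna()]
    relative = None
    if baseline is not None:
        relative = gene.div(gene[baseline], axis=0)
    return gene, relative
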