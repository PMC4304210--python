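"""Enhancer-to-gene assignment and class enrichment around gene sets.

Every enhancer is naively assigned to the most proximal gene by the base
distance between the enhancer center and the gene TSS (same chromosome
only).  For a gene set, the number of assigned enhancers per TF-binding
class is compared with the counts expected under random shuffles of the
class labels, summarized as a Z-score per (gene set, class) pair.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def assign_enhancer_to_gene(
    enhancers: pd.DataFrame, genes: pd.DataFrame
) -> pd.DataFrame:
    """Nearest gene per enhancer by |enhancer center - gene TSS|.

    Ties break toward the lexicographically smallest gene id; enhancers on a
    chromosome without genes stay unassigned (NaN gene, logged).  Returns a
    table of enhancer id, gene id and signed distance (center - TSS).
    ``enhancers`` needs ``region_id``/``chrom``/``center``; ``genes`` needs
    ``gene_id``/``chrom``/``tss``.
    """
    if genes.empty:
        raise ValueError("need at least one gene")
    out = []
    for chrom, enh in enhancers.groupby("chrom", sort=False):
        g = genes[genes["chrom"] == chrom]
        if g.empty:
            logger.warning("%d enhancers on %s have no genes; unassigned", len(enh), chrom)
            for r in enh.itertuples():
                out.append((r.region_id, None, np.nan))
            continue
        # collapse duplicate TSS positions to their lexicographically smallest id
        rep = g.groupby("tss")["gene_id"].min().sort_index()
        tss = rep.index.to_numpy(dtype=np.int64)
        ids = rep.to_numpy(dtype=object)
        centers = enh["center"].to_numpy(dtype=np.int64)
        right = np.searchsorted(tss, centers)
        left = np.clip(right - 1, 0, len(tss) - 1)
        right = np.clip(right, 0, len(tss) - 1)
        for rid, c, li, ri in zip(enh["region_id"], centers, left, right):
            dl, dr = abs(int(c) - int(tss[li])), abs(int(c) - int(tss[ri]))
            if dl < dr:
                gi = li
            elif dr < dl:
                gi = ri
            else:
                gi = li if str(ids[li]) <= str(ids[ri]) else ri
            out.append((rid, ids[gi], int(c) - int(tss[gi])))
    return pd.DataFrame(out, columns=["region_id", "gene_id", "distance"])


def observed_class_counts(
    assignment: pd.DataFrame,
    gene_set,
    class_labels: pd.Series,
    classes: list[str] | None = None,
) -> pd.Series:
    """Count, per class, the enhancers whose nearest gene lies in the set.

    ``class_labels`` is indexed by enhancer ``region_id``; unassigned
    enhancers are excluded.
    """
    gene_set = set(gene_set)
    assigned = assignment.dropna(subset=["gene_id"])
    in_set = assigned[assigned["gene_id"].isin(gene_set)]
    labels = class_labels.loc[in_set["region_id"]]
    counts = labels.value_counts()
    if classes is None:
        classes = sorted(class_labels.unique())
    return counts.reindex(classes, fill_value=0).astype(int)


def permutation_enrichment(
    assignment: pd.DataFrame,
    gene_set,
    class_labels: pd.Series,
    n_perm: int = 100,
    seed: int = 0,
    classes: list[str] | None = None,
) -> pd.DataFrame:
    """Z-scores of observed class counts vs label-shuffled expectations.

    Class labels are permuted across the whole enhancer universe (the
    gene assignment stays fixed) ``n_perm`` times; for each class,
    ``Z = (observed - mean_perm) / sd_perm`` with the sample standard
    deviation.  A zero permutation sd leaves Z as NaN (flagged).  With the
    default 100 permutations the sd estimate is coarse; increase ``n_perm``
    for stable Z values.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    if classes is None:
        classes = sorted(class_labels.unique())
    if len(classes) < 2:
        warnings.warn("single-class labeling; enrichment is degenerate")
    rng = np.random.default_rng(seed)
    assigned = assignment.dropna(subset=["gene_id"])
    labels = class_labels.loc[assigned["region_id"]].to_numpy(dtype=object)
    in_set = assigned["gene_id"].isin(set(gene_set)).to_numpy()
    lut = {c: i for i, c in enumerate(classes)}
    codes = np.array([lut[x] for x in labels])
    observed = np.bincount(codes[in_set], minlength=len(classes))
    perm_counts = np.empty((n_perm, len(classes)), dtype=np.int64)
    for b in range(n_perm):
        shuffled = codes[rng.permutation(len(codes))]
        perm_counts[b] = np.bincount(shuffled[in_set], minlength=len(classes))
    mean = perm_counts.mean(axis=0)
    sd = perm_counts.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (observed - mean) / sd, np.nan)
    if np.any(sd == 0):
        warnings.warn("zero permutation sd for some classes; Z undefined there")
    return pd.DataFrame(
        {
            "class": classes,
            "observed": observed,
            "expected_mean": mean,
            "expected_sd": sd,
            "z": z,
        }
    )


def enrichment_table(
    assignment: pd.DataFrame,
    gene_sets: dict[str, list],
    class_labels: pd.Series,
    n_perm: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Per (gene set, class) enrichment Z-scores, one permutation run each."""
    frames = []
    for i, (name, genes) in enumerate(gene_sets.items()):
        res = permutation_enrichment(
            assignment, genes, class_labels, n_perm=n_perm, seed=seed + i
        )
        res.insert(0, "gene_set", name)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)
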