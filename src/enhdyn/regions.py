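"""Genomic region discovery from binned tag tracks.

Tags are counted in 200-bp bins (ChIP reads shifted 75 bp in the 3'
direction, TSS-seq binned per strand); bins enriched over a genome-wide
Poisson background at p <= 1e-6 are merged across features into candidate
regions when separated by less than 500 bp.  Each region gets a weighted
central bin, an oriented 21-bin x feature profile of ppm-normalized counts
(4.2 kb total), a genomic annotation, and regions supported only by TSS-seq
are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from enhdyn._constants import FEATURES
from enhdyn.simulate import TagTrack

logger = logging.getLogger(__name__)


@dataclass
class PeakCallParams:
    bin_size: int = 200
    step: int = 200
    chip_shift: int = 75
    p_threshold: float = 1e-6
    merge_gap: int = 500
    flank_bins: int = 10
    tss_strand_specific: bool = True

    def __post_init__(self) -> None:
        if self.bin_size <= 0 or self.step != self.bin_size:
            raise ValueError("bin_size must be positive and equal to step")
        if self.flank_bins < 0:
            raise ValueError("flank_bins must be >= 0")
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must lie in (0, 1)")

    @property
    def window_bins(self) -> int:
        return 2 * self.flank_bins + 1


@dataclass
class BinnedTrack:
    """Per-chromosome tag counts per bin for one feature track.

    For strand-specific tracks (TSS-seq) per-strand counts are retained;
    ``counts`` always holds the strand-summed totals.
    """

    feature: str
    counts: dict[str, np.ndarray]
    total: int
    stranded: bool = False
    strand_counts: dict[str, dict[str, np.ndarray]] | None = None

    @property
    def ppm_factor(self) -> float:
        # counts x 1e6 / total mapped tags
        return 1e6 / self.total if self.total > 0 else 0.0

    @property
    def n_bins(self) -> int:
        return int(sum(len(v) for v in self.counts.values()))


@dataclass
class CandidateRegion:
    chrom: str
    bins: np.ndarray  # significant bin indices of the merged run
    sig_features: dict[str, bool]
    center_bin: int | None = None
    start: int | None = None  # 21-bin window, 0-based half-open
    end: int | None = None
    strand: str = "+"

    def window(self, params: PeakCallParams) -> tuple[int, int]:
        c = self.center_bin
        return (
            (c - params.flank_bins) * params.bin_size,
            (c + params.flank_bins + 1) * params.bin_size,
        )


def bin_tag_counts(
    track: TagTrack,
    chrom_lengths: Mapping[str, int],
    params: PeakCallParams,
    is_chip: bool,
) -> BinnedTrack:
    """Count read 5' ends in fixed bins, shifting ChIP reads 75 bp 3'-ward.

    Plus-strand ChIP reads shift by ``+chip_shift``, minus-strand by
    ``-chip_shift``.  Positions falling outside the chromosome after the
    shift are clamped to the terminal bin (with a warning).  TSS-seq tracks
    are binned per strand when ``params.tss_strand_specific`` is set.
    """
    reads = track.reads
    stranded = (not is_chip) and params.tss_strand_specific
    counts: dict[str, np.ndarray] = {}
    strand_counts: dict[str, dict[str, np.ndarray]] = {}
    total = 0
    for chrom, length in chrom_lengths.items():
        n_bins = length // params.bin_size
        sub = reads[reads["chrom"] == chrom]
        pos = sub["pos"].to_numpy(dtype=np.int64)
        strand = sub["strand"].to_numpy()
        if is_chip and len(pos):
            pos = pos + np.where(strand == "+", params.chip_shift, -params.chip_shift)
        if len(pos) and (pos.min() < 0 or pos.max() >= n_bins * params.bin_size):
            n_out = int(((pos < 0) | (pos >= n_bins * params.bin_size)).sum())
            logger.warning(
                "%s: %d reads outside %s after shift; clamped to terminal bins",
                track.feature, n_out, chrom,
            )
            pos = np.clip(pos, 0, n_bins * params.bin_size - 1)
        idx = pos // params.bin_size
        if stranded:
            per = {
                s: np.bincount(idx[strand == s], minlength=n_bins).astype(np.int64)
                for s in ("+", "-")
            }
            strand_counts[chrom] = per
            counts[chrom] = per["+"] + per["-"]
        else:
            counts[chrom] = np.bincount(idx, minlength=n_bins).astype(np.int64)
        total += len(pos)
    return BinnedTrack(
        feature=track.feature,
        counts=counts,
        total=total,
        stranded=stranded,
        strand_counts=strand_counts if stranded else None,
    )


def poisson_bin_pvalue(count: int, lam: float) -> float:
    """Upper-tail Poisson probability ``P(X >= count)`` for ``X ~ Poisson(lam)``."""
    if lam <= 0:
        raise ValueError("lam must be > 0")
    if count < 0:
        raise ValueError("count must be >= 0")
    return float(stats.poisson.sf(count - 1, lam))


def call_significant_bins(
    binned: BinnedTrack, params: PeakCallParams
) -> dict[str, np.ndarray]:
    """Bins whose count clears the Poisson background at ``p_threshold``.

    The background rate is genome-wide: total mapped tags divided by the
    total number of bins (per strand for strand-specific tracks; a bin is
    then significant if either strand is).  Returns sorted significant bin
    indices per chromosome.
    """
    n_bins_total = binned.n_bins
    out: dict[str, np.ndarray] = {}
    if binned.total == 0 or n_bins_total == 0:
        logger.warning("%s: empty track, no significant bins", binned.feature)
        return {c: np.array([], dtype=np.int64) for c in binned.counts}
    if binned.stranded and binned.strand_counts is not None:
        lam = {
            s: sum(int(v[s].sum()) for v in binned.strand_counts.values()) / n_bins_total
            for s in ("+", "-")
        }
        for chrom, per in binned.strand_counts.items():
            sig = np.zeros(len(per["+"]), dtype=bool)
            for s in ("+", "-"):
                if lam[s] <= 0:
                    continue
                # significant iff P(X >= count) <= threshold
                pv = stats.poisson.sf(per[s] - 1, lam[s])
                sig |= pv <= params.p_threshold
            out[chrom] = np.flatnonzero(sig).astype(np.int64)
    else:
        lam_track = binned.total / n_bins_total
        for chrom, c in binned.counts.items():
            pv = stats.poisson.sf(c - 1, lam_track)
            out[chrom] = np.flatnonzero(pv <= params.p_threshold).astype(np.int64)
    return out


def merge_into_regions(
    sig_bins: Mapping[str, Mapping[str, np.ndarray]],
    params: PeakCallParams,
) -> list[CandidateRegion]:
    """Merge significant bins across features into candidate regions.

    Takes the union of significant bins over all feature tracks per
    chromosome and merges consecutive runs whose separating gap is strictly
    less than ``merge_gap`` bases.  Each merged run becomes one candidate
    region carrying per-feature significance flags.
    """
    features = list(sig_bins)
    chroms = sorted({c for f in features for c in sig_bins[f]})
    regions: list[CandidateRegion] = []
    for chrom in chroms:
        per_feature = {f: set(map(int, sig_bins[f].get(chrom, ()))) for f in features}
        union = np.array(sorted(set().union(*per_feature.values())), dtype=np.int64)
        if len(union) == 0:
            continue
        # gap between bin i and j (j > i) is (j - i - 1) * bin_size bases
        breaks = np.flatnonzero(
            (np.diff(union) - 1) * params.bin_size >= params.merge_gap
        )
        for run in np.split(union, breaks + 1):
            flags = {f: bool(per_feature[f] & set(map(int, run))) for f in features}
            regions.append(CandidateRegion(chrom=chrom, bins=run, sig_features=flags))
    return regions


def locate_center_and_profile(
    region: CandidateRegion,
    binned_tracks: Mapping[str, BinnedTrack],
    params: PeakCallParams,
) -> np.ndarray | None:
    """Set the region's central bin and return its 21-bin x feature profile.

    The central bin is the ppm-weighted average of the merged run's bin
    indices (weights summed over all feature tracks), rounded half-up; with
    zero total weight the geometric midpoint is used.  Returns the profile
    matrix (window_bins x features, ppm units) or ``None`` when the window
    would extend past a chromosome edge (such regions are dropped).
    """
    chrom = region.chrom
    feats = list(binned_tracks)
    weights = np.zeros(len(region.bins))
    for bt in binned_tracks.values():
        weights += bt.counts[chrom][region.bins] * bt.ppm_factor
    if weights.sum() > 0:
        center = int(np.floor(np.sum(weights * region.bins) / weights.sum() + 0.5))
    else:
        logger.warning("%s: zero-weight region at bins %s; using midpoint",
                       chrom, region.bins[:3])
        center = int(np.floor((region.bins[0] + region.bins[-1]) / 2 + 0.5))
    region.center_bin = center
    n_bins = len(next(iter(binned_tracks.values())).counts[chrom])
    lo, hi = center - params.flank_bins, center + params.flank_bins + 1
    if lo < 0 or hi > n_bins:
        logger.info("%s: window around bin %d truncated at chromosome edge; dropped",
                    chrom, center)
        return None
    region.start, region.end = region.window(params)
    profile = np.column_stack(
        [binned_tracks[f].counts[chrom][lo:hi] * binned_tracks[f].ppm_factor for f in feats]
    )
    return profile


def orient_and_filter(
    regions: list[CandidateRegion],
    profiles: list[np.ndarray],
    tss_binned: BinnedTrack | None,
    params: PeakCallParams,
    tss_feature: str = "TSS",
) -> tuple[list[CandidateRegion], list[np.ndarray]]:
    """Orient regions by TSS strand majority and drop TSS-only regions.

    A region is oriented '-' when the majority of TSS-seq tags in its window
    map to the minus strand (profile bin order is then reversed); ties and
    regions without TSS tags default to '+'.  Regions whose only significant
    feature is TSS-seq (no histone modification support) are removed.
    """
    kept_r, kept_p = [], []
    for region, profile in zip(regions, profiles):
        non_tss = [f for f, v in region.sig_features.items() if v and f != tss_feature]
        if region.sig_features.get(tss_feature) and not non_tss:
            continue
        if tss_binned is not None and tss_binned.stranded and tss_binned.strand_counts:
            per = tss_binned.strand_counts.get(region.chrom)
            if per is not None:
                lo = region.center_bin - params.flank_bins
                hi = region.center_bin + params.flank_bins + 1
                plus = int(per["+"][lo:hi].sum())
                minus = int(per["-"][lo:hi].sum())
                if minus > plus:
                    region.strand = "-"
                    profile = profile[::-1].copy()
        kept_r.append(region)
        kept_p.append(profile)
    return kept_r, kept_p


# ---------------------------------------------------------------------------
# annotation

ANNOTATION_PRECEDENCE = ("TSS", "five_prime_utr", "three_prime_utr", "exon", "intron")


class GeneAnnotator:
    """Annotates intervals against gene models with a fixed precedence.

    Labels, in order of preference: TSS (within ``tss_window`` bp of an
    annotated gene TSS), 5' UTR, 3' UTR, exon, intron; anything else is
    intergenic.
    """

    def __init__(self, genes: pd.DataFrame, features: pd.DataFrame, tss_window: int = 500):
        self.tss_window = tss_window
        self._trees: dict[str, dict[str, IntervalTree]] = {}

        def add(label: str, chrom: str, start: int, end: int) -> None:
            if end <= start:
                return
            self._trees.setdefault(chrom, {}).setdefault(label, IntervalTree()).addi(
                start, end
            )

        for g in genes.itertuples():
            if not {"gene_id", "chrom", "start", "end", "tss"} <= set(genes.columns):
                raise ValueError("malformed gene model table (missing columns)")
            add("TSS", g.chrom, int(g.tss) - tss_window, int(g.tss) + tss_window + 1)
        for f in features.itertuples():
            if f.feature == "exon":
                add("exon", f.chrom, int(f.start), int(f.end))
            elif f.feature in ("five_prime_utr", "three_prime_utr"):
                add(f.feature, f.chrom, int(f.start), int(f.end))
        # introns: gene span minus exons
        for gid, grp in features[features["feature"] == "exon"].groupby("gene_id"):
            grp = grp.sort_values("start")
            ends = grp["end"].to_numpy()
            starts = grp["start"].to_numpy()
            chrom = grp["chrom"].iloc[0]
            for s, e in zip(ends[:-1], starts[1:]):
                add("intron", chrom, int(s), int(e))

    def annotate(self, chrom: str, start: int, end: int) -> str:
        trees = self._trees.get(chrom, {})
        for label in ANNOTATION_PRECEDENCE:
            tree = trees.get(label)
            if tree is not None and tree.overlap(start, end):
                return "TSS" if label == "TSS" else label
        return "intergenic"


def annotate_region(region: CandidateRegion, annotator: GeneAnnotator) -> str:
    """First matching genomic label in precedence order, else 'intergenic'."""
    if region.start is None:
        raise ValueError("region has no located window; run locate_center_and_profile")
    return annotator.annotate(region.chrom, region.start, region.end)


# ---------------------------------------------------------------------------
# sequence composition


def compute_gc_cpg(sequence: str, bin_size: int = 200) -> pd.DataFrame:
    """Per-bin GC fraction and CpG score (observed/expected CpG).

    GC = (#G + #C) / bin length; expected CpG = (#C * #G) / bin length;
    score = observed CpG dinucleotides / expected (0 when the expectation is
    zero).  Ambiguous bases count toward the length but not the numerators.
    """
    if len(sequence) < bin_size:
        raise ValueError("sequence shorter than one bin")
    seq = sequence.upper()
    rows = []
    for i in range(0, len(seq) - bin_size + 1, bin_size):
        s = seq[i : i + bin_size]
        g, c = s.count("G"), s.count("C")
        obs = s.count("CG")
        exp = c * g / len(s)
        rows.append(
            {
                "bin_start": i,
                "gc": (g + c) / len(s),
                "cpg_score": (obs / exp) if exp > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration


def discover_regions(
    tracks: Mapping[str, TagTrack],
    chrom_lengths: Mapping[str, int],
    params: PeakCallParams | None = None,
    annotator: GeneAnnotator | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Full discovery pass: bin, call, merge, center, orient, annotate.

    Returns a region table and the stacked profile array
    ``(n_regions, window_bins, n_features)`` with features ordered as in the
    ``tracks`` mapping.
    """
    params = params or PeakCallParams()
    feats = list(tracks)
    binned = {
        f: bin_tag_counts(tracks[f], chrom_lengths, params, is_chip=(f != "TSS"))
        for f in feats
    }
    sig = {f: call_significant_bins(binned[f], params) for f in feats}
    candidates = merge_into_regions(sig, params)
    regions, profiles = [], []
    for r in candidates:
        p = locate_center_and_profile(r, binned, params)
        if p is not None:
            regions.append(r)
            profiles.append(p)
    regions, profiles = orient_and_filter(
        regions, profiles, binned.get("TSS"), params
    )
    rows = []
    for i, r in enumerate(regions):
        row = {
            "region_id": f"d{i:05d}",
            "chrom": r.chrom,
            "center_bin": r.center_bin,
            "center": r.center_bin * params.bin_size + params.bin_size // 2,
            "start": r.start,
            "end": r.end,
            "strand": r.strand,
        }
        for f in feats:
            row[f"sig_{f}"] = r.sig_features.get(f, False)
        if annotator is not None:
            row["annotation"] = annotate_region(r, annotator)
        rows.append(row)
    table = pd.DataFrame(rows)
    stack = (
        np.stack(profiles)
        if profiles
        else np.empty((0, params.window_bins, len(feats)))
    )
    return table, stack
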