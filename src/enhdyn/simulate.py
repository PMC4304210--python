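"""Seeded synthetic genomes, tag tracks, TF peak tables and expression data.

The generator plants the statistical structure the downstream analysis
assumes and records it as ground truth:

* a genome of non-overlapping gene models (TSS, UTRs, exons, introns);
* regions of four chromatin states, each enriching its signature feature
  tracks over a Poisson background (active promoters carry H3K4me3 and
  strand-specific transcription initiation, enhancers H3K4me1, the two
  repressed states H3K27me3 with or without residual H3K4me1/H3K4me3);
* combinatorial TF-binding classes at enhancers, with class transitions at
  configurable time intervals that may be spatially clustered near existing
  target-class enhancers;
* gene expression time courses with induction/repression archetypes, where
  genes nearest highly bound enhancers are induced with a configurable
  linkage probability.

All randomness flows from ``SimulationConfig.seed``; a fixed seed gives
bit-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from enhdyn._constants import (
    CHROMATIN_STATES,
    EXPR_TIME_POINTS,
    FEATURES,
    PRINCIPAL_TFS,
    SCORE_CAP,
    TF_TIME_POINTS,
)

logger = logging.getLogger(__name__)

BIN_SIZE = 200

#: Qualitative binding design of the 13 TF-combination classes: which of the
#: six principal TFs bind each class.  H classes are bound by >=4 TFs, M by
#: 2-3, L by <=1 and C classes by CTCF.  Bound TFs receive mean peak score
#: equal to the binding threshold (26.9), unbound TFs mean 0.
DEFAULT_CLASS_TFS: dict[str, tuple[str, ...]] = {
    "H_1": ("PU.1", "CEBPB", "ATF3", "IRF4", "JUNB"),
    "H_2": ("PU.1", "CEBPB", "ATF3", "JUNB"),
    "H_3": ("PU.1", "CEBPB", "IRF4", "JUNB"),
    "M_1": ("PU.1", "ATF3", "JUNB"),
    "M_2": ("PU.1", "CEBPB", "JUNB"),
    "M_3": ("PU.1", "CEBPB"),
    "L_1": ("PU.1",),
    "L_2": ("CEBPB",),
    "L_3": ("JUNB",),
    "L_4": (),
    "C_1": ("PU.1", "CEBPB", "CTCF"),
    "C_2": ("PU.1", "CTCF"),
    "C_3": ("CTCF",),
}


def _default_profiles() -> dict[str, dict[str, float]]:
    return {
        cls: {tf: (SCORE_CAP if tf in bound else 0.0) for tf in PRINCIPAL_TFS}
        for cls, bound in DEFAULT_CLASS_TFS.items()
    }


# Per chromatin state, which feature tracks are enriched in planted bins and
# at what multiple of the configured enrichment rate.
STATE_SIGNATURES: dict[str, dict[str, float]] = {
    "active_promoter": {"H3K4me3": 1.0, "TSS": 1.0, "H3K4me1": 0.25},
    "enhancer": {"H3K4me1": 1.0},
    "repressed_1": {"H3K27me3": 1.0, "H3K4me1": 0.25, "H3K4me3": 0.15},
    "repressed_2": {"H3K27me3": 1.0},
}

#: Default class transitions after stimulation, as
#: (from_class, to_class, interval index, fraction, spatially clustered).
#: Interval i covers consecutive TF time points (t_i, t_{i+1}).
DEFAULT_TRANSITIONS: list[tuple[str, str, int, float, bool]] = [
    ("H_1", "H_3", 0, 0.23, True),
    ("H_1", "H_2", 1, 0.27, True),
    ("H_2", "H_1", 2, 0.48, True),
    ("H_3", "H_1", 2, 0.30, True),
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class SizingError(ConfigError):
    """The requested layout does not fit in the configured genome."""


@dataclass
class Transition:
    from_class: str
    to_class: str
    interval: int
    fraction: float
    spatially_clustered: bool = False


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    Rates are expected tags per 200-bp bin.  ``n_regions_per_state`` may be a
    single integer (applied to each chromatin state) or a mapping keyed by
    state name.  ``class_binding_profiles`` maps TF-class name -> TF -> mean
    peak score on the 0-26.9 scale.  ``expression_link`` is the probability
    that the gene nearest a planted highly bound (group H) enhancer is
    induced after stimulation.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 5_000_000
    background_rate: float = 1.0
    enrichment_rate: float = 20.0
    region_width_bins: int = 5
    n_regions_per_state: int | Mapping[str, int] = field(
        default_factory=lambda: {
            "active_promoter": 60,
            "enhancer": 260,
            "repressed_1": 60,
            "repressed_2": 60,
        }
    )
    class_binding_profiles: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_profiles
    )
    score_sigma: float = 3.0
    transition_spec: Sequence[Transition | tuple] = field(
        default_factory=lambda: list(DEFAULT_TRANSITIONS)
    )
    expression_link: float = 0.5
    n_genes: int = 300
    induced_set_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "early_induction": 0.08,
            "late_induction": 0.06,
            "gradual_induction": 0.06,
            "repression": 0.06,
        }
    )

    @property
    def n_enhancer_classes(self) -> int:
        return len(self.class_binding_profiles)

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(self.class_binding_profiles)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chromosomes)}

    def regions_for(self, state: str) -> int:
        if isinstance(self.n_regions_per_state, Mapping):
            return int(self.n_regions_per_state.get(state, 0))
        return int(self.n_regions_per_state)

    @property
    def transitions(self) -> list[Transition]:
        out = []
        for t in self.transition_spec:
            out.append(t if isinstance(t, Transition) else Transition(*t))
        return out

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length < BIN_SIZE:
            raise ConfigError("need at least one chromosome of >= one bin")
        if self.background_rate < 0:
            raise ConfigError("background_rate must be >= 0")
        if self.enrichment_rate < self.background_rate:
            raise ConfigError("enrichment_rate must be >= background_rate")
        if not 0.0 <= self.expression_link <= 1.0:
            raise ConfigError("expression_link must lie in [0, 1]")
        for cls, prof in self.class_binding_profiles.items():
            for tf, mu in prof.items():
                if tf not in PRINCIPAL_TFS:
                    raise ConfigError(f"unknown TF {tf!r} in class {cls!r}")
                if not 0.0 <= mu <= SCORE_CAP:
                    raise ConfigError(
                        f"class {cls!r} mean for {tf} outside [0, {SCORE_CAP}]"
                    )
        for tr in self.transitions:
            if tr.from_class not in self.class_binding_profiles:
                raise ConfigError(f"transition from unknown class {tr.from_class!r}")
            if tr.to_class not in self.class_binding_profiles:
                raise ConfigError(f"transition to unknown class {tr.to_class!r}")
            if not 0.0 <= tr.fraction <= 1.0:
                raise ConfigError("transition fraction must lie in [0, 1]")
            if not 0 <= tr.interval < len(TF_TIME_POINTS) - 1:
                raise ConfigError(f"transition interval {tr.interval} out of range")

    def _rng(self, stage: int) -> np.random.Generator:
        # Independent, reproducible stream per pipeline stage.
        return np.random.default_rng([int(self.seed), stage])


@dataclass
class Genome:
    """Gene models on named chromosomes (0-based, half-open coordinates)."""

    chrom_lengths: dict[str, int]
    genes: pd.DataFrame  # gene_id, chrom, start, end, strand, tss
    features: pd.DataFrame  # gene_id, chrom, feature, start, end, strand


@dataclass
class TagTrack:
    """Mapped read 5'-end positions with strand for one feature track."""

    feature: str
    reads: pd.DataFrame  # chrom, pos, strand

    @property
    def total(self) -> int:
        return len(self.reads)


@dataclass
class SyntheticTruth:
    """Planted ground truth, sufficient for every downstream recovery metric."""

    regions: pd.DataFrame  # region_id, chrom, center, start, end, state, strand
    classes_by_time: dict[float, list[str]]  # per enhancer (regions order)
    enhancer_ids: list[str]
    transitions: pd.DataFrame  # region_id, from_class, to_class, interval
    gene_sets: pd.DataFrame | None = None  # gene_id, set_label, linked

    @property
    def enhancers(self) -> pd.DataFrame:
        return self.regions[self.regions["state"] == "enhancer"].reset_index(drop=True)

    def to_json(self) -> str:
        payload = {
            "regions": self.regions.to_dict(orient="list"),
            "classes_by_time": {str(t): c for t, c in self.classes_by_time.items()},
            "enhancer_ids": list(self.enhancer_ids),
            "transitions": self.transitions.to_dict(orient="list"),
            "gene_sets": None
            if self.gene_sets is None
            else self.gene_sets.to_dict(orient="list"),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        payload = json.loads(text)
        return cls(
            regions=pd.DataFrame(payload["regions"]),
            classes_by_time={
                float(t): list(c) for t, c in payload["classes_by_time"].items()
            },
            enhancer_ids=list(payload["enhancer_ids"]),
            transitions=pd.DataFrame(
                payload["transitions"],
                columns=["region_id", "from_class", "to_class", "interval"],
            ),
            gene_sets=None
            if payload["gene_sets"] is None
            else pd.DataFrame(payload["gene_sets"]),
        )


@dataclass
class ExpressionData:
    counts: pd.DataFrame  # gene x time point, integer read counts
    gene_lengths: pd.Series
    total_reads: pd.Series


@dataclass
class SimulationResult:
    config: SimulationConfig
    genome: Genome
    truth: SyntheticTruth
    tracks: dict[str, TagTrack]
    peaks: pd.DataFrame
    expression: ExpressionData


# ---------------------------------------------------------------------------
# genome


def generate_genome(config: SimulationConfig) -> Genome:
    """Lay out non-overlapping gene models with TSS, UTRs, exons and introns.

    Gene structure is drawn gene by gene (2-5 exons of 200-1,500 bp separated
    by introns of 200-5,000 bp, UTRs carved from the terminal exons); genes
    are then packed into each chromosome with random inter-genic gaps.
    Raises :class:`SizingError` when the chromosome cannot hold its share of
    genes.
    """
    config.validate()
    rng = config._rng(0)
    chroms = list(config.chrom_lengths)
    per_chrom = [config.n_genes // len(chroms)] * len(chroms)
    for i in range(config.n_genes % len(chroms)):
        per_chrom[i] += 1

    gene_rows, feat_rows = [], []
    gid = 0
    for chrom, n_here in zip(chroms, per_chrom):
        length = config.chrom_lengths[chrom]
        structures = []
        for _ in range(n_here):
            n_ex = int(rng.integers(2, 6))
            ex_lens = rng.integers(200, 1501, size=n_ex)
            in_lens = rng.integers(200, 5001, size=n_ex - 1)
            structures.append((ex_lens, in_lens))
        spans = [int(e.sum() + i.sum()) for e, i in structures]
        margin = 2_000  # keep TSSs away from chromosome edges
        free = length - sum(spans) - 2 * margin
        if free < n_here:
            raise SizingError(
                f"{chrom}: {n_here} genes (total span {sum(spans)}) do not fit "
                f"in {length} bp"
            )
        # stars-and-bars gap placement
        cuts = np.sort(rng.integers(0, free + 1, size=n_here))
        gaps = np.diff(np.concatenate(([0], cuts)))
        pos = margin
        for (ex_lens, in_lens), span, gap in zip(structures, spans, gaps):
            start = pos + int(gap)
            end = start + span
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"g{gid:05d}"
            gid += 1
            tss = start if strand == "+" else end - 1
            gene_rows.append((gene_id, chrom, start, end, strand, tss))
            # exon coordinates in genomic order
            p = start
            exon_coords = []
            for k, el in enumerate(ex_lens):
                exon_coords.append((p, p + int(el)))
                p += int(el)
                if k < len(in_lens):
                    p += int(in_lens[k])
            for s, e in exon_coords:
                feat_rows.append((gene_id, chrom, "exon", s, e, strand))
            # UTRs carved from the terminal exons in transcription order
            first, last = (
                (exon_coords[0], exon_coords[-1])
                if strand == "+"
                else (exon_coords[-1], exon_coords[0])
            )
            u5 = min(int(rng.integers(100, 301)), (first[1] - first[0]) - 50)
            u3 = min(int(rng.integers(200, 801)), (last[1] - last[0]) - 50)
            if strand == "+":
                feat_rows.append((gene_id, chrom, "five_prime_utr", first[0], first[0] + u5, strand))
                feat_rows.append((gene_id, chrom, "three_prime_utr", last[1] - u3, last[1], strand))
            else:
                feat_rows.append((gene_id, chrom, "five_prime_utr", first[1] - u5, first[1], strand))
                feat_rows.append((gene_id, chrom, "three_prime_utr", last[0], last[0] + u3, strand))
            pos = end
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "strand", "tss"]
    )
    features = pd.DataFrame(
        feat_rows, columns=["gene_id", "chrom", "feature", "start", "end", "strand"]
    )
    return Genome(dict(config.chrom_lengths), genes, features)


# ---------------------------------------------------------------------------
# planted regions, classes and transitions


_MIN_CENTER_SEP = 6_000  # planted centers kept apart so 21-bin windows never collide


def _bin_center(pos: int) -> int:
    return (pos // BIN_SIZE) * BIN_SIZE + BIN_SIZE // 2


def plant_truth(config: SimulationConfig, genome: Genome) -> SyntheticTruth:
    """Place chromatin-state regions and assign TF classes and transitions.

    Active-promoter regions sit on gene TSSs (oriented by the gene strand);
    enhancers are placed 5-100 kb from a chosen gene's TSS; repressed regions
    land in remaining space.  Enhancer TF classes cycle through the
    configured class list, and the transition spec is realized interval by
    interval -- spatially clustered transitions pick the from-class members
    nearest an existing target-class enhancer.
    """
    config.validate()
    rng = config._rng(1)
    margin = (10 + config.region_width_bins) * BIN_SIZE
    occupied: dict[str, list[int]] = {c: [] for c in genome.chrom_lengths}

    def free(chrom: str, center: int) -> bool:
        lo, hi = margin, genome.chrom_lengths[chrom] - margin
        if not lo <= center <= hi:
            return False
        return all(abs(center - o) >= _MIN_CENTER_SEP for o in occupied[chrom])

    rows = []
    rid = 0

    def add(chrom: str, center: int, state: str, strand: str) -> None:
        nonlocal rid
        half = (config.region_width_bins // 2) * BIN_SIZE + BIN_SIZE // 2
        rows.append(
            (f"r{rid:05d}", chrom, center, center - half, center + half, state, strand)
        )
        occupied[chrom].append(center)
        rid += 1

    # promoters at well-separated gene TSSs
    n_prom = config.regions_for("active_promoter")
    candidates = genome.genes.sample(frac=1.0, random_state=int(rng.integers(2**31)))
    placed = 0
    for g in candidates.itertuples():
        if placed >= n_prom:
            break
        center = _bin_center(int(g.tss))
        if free(g.chrom, center):
            add(g.chrom, center, "active_promoter", g.strand)
            placed += 1
    if placed < n_prom:
        raise SizingError(
            f"could only place {placed}/{n_prom} promoter regions at gene TSSs"
        )

    def place_random(state: str, n: int, near_genes: bool) -> None:
        chroms = list(genome.chrom_lengths)
        for _ in range(n):
            for _attempt in range(2000):
                if near_genes and len(genome.genes):
                    g = genome.genes.iloc[int(rng.integers(len(genome.genes)))]
                    offset = int(rng.integers(5_000, 100_001))
                    if rng.random() < 0.5:
                        offset = -offset
                    chrom = g["chrom"]
                    center = _bin_center(int(g["tss"]) + offset)
                else:
                    chrom = chroms[int(rng.integers(len(chroms)))]
                    center = _bin_center(
                        int(rng.integers(margin, genome.chrom_lengths[chrom] - margin))
                    )
                if free(chrom, center):
                    add(chrom, center, state, "+")
                    break
            else:
                raise SizingError(f"could not place {state} region (genome too full)")

    place_random("enhancer", config.regions_for("enhancer"), near_genes=True)
    place_random("repressed_1", config.regions_for("repressed_1"), near_genes=False)
    place_random("repressed_2", config.regions_for("repressed_2"), near_genes=False)

    regions = pd.DataFrame(
        rows, columns=["region_id", "chrom", "center", "start", "end", "state", "strand"]
    )

    # TF classes at time 0: balanced assignment, shuffled
    enh = regions[regions["state"] == "enhancer"].reset_index(drop=True)
    names = list(config.class_names)
    reps = int(np.ceil(len(enh) / max(len(names), 1))) if names else 0
    labels0 = np.array((names * reps)[: len(enh)], dtype=object)
    labels0 = labels0[rng.permutation(len(labels0))]

    classes_by_time: dict[float, list[str]] = {TF_TIME_POINTS[0]: list(labels0)}
    centers = enh["center"].to_numpy()
    chroms_arr = enh["chrom"].to_numpy()
    current = labels0.copy()
    realized = []
    for i in range(len(TF_TIME_POINTS) - 1):
        nxt = current.copy()
        for tr in config.transitions:
            if tr.interval != i:
                continue
            members = np.flatnonzero(current == tr.from_class)
            n_change = int(round(tr.fraction * len(members)))
            if n_change == 0:
                continue
            if tr.spatially_clustered:
                targets = np.flatnonzero(current == tr.to_class)
                dist = np.full(len(members), np.inf)
                for j, m in enumerate(members):
                    same = targets[chroms_arr[targets] == chroms_arr[m]]
                    if len(same):
                        dist[j] = np.abs(centers[same] - centers[m]).min()
                order = np.argsort(dist, kind="stable")
                chosen = members[order[:n_change]]
            else:
                chosen = rng.choice(members, size=n_change, replace=False)
            nxt[chosen] = tr.to_class
            for m in chosen:
                realized.append(
                    (enh["region_id"].iloc[m], tr.from_class, tr.to_class, i)
                )
        current = nxt
        classes_by_time[TF_TIME_POINTS[i + 1]] = list(current)

    transitions = pd.DataFrame(
        realized, columns=["region_id", "from_class", "to_class", "interval"]
    )
    return SyntheticTruth(
        regions=regions,
        classes_by_time=classes_by_time,
        enhancer_ids=list(enh["region_id"]),
        transitions=transitions,
    )


# ---------------------------------------------------------------------------
# tag tracks


def generate_tag_tracks(
    config: SimulationConfig, truth: SyntheticTruth
) -> dict[str, TagTrack]:
    """Draw per-bin Poisson tag counts and expand them into read positions.

    Background bins draw ``Poisson(background_rate)``; bins inside a planted
    region draw ``Poisson(scale * enrichment_rate)`` for the region state's
    signature features (floored at the background rate).  ChIP read 5' ends
    are placed so that the downstream +/-75 bp shift returns them to the
    drawn bin; TSS-seq reads carry the planted strand inside promoter
    regions and a random strand elsewhere.
    """
    config.validate()
    rng = config._rng(2)
    half_w = config.region_width_bins // 2
    chrom_lengths = config.chrom_lengths
    tracks: dict[str, TagTrack] = {}
    for feature in FEATURES:
        frames = []
        for chrom, length in chrom_lengths.items():
            n_bins = length // BIN_SIZE
            lam = np.full(n_bins, float(config.background_rate))
            strand_lock = np.full(n_bins, "", dtype=object)
            sub = truth.regions[truth.regions["chrom"] == chrom]
            for r in sub.itertuples():
                scale = STATE_SIGNATURES[r.state].get(feature)
                if scale is None:
                    continue
                cbin = r.center // BIN_SIZE
                lo, hi = max(0, cbin - half_w), min(n_bins, cbin + half_w + 1)
                lam[lo:hi] = max(config.background_rate, scale * config.enrichment_rate)
                if feature == "TSS":
                    strand_lock[lo:hi] = r.strand
            counts = rng.poisson(lam)
            total = int(counts.sum())
            if total == 0:
                continue
            bin_idx = np.repeat(np.arange(n_bins), counts)
            bin_start = bin_idx * BIN_SIZE
            if feature == "TSS":
                strand_of_bin = strand_lock[bin_idx]
                rand_strand = np.where(rng.random(total) < 0.5, "+", "-")
                strand = np.where(strand_of_bin == "", rand_strand, strand_of_bin)
                pos = bin_start + rng.integers(0, BIN_SIZE, size=total)
            else:
                strand = np.where(rng.random(total) < 0.5, "+", "-")
                # place 5' ends so that the +/-75 bp ChIP shift re-bins them here
                plus_off = rng.integers(-75, BIN_SIZE - 75, size=total)
                minus_off = rng.integers(75, BIN_SIZE + 75, size=total)
                pos = bin_start + np.where(strand == "+", plus_off, minus_off)
                pos = np.clip(pos, 0, length - 1)
            frames.append(
                pd.DataFrame({"chrom": chrom, "pos": pos.astype(np.int64), "strand": strand})
            )
        reads = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["chrom", "pos", "strand"])
        )
        reads = reads.sort_values(["chrom", "pos", "strand"], kind="stable").reset_index(
            drop=True
        )
        tracks[feature] = TagTrack(feature, reads)
    return tracks


# ---------------------------------------------------------------------------
# TF peak tables


def generate_tf_peak_tables(
    config: SimulationConfig, truth: SyntheticTruth
) -> pd.DataFrame:
    """Emit per-TF, per-time-point peak tables at planted enhancers.

    Each enhancer of class ``c`` receives, for every TF with a positive class
    mean, one peak with score drawn from ``Normal(mean, score_sigma)``
    truncated at zero and centered uniformly within the central 11 bins
    (+/-1.1 kb).  Class transitions are already realized in the truth, so a
    changed class simply draws from its new profile at later time points.
    TFs with a zero class mean emit no peak.
    """
    config.validate()
    rng = config._rng(3)
    enh = truth.enhancers
    profiles = {
        cls: np.array([config.class_binding_profiles[cls].get(tf, 0.0) for tf in PRINCIPAL_TFS])
        for cls in config.class_names
    }
    rows = []
    for t in TF_TIME_POINTS:
        classes = truth.classes_by_time[t]
        means = np.stack([profiles[c] for c in classes])  # n_enh x 6
        scores = rng.normal(means, config.score_sigma)
        offsets = rng.integers(-1100, 1100, size=means.shape)
        emit = (means > 0) & (scores > 0)
        for j, tf in enumerate(PRINCIPAL_TFS):
            idx = np.flatnonzero(emit[:, j])
            if len(idx) == 0:
                continue
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": enh["chrom"].to_numpy()[idx],
                        "center": enh["center"].to_numpy()[idx] + offsets[idx, j],
                        "score": scores[idx, j],
                        "tf": tf,
                        "time": t,
                    }
                )
            )
    if not rows:
        return pd.DataFrame(columns=["chrom", "center", "score", "tf", "time"])
    peaks = pd.concat(rows, ignore_index=True)
    return peaks.sort_values(["time", "tf", "chrom", "center"], kind="stable").reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# expression


_SET_LABELS = ("early_induction", "late_induction", "gradual_induction", "repression")


def _class_group(profile: Mapping[str, float]) -> str:
    bound = [tf for tf in PRINCIPAL_TFS if profile.get(tf, 0.0) >= SCORE_CAP / 2]
    if "CTCF" in bound:
        return "C"
    n = len(bound)
    return "H" if n >= 4 else ("M" if n >= 2 else "L")


def generate_expression(
    config: SimulationConfig, truth: SyntheticTruth, genome: Genome
) -> ExpressionData:
    """Simulate gene read counts over 0/1/4 h with planted expression sets.

    Genes nearest a planted group-H (highly bound) enhancer are induced with
    probability ``expression_link`` and given an induction archetype; other
    genes draw a set label from ``induced_set_fractions`` (the remainder are
    "no_change", whose max/min RPKM ratio stays below 3 by construction).
    Records gene-set labels into ``truth.gene_sets``.
    """
    config.validate()
    rng = config._rng(4)
    genes = genome.genes.reset_index(drop=True)
    n = len(genes)
    set_label = np.array(["no_change"] * n, dtype=object)
    linked = np.zeros(n, dtype=bool)

    # genes nearest a highly bound enhancer
    h_classes = {
        c for c, p in config.class_binding_profiles.items() if _class_group(p) == "H"
    }
    enh = truth.enhancers
    classes0 = np.array(truth.classes_by_time[TF_TIME_POINTS[0]], dtype=object)
    h_enh = enh[np.isin(classes0, list(h_classes))]
    for r in h_enh.itertuples():
        same = genes[genes["chrom"] == r.chrom]
        if same.empty:
            continue
        d = (same["tss"] - r.center).abs()
        gi = d.idxmin()
        if rng.random() < config.expression_link:
            linked[gi] = True
    induced_labels = ("early_induction", "late_induction", "gradual_induction")
    set_label[linked] = rng.choice(induced_labels, p=(0.5, 0.25, 0.25), size=linked.sum())

    # background labels for unlinked genes
    for lab in _SET_LABELS:
        frac = float(config.induced_set_fractions.get(lab, 0.0))
        pool = np.flatnonzero(set_label == "no_change")
        k = min(int(round(frac * n)), len(pool))
        if k:
            set_label[rng.choice(pool, size=k, replace=False)] = lab

    base = 10 ** rng.uniform(0.2, 1.2, size=n)  # RPKM at the reference level
    prof = np.empty((n, len(EXPR_TIME_POINTS)))
    for i in range(n):
        lab = set_label[i]
        if lab == "early_induction":
            m = (1.0, rng.uniform(5.0, 8.0), rng.uniform(3.0, 5.0))
        elif lab == "late_induction":
            m = (1.0, rng.uniform(0.8, 1.2), rng.uniform(5.0, 8.0))
        elif lab == "gradual_induction":
            m = (1.0, rng.uniform(2.0, 3.0), rng.uniform(5.0, 8.0))
        elif lab == "repression":
            m = (1.0, rng.uniform(0.35, 0.6), rng.uniform(0.1, 0.3))
        else:  # no_change: ratio bounded by 1.15/0.85 < 3
            m = (1.0, rng.uniform(0.85, 1.15), rng.uniform(0.85, 1.15))
        prof[i] = base[i] * np.asarray(m)

    lengths = (genes["end"] - genes["start"]).astype(float)
    target_total = 2e7
    counts = np.rint(prof * lengths.to_numpy()[:, None] / 1e3 * target_total / 1e6)
    counts_df = pd.DataFrame(
        counts.astype(np.int64), index=genes["gene_id"], columns=list(EXPR_TIME_POINTS)
    )
    truth.gene_sets = pd.DataFrame(
        {"gene_id": genes["gene_id"], "set_label": set_label, "linked": linked}
    )
    return ExpressionData(
        counts=counts_df,
        gene_lengths=pd.Series(lengths.to_numpy(), index=genes["gene_id"], name="length"),
        total_reads=counts_df.sum(axis=0),
    )


# ---------------------------------------------------------------------------


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run every generator stage and bundle the outputs with their truth."""
    genome = generate_genome(config)
    truth = plant_truth(config, genome)
    tracks = generate_tag_tracks(config, truth)
    peaks = generate_tf_peak_tables(config, truth)
    expression = generate_expression(config, truth, genome)
    return SimulationResult(config, genome, truth, tracks, peaks, expression)
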