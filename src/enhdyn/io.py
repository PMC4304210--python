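"""Plain-text readers and writers for the pipeline's on-disk formats.

Tag tracks travel as 6-column BED (one row per read 5' end), gene models as
GTF (1-based on disk, 0-based half-open in memory), peak tables and count
matrices as TSV, and simulation truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from enhdyn.simulate import (
    Genome,
    SimulationConfig,
    SyntheticTruth,
    TagTrack,
    Transition,
)


# -- tag tracks (BED6) ------------------------------------------------------


def write_tag_track(track: TagTrack, path: str | Path) -> None:
    df = track.reads
    bed = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["pos"],
            "end": df["pos"] + 1,
            "name": track.feature,
            "score": 1,
            "strand": df["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_tag_track(path: str | Path, feature: str) -> TagTrack:
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    return TagTrack(
        feature,
        pd.DataFrame(
            {"chrom": bed["chrom"], "pos": bed["start"], "strand": bed["strand"]}
        ),
    )


# -- gene models (GTF) ------------------------------------------------------

_GTF_COLS = [
    "seqname", "source", "feature", "start", "end",
    "score", "strand", "frame", "attribute",
]


def write_genome_gtf(genome: Genome, path: str | Path) -> None:
    rows = []
    for g in genome.genes.itertuples():
        attr = f'gene_id "{g.gene_id}";'
        rows.append((g.chrom, "enhdyn", "gene", g.start + 1, g.end, ".", g.strand, ".", attr))
    for f in genome.features.itertuples():
        attr = f'gene_id "{f.gene_id}";'
        rows.append((f.chrom, "enhdyn", f.feature, f.start + 1, f.end, ".", f.strand, ".", attr))
    pd.DataFrame(rows, columns=_GTF_COLS).to_csv(path, sep="\t", header=False, index=False)


def read_genome_gtf(path: str | Path, chrom_lengths: Mapping[str, int]) -> Genome:
    gtf = pd.read_csv(path, sep="\t", header=None, names=_GTF_COLS, comment="#")
    gtf["gene_id"] = gtf["attribute"].str.extract(r'gene_id "([^"]+)"')
    if gtf["gene_id"].isna().any():
        bad = gtf[gtf["gene_id"].isna()].index[0]
        raise ValueError(f"malformed gene model record at line {bad + 1}")
    gtf["start0"] = gtf["start"] - 1  # GTF is 1-based inclusive
    genes = gtf[gtf["feature"] == "gene"]
    genes = pd.DataFrame(
        {
            "gene_id": genes["gene_id"],
            "chrom": genes["seqname"],
            "start": genes["start0"],
            "end": genes["end"],
            "strand": genes["strand"],
        }
    ).reset_index(drop=True)
    genes["tss"] = genes["start"].where(genes["strand"] == "+", genes["end"] - 1)
    feats = gtf[gtf["feature"].isin(["exon", "five_prime_utr", "three_prime_utr"])]
    features = pd.DataFrame(
        {
            "gene_id": feats["gene_id"],
            "chrom": feats["seqname"],
            "feature": feats["feature"],
            "start": feats["start0"],
            "end": feats["end"],
            "strand": feats["strand"],
        }
    ).reset_index(drop=True)
    return Genome(dict(chrom_lengths), genes, features)


# -- misc tables ------------------------------------------------------------


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    Path(path).write_text(truth.to_json())


def read_truth(path: str | Path) -> SyntheticTruth:
    return SyntheticTruth.from_json(Path(path).read_text())


def load_config(path: str | Path) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a YAML mapping."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "transition_spec" in raw:
        raw["transition_spec"] = [
            Transition(**t) if isinstance(t, dict) else Transition(*t)
            for t in raw["transition_spec"]
        ]
    return SimulationConfig(**raw)


def write_regions_bed(table: pd.DataFrame, path: str | Path) -> None:
    """Region table as BED6+ (name=id, score=center, extra columns appended)."""
    cols = ["chrom", "start", "end", "region_id", "center", "strand"]
    extra = [c for c in table.columns if c not in cols + ["center_bin"]]
    table[cols + extra].to_csv(path, sep="\t", header=True, index=False)


def write_profiles(profiles, features, path: str | Path) -> None:
    """Stacked (n, bins, F) profiles as a flat TSV, one region per row."""
    n, b, f = profiles.shape
    cols = [f"{feat}_bin{i:02d}" for feat in features for i in range(b)]
    flat = profiles.transpose(0, 2, 1).reshape(n, b * f)
    pd.DataFrame(flat, columns=cols).to_csv(path, sep="\t", index=False)


def read_profiles(path: str | Path, n_features: int):
    df = pd.read_csv(path, sep="\t")
    n, bf = df.shape
    b = bf // n_features
    return df.to_numpy().reshape(n, n_features, b).transpose(0, 2, 1)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=str))
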