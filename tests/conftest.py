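"""Shared fixtures: small synthetic studies generated at test time."""

import numpy as np
import pandas as pd
import pytest

from enhdyn.simulate import SimulationConfig, SimulationResult, simulate


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale study: 2 x 5 Mb genome, default 13-class design."""
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def small_sim(small_config) -> SimulationResult:
    return simulate(small_config)


def match_truth_states(table: pd.DataFrame, truth_regions: pd.DataFrame) -> pd.Series:
    """Planted state per detected region (nearest planted center, <= 2 kb)."""
    left = table[["chrom", "center"]].copy()
    left["orig"] = np.arange(len(table))
    merged = pd.merge_asof(
        left.sort_values("center"),
        truth_regions.sort_values("center"),
        on="center",
        by="chrom",
        direction="nearest",
        tolerance=2000,
        suffixes=("", "_truth"),
    ).set_index("orig").sort_index()
    return merged["state"]


def match_truth_ids(table: pd.DataFrame, truth_regions: pd.DataFrame) -> pd.Series:
    left = table[["chrom", "center"]].copy()
    left["orig"] = np.arange(len(table))
    merged = pd.merge_asof(
        left.sort_values("center"),
        truth_regions.sort_values("center"),
        on="center",
        by="chrom",
        direction="nearest",
        tolerance=2000,
        suffixes=("", "_truth"),
    ).set_index("orig").sort_index()
    return merged["region_id"]
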