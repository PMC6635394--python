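"""Readers, writers and pipeline configuration.

All tables are tab-separated with a fixed header row; genomic intervals
are 0-based half-open on disk and in memory (GFF-style 1-based inputs are
converted on read). Readers validate and reject malformed input rather
than silently coercing it.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import Segmentation
from .fourc import VirtualFourCProfile
from .silencing import COUNT_COLUMNS
from .simulate import STATE_NAMES

logger = logging.getLogger(__name__)

_STATE_BY_NAME = {name: idx for idx, name in STATE_NAMES.items()}


def read_counts(path) -> pd.DataFrame:
    """Read a validated allele-split count table (TSV).

    Required columns: gene_id, sample_id, condition, genotype, replicate,
    xi, xa. Rows with negative counts or unknown conditions are rejected
    with their line numbers.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if df.empty:
        logger.warning("%s: count table has a header but no rows", path)
        return df
    lines = df.index + 2  # header is line 1
    for col in ("xi", "xa"):
        if not np.issubdtype(df[col].dtype, np.number):
            bad = lines[pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValueError(f"{path}: non-numeric {col} at line(s) {list(bad)[:5]}")
        neg = lines[df[col] < 0]
        if len(neg):
            raise ValueError(f"{path}: negative {col} at line(s) {list(neg)[:5]}")
    bad_cond = lines[~df["condition"].isin(["dox", "nodox"])]
    if len(bad_cond):
        raise ValueError(f"{path}: condition must be dox|nodox at line(s) {list(bad_cond)[:5]}")
    dup = df.duplicated(subset=["gene_id", "sample_id"])
    if dup.any():
        raise ValueError(f"{path}: duplicate (gene_id, sample_id) at line(s) {list(lines[dup])[:5]}")
    return df


def write_counts(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_segmentation(path) -> Segmentation:
    """Read a ChromHMM dense-style BED (chrom, start, end, state label).

    State labels may be the enumerated names or bare indices 1..12;
    unknown labels and overlapping intervals are rejected.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValueError(f"{path}: segmentation BED needs at least 4 columns")
    df = df.iloc[:, :4]
    df.columns = ["chrom", "start", "end", "state"]

    def to_state(label) -> int:
        text = str(label)
        if text in _STATE_BY_NAME:
            return _STATE_BY_NAME[text]
        try:
            idx = int(text)
        except ValueError:
            raise ValueError(f"{path}: unknown chromatin state label {label!r}") from None
        if idx not in STATE_NAMES:
            raise ValueError(f"{path}: unknown chromatin state label {label!r}")
        return idx

    df["state"] = df["state"].map(to_state)
    return Segmentation(df)


def write_segmentation(segmentation: Segmentation, path) -> None:
    df = segmentation.intervals.copy()
    df["state"] = df["state"].map(STATE_NAMES)
    df.to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(track: pd.DataFrame, path, value_col: str = "value", chrom_col: str = "chrom") -> None:
    """Write a 4-column bedGraph (0-based half-open, 6 significant digits).

    Adjacent equal-value windows are preserved, never merged; unsorted
    input is sorted on write with a log message.
    """
    df = track.copy()
    if chrom_col not in df.columns:
        df[chrom_col] = "chrSim"
    sorted_ok = (
        df.sort_values([chrom_col, "start"], kind="mergesort").index.equals(df.index)
    )
    if not sorted_ok:
        logger.info("bedGraph input unsorted; sorting on write")
        df = df.sort_values([chrom_col, "start"], kind="mergesort")
    with open(path, "w") as fh:
        if df.empty:
            fh.write("# empty track\n")
            return
        for row in df.itertuples(index=False):
            d = row._asdict()
            fh.write(f"{d[chrom_col]}\t{int(d['start'])}\t{int(d['end'])}\t{d[value_col]:.6g}\n")


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
    )
    return df


def write_profile(profile: VirtualFourCProfile, path) -> None:
    write_bedgraph(profile.to_frame(), path)


def read_profile(path, viewpoint: int) -> VirtualFourCProfile:
    df = read_bedgraph(path)
    if df.empty:
        raise ValueError(f"{path}: empty 4C profile")
    bin_size = int(df["end"].iloc[0] - df["start"].iloc[0])
    values = np.zeros(int(df["end"].max()) // bin_size)
    values[(df["start"] // bin_size).to_numpy()] = df["value"].to_numpy()
    return VirtualFourCProfile(
        chrom=str(df["chrom"].iloc[0]), bin_size=bin_size, viewpoint=viewpoint, values=values
    )


def read_contacts(path) -> np.ndarray:
    """Read contact pairs as a 2-column TSV of bp positions, or BEDPE.

    For BEDPE (>= 6 columns) the two start coordinates are used.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] >= 6:
        pairs = df.iloc[:, [1, 4]]
    elif df.shape[1] >= 2:
        pairs = df.iloc[:, :2]
    else:
        raise ValueError(f"{path}: contacts need 2 (positions) or >= 6 (BEDPE) columns")
    return pairs.to_numpy(dtype=np.int64)


@dataclass
class PipelineConfig:
    """All pipeline thresholds and input paths in one place.

    Threshold defaults mirror the analysis: min 10 informative reads per
    gene, silencing-class cutoffs -0.05 / -0.2, min 20 allelic reads per
    1 Mb window, 10 Mb exclusion flank around Xist, 1 Mb bins, 2 kb
    promoter flank, 50 trees / 5 folds, 180 permutations of 45 genes and
    a 10-million-read calibration target.
    """

    counts: str | None = None
    annotation: str | None = None
    segmentation: str | None = None
    contacts: str | None = None
    chip_windows: str | None = None
    chip_libraries: str | None = None
    simulate: bool = True
    simulation: dict = field(default_factory=dict)
    min_reads: int = 10
    filter_mode: str = "per_sample"
    weak_threshold: float = -0.05
    high_threshold: float = -0.2
    min_window_reads: int = 20
    exclusion_flank: int = 10_000_000
    bin_size: int = 1_000_000
    promoter_flank: int = 2000
    n_trees: int = 50
    n_folds: int = 5
    n_perm: int = 180
    subsample_size: int = 45
    target_total: float = 1e7
    mutant_pathway_multiplier: float = 0.1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def validate(self) -> None:
        if not self.simulate and self.counts is None:
            raise ValueError("config error: no counts path and simulation disabled")
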