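"""Promoter chromatin-state assignment and classifier feature construction.

Consumes a 12-state ChromHMM-style segmentation and builds, per gene, the
16 features used by the silencing-efficiency classifier: two [0,1] scalings
of mESC expression (max-scaled and rank-scaled FPKM), genomic (2D) and
topological (3D) proximity to the Xist locus, and the bp fraction of each
of the 12 chromatin states in the 4 kb windows around the gene's TSSs
(weighted by TSS usage).

Coordinates are 0-based half-open throughout.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .fourc import VirtualFourCProfile, distance_3d
from .simulate import STATE_NAMES

logger = logging.getLogger(__name__)

N_STATES = 12
UNASSIGNED = "unassigned"
DEFAULT_FLANK = 2000


@dataclass
class Segmentation:
    """Non-overlapping chromatin-state intervals of one chromosome set.

    ``intervals`` columns: chrom, start, end (0-based half-open bp),
    state (integer 1..12).
    """

    intervals: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.intervals
        required = {"chrom", "start", "end", "state"}
        if not required <= set(df.columns):
            raise ValueError(f"segmentation needs columns {sorted(required)}")
        bad = set(df["state"].unique()) - set(STATE_NAMES)
        if bad:
            raise ValueError(f"unknown state indices: {sorted(bad)}")
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        for chrom, sub in df.groupby("chrom"):
            overlap = sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]
            if overlap.any():
                rows = sub.index[:-1][overlap].tolist()
                raise ValueError(f"overlapping intervals on {chrom} at rows {rows}")
        self.intervals = df

    def state_coverage(self, chrom: str, start: int, end: int) -> np.ndarray:
        """bp covered by each state within [start, end); index 0 = state 1."""
        cover = np.zeros(N_STATES)
        sub = self.intervals[self.intervals["chrom"] == chrom]
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        st = sub["state"].to_numpy()
        lo = np.maximum(s, start)
        hi = np.minimum(e, end)
        width = hi - lo
        hit = width > 0
        np.add.at(cover, st[hit] - 1, width[hit])
        return cover


@dataclass
class GeneAnnotation:
    """One gene: representative locus plus all annotated TSSs with usage counts."""

    gene_id: str
    chrom: str
    strand: str
    locus: int
    tss_list: list[tuple[int, int]]  # (position, n_transcripts using it)
    fpkm: float = 0.0

    def __post_init__(self) -> None:
        if not self.tss_list:
            raise ValueError(f"{self.gene_id}: tss_list must be non-empty")
        if any(n < 1 for _, n in self.tss_list):
            raise ValueError(f"{self.gene_id}: TSS usage counts must be >= 1")


def select_primary_tss(gene: GeneAnnotation, seed: int = 0) -> int:
    """The TSS used by the most transcripts; ties broken by a seeded draw."""
    counts = np.array([n for _, n in gene.tss_list])
    best = counts.max()
    candidates = [pos for pos, n in gene.tss_list if n == best]
    if len(candidates) == 1:
        return candidates[0]
    rng = np.random.default_rng(seed)
    return int(rng.choice(sorted(candidates)))


def promoter_state(
    gene: GeneAnnotation,
    segmentation: Segmentation,
    flank: int = DEFAULT_FLANK,
    seed: int = 0,
) -> int | str:
    """Predominant chromatin state in [TSS - flank, TSS + flank).

    Uncovered bp count toward no state; a fully uncovered window returns
    "unassigned". Ties go to the lowest state index so annotations are
    reproducible.
    """
    tss = select_primary_tss(gene, seed=seed)
    cover = segmentation.state_coverage(gene.chrom, tss - flank, tss + flank)
    if cover.sum() == 0:
        return UNASSIGNED
    return int(np.argmax(cover)) + 1  # argmax takes first (lowest) index on ties


def state_proportions(
    gene: GeneAnnotation, segmentation: Segmentation, flank: int = DEFAULT_FLANK
) -> np.ndarray:
    """12-vector of state fractions around all the gene's TSSs.

    For each TSS the bp fraction of each state in its 4 kb window is
    computed (uncovered bp assigned to state 12, LowSignal, so fractions
    stay normalised), then averaged across TSSs weighted by transcript
    usage. Always sums to 1.
    """
    weights = np.array([n for _, n in gene.tss_list], dtype=float)
    weights /= weights.sum()
    out = np.zeros(N_STATES)
    for (tss, _), w in zip(gene.tss_list, weights):
        window = 2 * flank
        cover = segmentation.state_coverage(gene.chrom, tss - flank, tss + flank)
        cover[N_STATES - 1] += window - cover.sum()  # uncovered -> LowSignal
        out += w * cover / window
    return out


def distance_2d(gene_locus: int, xist_locus: int) -> float:
    """Genomic proximity 1 - |Xist - gene| / Xist, clamped to [0, 1]."""
    if xist_locus <= 0:
        raise ValueError("xist_locus must be positive")
    value = 1.0 - abs(xist_locus - gene_locus) / xist_locus
    return float(min(1.0, max(0.0, value)))


def normalize_expression(fpkm, method: str = "max") -> np.ndarray:
    """Scale FPKM to [0, 1].

    ``max``: divide by the maximum (highest-expressed gene becomes 1).
    ``rank``: map rank positions linearly onto [0, 1] with ties averaged,
    so the lowest gene gets 0 and the highest 1.
    """
    x = np.asarray(fpkm, dtype=float)
    if (x < 0).any():
        raise ValueError("FPKM values must be non-negative")
    if method == "max":
        top = x.max(initial=0.0)
        if top <= 0:
            raise ValueError("max-scaling undefined for an all-zero vector")
        return x / top
    if method == "rank":
        if x.size < 2:
            raise ValueError("rank-scaling needs at least 2 genes")
        return (rankdata(x, method="average") - 1) / (x.size - 1)
    raise ValueError(f"unknown method: {method!r}")


def build_feature_matrix(
    genes: list[GeneAnnotation] | pd.DataFrame,
    segmentation: Segmentation,
    fourc_profile: VirtualFourCProfile,
    xist_locus: int,
    flank: int = DEFAULT_FLANK,
) -> pd.DataFrame:
    """Assemble the 16 classifier features per gene, all in [0, 1].

    Columns: expr_maxscaled, expr_rankscaled, dist2d, dist3d,
    state_frac_1 .. state_frac_12. Genes whose locus falls outside the 4C
    profile get dist3d = 0 with a warning.
    """
    if isinstance(genes, pd.DataFrame):
        genes = annotations_from_frame(genes)
    fpkm = np.array([g.fpkm for g in genes])
    rows = {
        "expr_maxscaled": normalize_expression(fpkm, "max"),
        "expr_rankscaled": normalize_expression(fpkm, "rank"),
        "dist2d": [distance_2d(g.locus, xist_locus) for g in genes],
    }
    d3 = []
    for g in genes:
        try:
            d3.append(distance_3d(fourc_profile, g.locus))
        except KeyError:
            logger.warning("%s: locus outside 4C profile, dist3d set to 0", g.gene_id)
            d3.append(0.0)
    rows["dist3d"] = d3
    props = np.vstack([state_proportions(g, segmentation, flank=flank) for g in genes])
    for k in range(N_STATES):
        rows[f"state_frac_{k + 1}"] = props[:, k]
    return pd.DataFrame(rows, index=pd.Index([g.gene_id for g in genes], name="gene_id"))


def annotations_from_frame(genes: pd.DataFrame) -> list[GeneAnnotation]:
    """Build single-TSS GeneAnnotation objects from a simulator gene table."""
    return [
        GeneAnnotation(
            gene_id=row.gene_id,
            chrom=row.chrom,
            strand=row.strand,
            locus=int(row.locus),
            tss_list=[(int(row.tss), 1)],
            fpkm=float(row.fpkm),
        )
        for row in genes.itertuples()
    ]
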