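"""Virtual 4C profiles and topological-proximity analysis.

A virtual 4C profile is the row of a chromosome-wide contact map belonging
to a single viewpoint bin (here the Xist locus), at 1 Mb resolution. It is
used two ways: normalised to its maximum it becomes the "3D proximity"
feature of each gene, and correlated against 1 Mb-windowed silencing or
Polycomb-gain signal it quantifies how far topological proximity to Xist
predicts silencing efficiency.
"""
from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

DEFAULT_BIN_SIZE = 1_000_000


@dataclass
class VirtualFourCProfile:
    """Per-bin contact counts of one viewpoint across a chromosome.

    Bins are 0-based half-open intervals ``[i*bin_size, (i+1)*bin_size)``
    tiling the chromosome; ``values[i]`` is the contact count of bin *i*
    with the viewpoint bin.
    """

    chrom: str
    bin_size: int
    viewpoint: int
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("profile values must be one-dimensional")
        if (self.values < 0).any():
            raise ValueError("contact values must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.values.size

    @property
    def viewpoint_bin(self) -> int:
        return self.bin_of(self.viewpoint)

    def bin_of(self, position: int) -> int:
        b = int(position) // self.bin_size
        if not 0 <= b < self.n_bins:
            raise KeyError(f"position {position} outside profile ({self.n_bins} bins)")
        return b

    def value_at(self, position: int) -> float:
        return float(self.values[self.bin_of(position)])

    def bin_centres(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_size

    def to_frame(self) -> pd.DataFrame:
        starts = np.arange(self.n_bins) * self.bin_size
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": starts,
                "end": starts + self.bin_size,
                "value": self.values,
            }
        )


def virtual_4c(
    contacts,
    viewpoint: int,
    bin_size: int = DEFAULT_BIN_SIZE,
    chrom_length: int | None = None,
    chrom: str = "chrSim",
) -> VirtualFourCProfile:
    """Build a viewpoint profile from raw contact-pair positions.

    ``contacts`` is an iterable of ``(posA, posB)`` bp pairs on one
    chromosome. Every pair with at least one end inside the viewpoint bin
    increments the bin of its other end; a pair with *both* ends in the
    viewpoint bin counts once, toward the viewpoint bin itself.
    """
    pairs = np.asarray(list(contacts), dtype=np.int64).reshape(-1, 2)
    if chrom_length is None:
        top = max(int(pairs.max(initial=0)), int(viewpoint))
        chrom_length = top + 1
    n_bins = int(np.ceil(chrom_length / bin_size))
    values = np.zeros(n_bins, dtype=float)
    vp_bin = int(viewpoint) // bin_size

    if pairs.size:
        bins_a = pairs[:, 0] // bin_size
        bins_b = pairs[:, 1] // bin_size
        touch_a = bins_a == vp_bin
        touch_b = bins_b == vp_bin
        # both-end pairs contribute a single count to the viewpoint bin
        other = np.where(touch_a, bins_b, bins_a)
        qualifying = other[touch_a | touch_b]
        qualifying = qualifying[(qualifying >= 0) & (qualifying < n_bins)]
        np.add.at(values, qualifying, 1.0)

    if values.sum() == 0:
        warnings.warn("no contact pair touches the viewpoint bin; profile is all zero")
    return VirtualFourCProfile(chrom=chrom, bin_size=bin_size, viewpoint=int(viewpoint), values=values)


def distance_3d(profile: VirtualFourCProfile, gene_locus: int) -> float:
    """Topological proximity of a gene: its bin's contact value / profile max.

    1.0 in the strongest-contact bin, 0.0 in contact-free bins.
    """
    vmax = profile.values.max(initial=0.0)
    if vmax <= 0:
        raise ValueError("profile maximum is zero; 3D proximity undefined")
    return profile.value_at(gene_locus) / vmax


def windowed_silencing(
    counts: pd.DataFrame,
    gene_positions: pd.Series,
    bin_size: int = DEFAULT_BIN_SIZE,
    chrom_length: int | None = None,
    min_reads: int = 20,
) -> pd.DataFrame:
    """Aggregate allele-split counts into 1 Mb windows and score silencing.

    Genes are assigned to the window containing their TSS; Xi/Xa counts are
    pooled within each (window, condition) and the window-level allelic
    ratio and silencing score computed. Windows with fewer than
    ``min_reads`` allelic reads in either condition are flagged invalid.

    Parameters
    ----------
    counts : long AllelicCountTable (gene_id, condition, xi, xa, ...)
    gene_positions : Series mapping gene_id -> bp position (TSS)
    """
    df = counts.copy()
    df["window"] = gene_positions.reindex(df["gene_id"]).to_numpy() // bin_size
    if df["window"].isna().any():
        missing = df.loc[df["window"].isna(), "gene_id"].unique()
        raise KeyError(f"genes without position: {list(missing)[:5]}")
    df["window"] = df["window"].astype(int)

    pooled = (
        df.groupby(["window", "condition"])[["xi", "xa"]]
        .sum()
        .unstack("condition", fill_value=0)
    )
    n_windows = (
        int(np.ceil(chrom_length / bin_size))
        if chrom_length is not None
        else int(pooled.index.max()) + 1
    )
    out = pd.DataFrame(index=pd.RangeIndex(n_windows, name="window"))
    for cond in ("dox", "nodox"):
        xi = pooled.get(("xi", cond), pd.Series(dtype=float)).reindex(out.index, fill_value=0)
        xa = pooled.get(("xa", cond), pd.Series(dtype=float)).reindex(out.index, fill_value=0)
        total = xi + xa
        with np.errstate(invalid="ignore"):
            out[f"ratio_{cond}"] = np.where(total > 0, xi / total.replace(0, np.nan), np.nan)
        out[f"reads_{cond}"] = total
    out["z"] = out["ratio_dox"] - out["ratio_nodox"]
    out["valid"] = (out["reads_dox"] >= min_reads) & (out["reads_nodox"] >= min_reads)
    out["start"] = out.index * bin_size
    out["end"] = out["start"] + bin_size
    return out


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho at small n."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    count = 0
    total = 0
    abs_obs = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(range(len(ry))):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        count += abs(r) >= abs_obs
        total += 1
    return count / total


def correlate_profile(
    profile: VirtualFourCProfile,
    window_values: pd.Series,
    xist_locus: int,
    exclusion_flank: int = 10_000_000,
    min_reads: int = 20,
    window_reads: pd.Series | None = None,
) -> tuple[float, float, int]:
    """Spearman correlation of a windowed signal with the 4C profile.

    Windows overlapping ``[xist_locus - exclusion_flank, xist_locus +
    exclusion_flank]`` are excluded (overlap, not containment); remaining
    windows must carry a finite signal value and, when ``window_reads`` is
    supplied, at least ``min_reads`` allelic reads.

    Returns ``(rho, two-sided p, n_windows retained)``. The p-value uses
    the large-sample t approximation, or exact permutation below n=10.
    """
    values = window_values.reindex(pd.RangeIndex(profile.n_bins))
    starts = np.arange(profile.n_bins) * profile.bin_size
    ends = starts + profile.bin_size
    lo, hi = xist_locus - exclusion_flank, xist_locus + exclusion_flank
    excluded = (starts <= hi) & (ends > lo)  # half-open window vs closed region

    keep = ~excluded & np.isfinite(values.to_numpy(dtype=float))
    if window_reads is not None:
        reads = window_reads.reindex(values.index).to_numpy(dtype=float)
        keep &= np.nan_to_num(reads) >= min_reads

    x = profile.values[keep]
    y = values.to_numpy(dtype=float)[keep]
    n = int(keep.sum())
    if n < 3:
        raise ValueError(f"only {n} windows retained; need at least 3")
    rho, p_t = sps.spearmanr(x, y)
    if n < 10:
        p = _spearman_exact_p(x, y, rho)
    else:
        p = float(p_t)
    return float(rho), p, n


def find_integration_site(anchors, window_size: int) -> tuple[int, int, int]:
    """Locate the densest window of chimeric-read anchor positions.

    Slides a ``window_size``-bp window over the anchor positions (each
    anchor is a candidate left edge) and returns ``(start, end, count)``
    of the window containing the most anchors; ties go to the leftmost
    window.
    """
    pos = np.sort(np.asarray(list(anchors), dtype=np.int64))
    if pos.size == 0:
        raise ValueError("no anchor positions supplied")
    # count of anchors in [a, a + window_size) for each anchor a
    right = np.searchsorted(pos, pos + window_size, side="left")
    left = np.arange(pos.size)
    counts = right - left
    best = int(np.argmax(counts))  # argmax returns first (leftmost) maximum
    start = int(pos[best])
    return start, start + int(window_size), int(counts[best])
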