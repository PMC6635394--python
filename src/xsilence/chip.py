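"""Spike-in calibrated allelic ChIP-seq analysis.

Samples sharing an exogenous (e.g. Drosophila) chromatin spike-in can be
placed on a common absolute scale: each sample's reads are normalised to
its spike-in library size, the reference (WT) sample is scaled to a fixed
total (10 million reads) and every other sample by the same factor. On
that calibrated scale the absolute allelic gain of a histone mark on Xist
induction is

    G = (Xi - Xa)_Dox - (Xi - Xa)_NoDox,

computed per genomic window; gene-class metaprofiles and rank-sum
comparisons between pre-active and pre-H3K27me3 gene sets summarise it.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import wilcoxon_rank_sum

DEFAULT_TARGET_TOTAL = 1e7


def calibration_factors(
    libraries: pd.DataFrame,
    reference_id: str,
    target_total: float = DEFAULT_TARGET_TOTAL,
) -> pd.Series:
    """Per-sample scale factors referenced to the spike-in.

    ``libraries`` needs columns sample_id, experimental_total, spike_total.
    The factor is ``(spike_ref / spike_i) * (target_total /
    experimental_total_ref)``: sample counts times factor are spike-in
    normalised and the reference sample's calibrated total is exactly
    ``target_total``. Multiplying one sample's experimental and spike-in
    totals by the same constant leaves its calibrated signal unchanged.
    """
    lib = libraries.set_index("sample_id")
    if reference_id not in lib.index:
        raise KeyError(f"reference sample {reference_id!r} not in library table")
    zero = lib.index[lib["spike_total"] <= 0]
    if len(zero):
        raise ValueError(f"spike-in library size is zero for sample(s): {list(zero)}")
    spike_ref = lib.loc[reference_id, "spike_total"]
    exp_ref = lib.loc[reference_id, "experimental_total"]
    if exp_ref <= 0:
        raise ValueError(f"reference sample {reference_id!r} has no experimental reads")
    factors = (spike_ref / lib["spike_total"]) * (target_total / exp_ref)
    factors.name = "factor"
    return factors


def calibrate_windows(
    windows: pd.DataFrame, factors: pd.Series, columns: tuple[str, ...] = ("xi", "xa")
) -> pd.DataFrame:
    """Scale per-window allele-split counts by each sample's calibration factor."""
    out = windows.copy()
    f = out["sample_id"].map(factors)
    if f.isna().any():
        missing = out.loc[f.isna(), "sample_id"].unique()
        raise KeyError(f"no calibration factor for sample(s): {list(missing)}")
    for col in columns:
        out[col] = out[col] * f
    return out


def allelic_gain(xi_dox, xa_dox, xi_nodox, xa_nodox):
    """Absolute allelic gain G = (Xi - Xa)_Dox - (Xi - Xa)_NoDox on the calibrated scale."""
    return (np.asarray(xi_dox, dtype=float) - np.asarray(xa_dox, dtype=float)) - (
        np.asarray(xi_nodox, dtype=float) - np.asarray(xa_nodox, dtype=float)
    )


def gain_track(calibrated: pd.DataFrame, dox_sample: str, nodox_sample: str) -> pd.DataFrame:
    """Per-window gain from a calibrated window table of two samples.

    The gain is defined only over windows present, with both alleles, in
    both conditions; windows are matched on (start, end).
    """
    dox = calibrated[calibrated["sample_id"] == dox_sample].set_index(["start", "end"])
    nod = calibrated[calibrated["sample_id"] == nodox_sample].set_index(["start", "end"])
    shared = dox.index.intersection(nod.index)
    g = allelic_gain(
        dox.loc[shared, "xi"], dox.loc[shared, "xa"],
        nod.loc[shared, "xi"], nod.loc[shared, "xa"],
    )
    out = pd.DataFrame(index=shared).reset_index()
    out["gain"] = np.asarray(g)
    return out.sort_values("start").reset_index(drop=True)


def region_fpkm(count, region_length: int, calibrated_library_total: float):
    """FPKM-style density making regions of different sizes comparable."""
    if region_length <= 0:
        raise ValueError("region_length must be positive")
    if calibrated_library_total <= 0:
        raise ValueError("calibrated_library_total must be positive")
    return np.asarray(count, dtype=float) * 1e9 / (region_length * calibrated_library_total)


def _step_lookup(track: pd.DataFrame, positions: np.ndarray) -> np.ndarray:
    """Value of a sorted, non-overlapping (start, end, gain) track at given bp."""
    starts = track["start"].to_numpy()
    ends = track["end"].to_numpy()
    vals = track["gain"].to_numpy(dtype=float)
    idx = np.searchsorted(starts, positions, side="right") - 1
    idx = np.clip(idx, 0, len(starts) - 1)
    inside = (positions >= starts[idx]) & (positions < ends[idx])
    return np.where(inside, vals[idx], np.nan)


def metaprofile(
    gene_set: pd.DataFrame,
    track: pd.DataFrame,
    bin_size: int = 50,
    n_body_bins: int = 60,
    flank: int = 2000,
) -> pd.DataFrame:
    """Scaled-gene-body mean signal profile for a gene set.

    Each gene body ([start, end), strand-aware) is rescaled to
    ``n_body_bins`` equal slices, flanked by ``flank`` bp upstream and
    downstream split into ``flank // bin_size`` fixed-width bins; the
    track value is sampled at each slice centre and averaged across genes.

    ``gene_set`` needs columns start, end, strand; ``track`` is a sorted
    (start, end, gain) window table.
    """
    if gene_set.empty:
        raise ValueError("empty gene set")
    n_flank = max(1, flank // bin_size)
    profiles = []
    for row in gene_set.itertuples():
        start, end = int(row.start), int(row.end)
        strand = getattr(row, "strand", "+")
        up = start - flank + (np.arange(n_flank) + 0.5) * bin_size
        body = start + (np.arange(n_body_bins) + 0.5) * (end - start) / n_body_bins
        down = end + (np.arange(n_flank) + 0.5) * bin_size
        pos = np.concatenate([up, body, down])
        vals = _step_lookup(track, pos)
        if strand == "-":
            vals = vals[::-1]
        profiles.append(vals)
    mean = np.nanmean(np.vstack(profiles), axis=0)
    labels = (
        [f"up_{i}" for i in range(n_flank)]
        + [f"body_{i}" for i in range(n_body_bins)]
        + [f"down_{i}" for i in range(n_flank)]
    )
    return pd.DataFrame({"bin": labels, "mean_gain": mean})


def gain_significance(gain_preactive, gain_pre_k27, alternative: str = "two_sided") -> float:
    """Wilcoxon rank-sum p comparing Polycomb gain between the two gene classes."""
    return wilcoxon_rank_sum(
        np.asarray(gain_preactive, dtype=float),
        np.asarray(gain_pre_k27, dtype=float),
        alternative=alternative,
    )
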