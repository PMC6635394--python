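"""Per-gene allelic silencing scoring and classification.

The silencing readout is the allelic ratio Xi/(Xi+Xa) of SNP-informative
reads: 0.5 means biallelic expression, 0 complete silencing of the
Xist-bearing allele. Silencing of a gene is quantified as the change in
allelic ratio on Xist induction,

    z = [Xi/(Xi+Xa)]_Dox - [Xi/(Xi+Xa)]_NoDox,

so negative z indicates silencing. Genes are classed weak/none
(z > -0.05), low (-0.2 < z <= -0.05) or high (z <= -0.2), and binned into
equal-size expression groups E1 < E2 < E3 by FPKM.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: silencing-class thresholds on z
WEAK_THRESHOLD = -0.05
HIGH_THRESHOLD = -0.2

COUNT_COLUMNS = ["gene_id", "sample_id", "condition", "genotype", "replicate", "xi", "xa"]


def filter_informative(
    table: pd.DataFrame, min_reads: int = 10, mode: str = "per_sample"
) -> pd.DataFrame:
    """Keep genes with enough SNP-informative reads.

    ``mode='per_sample'`` (default, stricter) requires xi+xa >= min_reads in
    every sample of the table, guaranteeing a defined allelic ratio in each;
    ``mode='summed'`` requires the total over all samples to meet min_reads.
    """
    if mode not in ("per_sample", "summed"):
        raise ValueError(f"unknown filter mode: {mode!r}")
    if table.empty:
        logger.warning("filter_informative called on an empty table")
        return table.copy()
    totals = table["xi"] + table["xa"]
    grouped = totals.groupby(table["gene_id"])
    if mode == "per_sample":
        ok = grouped.min() >= min_reads
    else:
        ok = grouped.sum() >= min_reads
    keep = ok[ok].index
    out = table[table["gene_id"].isin(keep)].copy()
    logger.info(
        "informative-read filter (%s, >=%d): %d of %d genes retained",
        mode, min_reads, len(keep), grouped.ngroups,
    )
    return out


def allelic_ratio(xi, xa):
    """Xi/(Xi+Xa); raises if no informative reads (filter first)."""
    xi = np.asarray(xi, dtype=float)
    xa = np.asarray(xa, dtype=float)
    total = xi + xa
    if np.any(total <= 0):
        raise ValueError("allelic ratio undefined for xi + xa = 0; filter genes first")
    out = xi / total
    return float(out) if out.ndim == 0 else out


def mean_replicate_ratio(ratios) -> float:
    """Average per-replicate allelic ratios (ratio-level, not pooled counts)."""
    ratios = np.asarray(list(ratios), dtype=float)
    if ratios.size == 0:
        raise ValueError("no replicate ratios supplied")
    return float(ratios.mean())


def silencing_score(ratio_dox, ratio_nodox):
    """z = induced minus uninduced allelic ratio; negative z = silencing."""
    return np.subtract(ratio_dox, ratio_nodox)


def classify_silencing(z):
    """Map z to 'weak_none' (z > -0.05), 'low' (-0.2 < z <= -0.05) or 'high' (z <= -0.2)."""
    z = np.asarray(z, dtype=float)
    out = np.where(z > WEAK_THRESHOLD, "weak_none", np.where(z > HIGH_THRESHOLD, "low", "high"))
    return str(out) if out.ndim == 0 else out


def silencing_deficiency(z_mutant, z_wt):
    """Per-gene mutant-minus-WT silencing score; positive = deficiency."""
    return np.subtract(z_mutant, z_wt)


def expression_quantiles(fpkm: pd.Series, k: int = 3) -> pd.Series:
    """Split genes into k equal-size expression groups E1 (lowest) .. Ek.

    Genes are sorted by FPKM with ties broken by gene_id; remainders go to
    the lower groups, so 10 genes with k=3 split (4, 3, 3).
    """
    fpkm = pd.Series(fpkm)
    if (np.asarray(fpkm) < 0).any():
        raise ValueError("FPKM values must be non-negative")
    n = len(fpkm)
    if n < k:
        raise ValueError(f"cannot split {n} genes into {k} groups")
    # sort by FPKM, ties broken deterministically by gene identifier
    order = np.lexsort((fpkm.index.astype(str).to_numpy(), fpkm.to_numpy()))
    base, rem = divmod(n, k)
    sizes = [base + (1 if i < rem else 0) for i in range(k)]
    labels = np.repeat([f"E{i + 1}" for i in range(k)], sizes)
    out = pd.Series(labels, index=fpkm.index[order])
    return out.reindex(fpkm.index)


def percent_in_class(n_class: int, n_total: int) -> float:
    """Percentage of genes in a class, rounded to one decimal (e.g. 127/512 -> 24.8)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_class <= n_total:
        raise ValueError("need 0 <= n_class <= n_total")
    return round(100.0 * n_class / n_total, 1)


def cpm_normalize(counts, library_size: float):
    """Counts per million mapped reads."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return np.asarray(counts, dtype=float) * 1e6 / library_size


def build_silencing_table(
    counts: pd.DataFrame,
    fpkm: pd.Series | None = None,
    min_reads: int = 10,
    filter_mode: str = "per_sample",
) -> pd.DataFrame:
    """Full per-gene silencing summary from an allele-split count table.

    Filters to informative genes, computes per-replicate allelic ratios,
    averages them per condition at the ratio level, then scores and
    classifies each gene. If an FPKM series (indexed by gene_id) is given,
    genes are additionally assigned expression groups E1-E3.
    """
    filtered = filter_informative(counts, min_reads=min_reads, mode=filter_mode)
    if filtered.empty:
        return pd.DataFrame(
            columns=["gene_id", "ratio_nodox", "ratio_dox", "z", "silencing_class", "n_informative_reads"]
        )
    work = filtered.copy()
    work["ratio"] = allelic_ratio(work["xi"], work["xa"])
    per_cond = work.groupby(["gene_id", "condition"])["ratio"].mean().unstack("condition")
    if not {"dox", "nodox"} <= set(per_cond.columns):
        raise ValueError("count table must contain both 'dox' and 'nodox' samples")
    out = pd.DataFrame(
        {
            "gene_id": per_cond.index,
            "ratio_nodox": per_cond["nodox"].to_numpy(),
            "ratio_dox": per_cond["dox"].to_numpy(),
        }
    )
    out["z"] = silencing_score(out["ratio_dox"], out["ratio_nodox"])
    out["silencing_class"] = classify_silencing(out["z"])
    reads = (work["xi"] + work["xa"]).groupby(work["gene_id"]).sum()
    out["n_informative_reads"] = reads.reindex(out["gene_id"]).to_numpy()
    if fpkm is not None:
        groups = expression_quantiles(pd.Series(fpkm).reindex(out["gene_id"]))
        out["expression_group"] = groups.to_numpy()
    return out.reset_index(drop=True)


def compare_genotypes(
    table_mutant: pd.DataFrame, table_wt: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene silencing deficiency (z_mutant - z_wt) over shared genes.

    Genes missing from either table are skipped with a log message.
    """
    mut = table_mutant.set_index("gene_id")["z"]
    wt = table_wt.set_index("gene_id")["z"]
    shared = mut.index.intersection(wt.index)
    skipped = len(mut.index.union(wt.index)) - len(shared)
    if skipped:
        logger.info("compare_genotypes: %d genes missing from one table, skipped", skipped)
    return pd.DataFrame(
        {
            "gene_id": shared,
            "z_mutant": mut.reindex(shared).to_numpy(),
            "z_wt": wt.reindex(shared).to_numpy(),
            "deficiency": silencing_deficiency(mut.reindex(shared), wt.reindex(shared)).to_numpy(),
        }
    )
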