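"""Synthetic data generator for the allelic-silencing pipeline.

Emulates the statistical structure of an Xist-inducible interspecific mESC
experiment: allele-split ChrRNA-seq counts whose NoDox allelic ratio is
centred on 0.5 with beta-binomial overdispersion, doxycycline-induced
Xi-specific repression whose magnitude decays with topological distance
from the Xist locus and is attenuated for highly expressed genes, a
promoter chromatin-state segmentation, a distance-decaying viewpoint
contact profile, and spike-in-bearing allelic ChIP window counts.

The simulator's definition of truth: a gene with silencing fraction
``s`` keeps its Xa output and emits ``1 - s`` of its Xi output, so the
induced allelic ratio is ``p = (1 - s) / (2 - s)`` (0.5 at s=0, 0 at s=1).
Every generator is a pure function of its config and seed.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .fourc import VirtualFourCProfile

# ChromHMM-style 12-state vocabulary; state 5 is the Polycomb-repressed
# (pre-H3K27me3) proxy and state 7 the pre-active promoter state.
STATE_NAMES: dict[int, str] = {
    1: "CTCF-binding",
    2: "Intergenic_Region",
    3: "Heterochromatin",
    4: "Enhancer",
    5: "RepressedChromatin",
    6: "BivalentChromatin",
    7: "ActivePromoter",
    8: "StrongEnhancer",
    9: "TranscriptionTransition",
    10: "TranscriptionElongation/GeneBody",
    11: "Weak/poised_Enhancer",
    12: "LowSignal/RepetitiveElements",
}
PRE_K27_STATE = 5
PRE_ACTIVE_STATE = 7

# relative weights for promoter states other than pre-active / pre-H3K27me3
_OTHER_STATE_WEIGHTS = {
    1: 0.05, 2: 0.20, 3: 0.08, 4: 0.08, 6: 0.08,
    8: 0.08, 9: 0.08, 10: 0.20, 11: 0.08, 12: 0.07,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic chromosome.

    Defaults emulate the autosomal (chromosome 3) transgene model: ~500
    genes with informative SNPs on a 160 Mb chromosome, viewpoint at the
    reported transgene integration region (~125.81 Mb), promoter-state
    fractions of roughly 180/500 pre-active and 45/500 pre-H3K27me3 genes.
    """

    n_genes: int = 500
    chrom_length: int = 160_000_000
    xist_locus: int = 125_810_000
    depth_mean: float = 200.0          # expected allelic reads per gene
    dispersion: float = 0.01           # beta-binomial rho in [0, 1)
    expr_logmean: float = 1.0          # log-normal FPKM parameters
    expr_logsd: float = 1.0
    s_max: float = 0.8                 # maximal Xi silencing fraction
    alpha: float = 1.0                 # distance-decay exponent (>= 0)
    expr_effect: float = 0.5           # multiplier for top-tertile expression
    state_effect: float = 1.3          # multiplier (>= 1) for pre-H3K27me3 genes
    pathway_multiplier: float = 1.0    # per-genotype attenuation m (WT = 1)
    contact_decay: float = 60_000_000.0  # bp scale of exponential 4C decay
    chip_gain: float = 3.0             # Dox Xi ChIP elevation near pre-K27 genes
    frac_preactive: float = 0.36
    frac_pre_k27: float = 0.09
    bin_size: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be at least 2")
        if not 0 < self.xist_locus < self.chrom_length:
            raise ValueError("need chrom_length > xist_locus > 0")
        if not 0 <= self.dispersion < 1:
            raise ValueError("dispersion rho must be in [0, 1)")
        if not 0 <= self.s_max <= 1:
            raise ValueError("s_max must be in [0, 1]")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 0 <= self.expr_effect <= 1:
            raise ValueError("expr_effect must be in [0, 1]")
        if self.state_effect < 1:
            raise ValueError("state_effect must be >= 1")
        if not 0 <= self.pathway_multiplier <= 1:
            raise ValueError("pathway_multiplier must be in [0, 1]")
        if self.contact_decay <= 0 or self.depth_mean <= 0:
            raise ValueError("contact_decay and depth_mean must be positive")
        if self.frac_preactive + self.frac_pre_k27 > 1:
            raise ValueError("promoter-state fractions exceed 1")

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(config: SimulationConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, salt]))


def _bin_centre(position: np.ndarray | int, bin_size: int) -> np.ndarray:
    return (np.asarray(position) // bin_size) * bin_size + bin_size / 2


def expected_proximity(config: SimulationConfig, positions) -> np.ndarray:
    """Noise-free 3D proximity of each position's 1 Mb bin, 1.0 at the viewpoint bin."""
    centres = _bin_centre(positions, config.bin_size)
    vp_centre = _bin_centre(config.xist_locus, config.bin_size)
    return np.exp(-np.abs(centres - vp_centre) / config.contact_decay)


def dox_ratio(s) -> np.ndarray:
    """Expected induced allelic ratio for silencing fraction s (equal-Xa model)."""
    s = np.asarray(s, dtype=float)
    return (1.0 - s) / (2.0 - s)


def simulate_genes(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place genes on the chromosome and draw their ground truth.

    Returns ``(genes, truth)``: a gene annotation table (gene_id, chrom,
    strand, tss, locus, fpkm, promoter_state) and the ground-truth table
    with the per-gene true silencing fraction
    ``s = s_max * prox**alpha * e * c * m`` (e = expr_effect for the top
    expression tertile, c = state_effect for pre-H3K27me3 genes, m the
    genotype pathway multiplier; capped at 1).
    """
    rng = _rng(config, 1)
    # unique positions, away from the extreme ends so promoter windows fit
    lo, hi = 10_000, config.chrom_length - 10_000
    positions = np.sort(rng.choice(hi - lo, size=config.n_genes, replace=False) + lo)
    strands = rng.choice(["+", "-"], size=config.n_genes)
    fpkm = rng.lognormal(config.expr_logmean, config.expr_logsd, size=config.n_genes)

    other_states = np.array(sorted(_OTHER_STATE_WEIGHTS))
    other_w = np.array([_OTHER_STATE_WEIGHTS[s] for s in other_states])
    other_w = other_w / other_w.sum() * (1 - config.frac_preactive - config.frac_pre_k27)
    state_ids = np.concatenate(([PRE_ACTIVE_STATE, PRE_K27_STATE], other_states))
    state_p = np.concatenate(([config.frac_preactive, config.frac_pre_k27], other_w))
    states = rng.choice(state_ids, size=config.n_genes, p=state_p)

    prox = expected_proximity(config, positions)
    tertile = np.quantile(fpkm, 2 / 3)
    e = np.where(fpkm >= tertile, config.expr_effect, 1.0)
    c = np.where(states == PRE_K27_STATE, config.state_effect, 1.0)
    s_true = np.clip(
        config.s_max * prox**config.alpha * e * c * config.pathway_multiplier, 0.0, 1.0
    )

    gene_ids = [f"gene{i:04d}" for i in range(config.n_genes)]
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": "chrSim",
            "strand": strands,
            "tss": positions,
            "locus": positions,
            "fpkm": fpkm,
            "promoter_state": states,
        }
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "s_true": s_true,
            "proximity_true": prox,
            "fpkm": fpkm,
            "promoter_state_true": states,
            "high_expression": fpkm >= tertile,
        }
    )
    return genes, truth


def _beta_binomial(rng: np.random.Generator, n: np.ndarray, p: np.ndarray, rho: float) -> np.ndarray:
    """Beta-binomial draws with mean np and overdispersion rho; rho=0 is binomial."""
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(n)
    degenerate = (p <= 0) | (p >= 1)
    out[p >= 1] = n[p >= 1]
    free = ~degenerate
    if free.any():
        if rho == 0:
            out[free] = rng.binomial(n[free], p[free])
        else:
            a = p[free] * (1 - rho) / rho
            b = (1 - p[free]) * (1 - rho) / rho
            pg = rng.beta(a, b)
            out[free] = rng.binomial(n[free], pg)
    return out


def simulate_allelic_counts(
    truth: pd.DataFrame,
    config: SimulationConfig,
    condition: str,
    n_replicates: int = 3,
    genotype: str = "WT",
) -> pd.DataFrame:
    """Draw an allele-split count table for one condition.

    Per gene and replicate the total allelic depth is
    ``N ~ Poisson(depth_mean * FPKM / mean FPKM)`` and the Xi count is
    beta-binomial with success probability 0.5 (NoDox) or
    ``(1 - s) / (2 - s)`` (Dox) and overdispersion ``rho``.
    """
    if condition not in ("dox", "nodox"):
        raise ValueError("condition must be 'dox' or 'nodox'")
    salt = 2 if condition == "nodox" else 3
    genotype_salt = zlib.crc32(genotype.encode()) % 100_000  # stable across processes
    rng = _rng(config, salt + 10 * genotype_salt)
    fpkm = truth["fpkm"].to_numpy()
    lam = config.depth_mean * fpkm / fpkm.mean()
    p = np.full(len(truth), 0.5) if condition == "nodox" else dox_ratio(truth["s_true"].to_numpy())

    frames = []
    for rep in range(1, n_replicates + 1):
        n = rng.poisson(lam)
        xi = _beta_binomial(rng, n, p, config.dispersion)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": truth["gene_id"],
                    "sample_id": f"{genotype}_{condition}_rep{rep}",
                    "condition": condition,
                    "genotype": genotype,
                    "replicate": rep,
                    "xi": xi,
                    "xa": n - xi,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_experiment(
    config: SimulationConfig, n_replicates: int = 3, genotype: str = "WT"
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Genes + truth + a combined Dox/NoDox count table for one genotype."""
    genes, truth = simulate_genes(config)
    counts = pd.concat(
        [
            simulate_allelic_counts(truth, config, "nodox", n_replicates, genotype),
            simulate_allelic_counts(truth, config, "dox", n_replicates, genotype),
        ],
        ignore_index=True,
    )
    return genes, truth, counts


def simulate_segmentation(genes: pd.DataFrame, config: SimulationConfig, flank: int = 2000) -> pd.DataFrame:
    """Non-overlapping 12-state segmentation consistent with the genes' promoter states.

    Each promoter gets a ``[tss - flank, tss + flank)`` interval of its true
    state (truncated at the midpoint between crowded neighbours); the rest
    of the chromosome is Intergenic_Region (state 2).
    """
    g = genes.sort_values("tss").reset_index(drop=True)
    starts = np.maximum(g["tss"] - flank, 0).to_numpy()
    ends = np.minimum(g["tss"] + flank, config.chrom_length).to_numpy()
    # resolve overlaps at the midpoint between adjacent promoters
    for i in range(1, len(g)):
        if starts[i] < ends[i - 1]:
            mid = (int(g.loc[i - 1, "tss"]) + int(g.loc[i, "tss"])) // 2
            ends[i - 1] = mid
            starts[i] = mid
    rows = []
    cursor = 0
    for start, end, state in zip(starts, ends, g["promoter_state"]):
        if start > cursor:
            rows.append(("chrSim", cursor, int(start), 2))
        if end > start:
            rows.append(("chrSim", int(start), int(end), int(state)))
        cursor = max(cursor, int(end))
    if cursor < config.chrom_length:
        rows.append(("chrSim", cursor, config.chrom_length, 2))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])


def simulate_4c(config: SimulationConfig, amplitude: float = 1000.0) -> VirtualFourCProfile:
    """Poisson contact profile decaying exponentially from the viewpoint bin."""
    rng = _rng(config, 4)
    n_bins = int(np.ceil(config.chrom_length / config.bin_size))
    centres = (np.arange(n_bins) + 0.5) * config.bin_size
    vp_centre = _bin_centre(config.xist_locus, config.bin_size)
    mu = amplitude * np.exp(-np.abs(centres - vp_centre) / config.contact_decay)
    values = rng.poisson(mu).astype(float)
    return VirtualFourCProfile(
        chrom="chrSim", bin_size=config.bin_size, viewpoint=config.xist_locus, values=values
    )


def simulate_chip(
    config: SimulationConfig,
    truth: pd.DataFrame,
    genes: pd.DataFrame,
    window_size: int = 250_000,
    base_rate: float = 50.0,
    mark: str = "H3K27me3",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Allele-split ChIP window counts plus spike-in library sizes.

    Four samples (WT NoDox/Dox, one replicate each of Xi and Xa tracks in
    one table). Windows overlapping a pre-H3K27me3 promoter have their Dox
    Xi rate multiplied by ``chip_gain``; each sample carries a random depth
    scale that multiplies both its window counts and its spike-in library,
    so spike-in calibration removes it by construction.

    Returns ``(windows, libraries)``: windows has one row per
    (sample_id, window) with xi/xa counts; libraries has per-sample
    experimental and spike-in totals.
    """
    rng = _rng(config, 5)
    n_windows = int(np.ceil(config.chrom_length / window_size))
    starts = np.arange(n_windows) * window_size

    k27_tss = genes.loc[genes["promoter_state"] == PRE_K27_STATE, "tss"].to_numpy()
    is_k27_window = np.zeros(n_windows, dtype=bool)
    if k27_tss.size:
        is_k27_window[np.unique(k27_tss // window_size)] = True

    samples = [("WT_nodox", "nodox"), ("WT_dox", "dox")]
    win_frames, lib_rows = [], []
    for sample_id, condition in samples:
        depth_scale = rng.lognormal(0.0, 0.2)
        xi_rate = np.full(n_windows, base_rate)
        xa_rate = np.full(n_windows, base_rate)
        if condition == "dox":
            xi_rate = np.where(is_k27_window, base_rate * config.chip_gain, base_rate)
        xi = rng.poisson(xi_rate * depth_scale)
        xa = rng.poisson(xa_rate * depth_scale)
        win_frames.append(
            pd.DataFrame(
                {
                    "sample_id": sample_id,
                    "condition": condition,
                    "mark": mark,
                    "start": starts,
                    "end": starts + window_size,
                    "xi": xi,
                    "xa": xa,
                }
            )
        )
        experimental_total = float((xi + xa).sum()) * 20.0  # windows are a slice of the genome
        spike_total = 1e6 * depth_scale
        lib_rows.append(
            {
                "sample_id": sample_id,
                "condition": condition,
                "mark": mark,
                "experimental_total": experimental_total,
                "spike_total": spike_total,
            }
        )
    return pd.concat(win_frames, ignore_index=True), pd.DataFrame(lib_rows)
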