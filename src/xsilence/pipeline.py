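"""End-to-end orchestration: simulate -> score -> features -> classify -> compare.

Runs the whole allelic-silencing analysis on synthetic (or supplied)
data and writes every artefact as TSV/BED/bedGraph together with a config
snapshot, so a run is reproducible from its output directory alone.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import chip as chip_mod
from . import features as feat_mod
from . import fourc as fourc_mod
from . import io as io_mod
from . import silencing as sil_mod
from . import simulate as sim_mod
from . import stats as stats_mod
from .simulate import PRE_ACTIVE_STATE, PRE_K27_STATE

logger = logging.getLogger(__name__)


def run_pipeline(config: io_mod.PipelineConfig, outdir) -> Path:
    """Execute the full analysis and return the output directory.

    Stages: simulate (optional) -> informative-read filter -> silencing
    scoring/classification -> feature matrix -> random-forest training ->
    mutant comparison -> 4C correlation -> ChIP calibration and gain.
    Every stage failure raises with the stage named.
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_snapshot.yaml")
    summary: dict = {"seed": config.seed}

    stage = "simulate"
    try:
        if config.simulate:
            sim_cfg = sim_mod.SimulationConfig(**{"seed": config.seed, **config.simulation})
            genes, truth = sim_mod.simulate_genes(sim_cfg)
            counts = pd.concat(
                [
                    sim_mod.simulate_allelic_counts(truth, sim_cfg, "nodox"),
                    sim_mod.simulate_allelic_counts(truth, sim_cfg, "dox"),
                ],
                ignore_index=True,
            )
            mut_cfg = sim_mod.SimulationConfig(
                **{
                    "seed": config.seed,
                    **config.simulation,
                    "pathway_multiplier": config.mutant_pathway_multiplier,
                }
            )
            _, mut_truth = sim_mod.simulate_genes(mut_cfg)
            mut_counts = pd.concat(
                [
                    sim_mod.simulate_allelic_counts(mut_truth, mut_cfg, "nodox", genotype="mutant"),
                    sim_mod.simulate_allelic_counts(mut_truth, mut_cfg, "dox", genotype="mutant"),
                ],
                ignore_index=True,
            )
            segmentation = feat_mod.Segmentation(sim_mod.simulate_segmentation(genes, sim_cfg))
            profile = sim_mod.simulate_4c(sim_cfg)
            chip_windows, chip_libs = sim_mod.simulate_chip(sim_cfg, truth, genes)
            xist_locus = sim_cfg.xist_locus
            io_mod.write_counts(counts, out / "counts_wt.tsv")
            io_mod.write_counts(mut_counts, out / "counts_mutant.tsv")
            truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
            genes.to_csv(out / "genes.tsv", sep="\t", index=False)
            io_mod.write_segmentation(segmentation, out / "segmentation.bed")
            io_mod.write_profile(profile, out / "virtual_4c.bedgraph")
        else:
            counts = io_mod.read_counts(config.counts)
            mut_counts = None
            genes = pd.read_csv(config.annotation, sep="\t")
            segmentation = io_mod.read_segmentation(config.segmentation)
            xist_locus = int(config.simulation.get("xist_locus", 125_810_000))
            pairs = io_mod.read_contacts(config.contacts)
            profile = fourc_mod.virtual_4c(
                pairs, viewpoint=xist_locus, bin_size=config.bin_size
            )
            chip_windows = (
                pd.read_csv(config.chip_windows, sep="\t") if config.chip_windows else None
            )
            chip_libs = (
                pd.read_csv(config.chip_libraries, sep="\t") if config.chip_libraries else None
            )
    except Exception as exc:  # re-raise with the stage named
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    stage = "silencing"
    try:
        fpkm = genes.set_index("gene_id")["fpkm"]
        table = sil_mod.build_silencing_table(
            counts, fpkm=fpkm, min_reads=config.min_reads, filter_mode=config.filter_mode
        )
        table.to_csv(out / "silencing_wt.tsv", sep="\t", index=False)
        logger.info("silencing: %d informative genes", len(table))
        class_counts = table["silencing_class"].value_counts()
        summary["n_genes"] = int(len(table))
        summary["percent_high"] = sil_mod.percent_in_class(
            int(class_counts.get("high", 0)), len(table)
        )
        summary["percent_silenced"] = sil_mod.percent_in_class(
            int(class_counts.get("high", 0) + class_counts.get("low", 0)), len(table)
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    stage = "features"
    try:
        kept = genes[genes["gene_id"].isin(table["gene_id"])]
        matrix = feat_mod.build_feature_matrix(kept, segmentation, profile, xist_locus)
        matrix.to_csv(out / "features.tsv", sep="\t")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    stage = "train"
    try:
        z = table.set_index("gene_id")["z"].reindex(matrix.index)
        model = stats_mod.SilencingEfficiencyModel.from_silencing(
            matrix, z, n_trees=config.n_trees, n_folds=config.n_folds
        )
        report = model.fit(seed=config.seed)
        report.to_frame().to_csv(out / "classifier_report.tsv", sep="\t")
        (out / "classifier_summary.txt").write_text(report.summary() + "\n")
        summary["auc"] = report.auc
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    stage = "compare"
    try:
        if mut_counts is not None:
            mut_table = sil_mod.build_silencing_table(
                mut_counts, min_reads=config.min_reads, filter_mode=config.filter_mode
            )
            mut_table.to_csv(out / "silencing_mutant.tsv", sep="\t", index=False)
            merged = sil_mod.compare_genotypes(mut_table, table)
            merged.to_csv(out / "deficiency.tsv", sep="\t", index=False)
            p_def = stats_mod.wilcoxon_rank_sum(
                merged["z_mutant"], merged["z_wt"], alternative="greater"
            )
            summary["mutant_deficiency_p"] = p_def
            # size-matched permutation comparison across promoter classes
            state = genes.set_index("gene_id")["promoter_state"]
            z_def = merged.set_index("gene_id")
            pre_active = z_def[state.reindex(z_def.index) == PRE_ACTIVE_STATE]
            pre_k27 = z_def[state.reindex(z_def.index) == PRE_K27_STATE]
            if len(pre_active) >= len(pre_k27) >= 2:
                perm = stats_mod.matched_permutation_test(
                    pre_active["z_mutant"],
                    pre_k27["z_mutant"],
                    pre_active["z_wt"],
                    n_perm=config.n_perm,
                    subsample_size=min(config.subsample_size, len(pre_active)),
                    seed=config.seed,
                )
                perm.to_frame().to_csv(out / "permutation_report.tsv", sep="\t", index=False)
                summary["permutation_mean_neglog10p"] = perm.mean
                summary["permutation_sd"] = perm.sd
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    stage = "correlate"
    try:
        tss = genes.set_index("gene_id")["tss"]
        windows = fourc_mod.windowed_silencing(
            counts, tss, bin_size=config.bin_size,
            chrom_length=profile.n_bins * profile.bin_size,
            min_reads=config.min_window_reads,
        )
        windows.to_csv(out / "windowed_silencing.tsv", sep="\t")
        rho, p, n = fourc_mod.correlate_profile(
            profile,
            windows["z"],
            xist_locus,
            exclusion_flank=config.exclusion_flank,
            min_reads=config.min_window_reads,
            window_reads=windows[["reads_dox", "reads_nodox"]].min(axis=1),
        )
        pd.DataFrame(
            [{"rho": rho, "p": p, "n_windows": n}]
        ).to_csv(out / "correlation_4c.tsv", sep="\t", index=False)
        summary["spearman_rho_4c"] = rho
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    stage = "chip"
    try:
        if chip_windows is not None and chip_libs is not None:
            factors = chip_mod.calibration_factors(
                chip_libs, reference_id="WT_nodox", target_total=config.target_total
            )
            factors.to_frame().to_csv(out / "calibration_factors.tsv", sep="\t")
            calibrated = chip_mod.calibrate_windows(chip_windows, factors)
            gain = chip_mod.gain_track(calibrated, "WT_dox", "WT_nodox")
            gain["chrom"] = "chrSim"
            io_mod.write_bedgraph(gain, out / "chip_gain.bedgraph", value_col="gain")
            summary["mean_chip_gain"] = float(gain["gain"].mean())
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return out
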