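# Methods

## Silencing model and score

Silencing is read out allele-specifically. For a gene with Xi (inactive,
Xist-bearing allele) and Xa (active allele) SNP-informative read counts,
the allelic ratio is Xi/(Xi+Xa): 0.5 under biallelic expression, 0 when
the Xi copy is fully silenced. The silencing score is the change on
induction,

    z = [Xi/(Xi+Xa)]_Dox − [Xi/(Xi+Xa)]_NoDox,

so z is negative when the gene is silenced. Per-replicate ratios are
averaged at the ratio level (not pooled at the count level), which keeps
replicates equally weighted regardless of depth. Classes are weak/none
(z > −0.05), low (−0.2 < z ≤ −0.05) and high (z ≤ −0.2). The printed
form of the middle band is ambiguous at its boundaries; we resolve them
so the stronger class wins at −0.2 (z ≤ −0.2 → high) and the milder
boundary value −0.05 stays in *low*, preserving the weak/low/high
ordering.

The informative-read filter defaults to ≥ 10 Xi+Xa reads **in every
sample** of the comparison, which guarantees a defined ratio in both
conditions; a `summed` mode (≥ 10 reads totalled over samples) is
exposed because the looser reading of "across all the samples" is also
defensible.

## Synthetic data: what it emulates

The generator (`simulate.SimulationConfig`) encodes the study
conditions as defaults and is a pure function of (config, seed):

- **Chromosome geometry** — 500 genes with informative SNPs on a
  160 Mb chromosome, viewpoint (Xist transgene) at 125.81 Mb.
- **Ground-truth silencing** — each gene's silencing fraction is
  s = s_max · prox^α · e · c · m, where prox is the (noise-free)
  exponential contact decay of the gene's 1 Mb bin from the viewpoint,
  e = `expr_effect` (0.5) for top-tertile-expression genes, c =
  `state_effect` (1.3) for pre-H3K27me3-promoter genes (capped at
  s ≤ 1), and m is a per-genotype pathway multiplier (1 for WT, e.g.
  0.1 for a Spen-null-like knockout).
- **Counts** — per gene and replicate, total allelic depth is
  Poisson(depth_mean · FPKM/mean FPKM) with log-normal FPKM; the Xi
  count is beta-binomial with p = 0.5 (NoDox) or p = (1−s)/(2−s)
  (Dox) and overdispersion ρ = 0.01. The equal-Xa convention — Xa
  output unchanged, Xi output scaled by 1−s — makes s interpretable as
  the fractional loss of Xi output and gives the closed form used
  throughout the tests.
- **Chromatin states** — promoter states drawn with pre-active
  (state 7) and pre-H3K27me3 (state 5) fractions 0.36 and 0.09
  (≈ 180 and 45 genes of 500), the remainder spread over the other ten
  states; the emitted segmentation places each promoter's state in
  TSS ± 2 kb over an intergenic background, truncating at midpoints
  where promoters crowd.
- **4C profile** — Poisson counts around an exponential decay from the
  viewpoint bin; **ChIP** — windowed allele-split counts where Dox Xi
  windows near pre-H3K27me3 promoters are elevated by `chip_gain`,
  with each sample's spike-in library scaling with its depth so
  calibration invariance holds by construction.

Parameter scales were fixed once against the qualitative shape of the
real experiment: `contact_decay` = 60 Mb so that day-1 silencing is
chromosome-wide but visibly weaker distally (distal genes retain
roughly a quarter of proximal silencing rather than none);
`depth_mean` = 200 allelic reads per gene and 3 biological replicates,
matching the depth and replication typical of these chromatin RNA-seq
designs; s_max = 0.8 so proximal genes approach but do not reach
complete silencing at day 1.

What the generator does **not** emulate: mappability and SNP-density
variation along the chromosome, reference bias in allelic assignment,
gene-length effects, correlated noise between neighbouring genes, or
escape genes with actively maintained biallelic expression. Passing
tests therefore demonstrate that the pipeline's operations are correct
and that its statistics behave as designed under the assumed noise
model — not that real-data artefacts are handled.

## Feature construction

Sixteen features per gene, all in [0, 1]: two expression scalings
(FPKM divided by the maximum; tie-averaged ranks mapped linearly onto
[0, 1]), genomic proximity 1 − |Xist_locus − gene_locus|/Xist_locus
(clamped at 0, since the formula goes negative beyond twice the
viewpoint coordinate), topological proximity (the gene's 1 Mb virtual
4C value divided by the profile maximum), and the bp fraction of each
of the 12 chromatin states in 4 kb windows centred on the gene's TSSs,
averaged with weights proportional to TSS usage. Uncovered bp in the
fraction vectors are assigned to state 12 (LowSignal) so each vector
sums to 1; in the single predominant-state call, uncovered bp count
toward no state and a fully uncovered window is "unassigned".
Predominant-state ties go to the lowest state index — a seeded random
choice was rejected so that annotations are reproducible artefacts.
The representative TSS is the one used by the most transcripts, ties
broken by a seeded uniform draw.

## Classifier

`SilencingEfficiencyModel` wraps a scikit-learn random forest:
50 trees, 5-fold stratified cross-validation, labels High/Low from a
median split of z (genes below the median — more silenced — are High;
genes exactly at the median go to Low). The AUC is computed by the
rank formulation from pooled out-of-fold probabilities, so it is an
honest generalisation estimate. Importance defaults to mean decrease
in impurity of a forest refit on all genes, normalised to sum 1;
permutation importance is available as an option since impurity-based
scores can favour high-cardinality features.

## Calibration and gain

With per-sample experimental and spike-in library sizes, the factor

    factor_i = (spike_ref / spike_i) · (target_total / experimental_ref)

scales every sample onto the reference's spike-in axis and the
reference itself to exactly `target_total` (10 M reads). The reference
defaults to the WT NoDox sample of the mark. Multiplying one sample's
experimental and spike-in totals by any c > 0 leaves its calibrated
signal unchanged. Gain G = (Xi−Xa)_Dox − (Xi−Xa)_NoDox is computed on
calibrated window counts (250 kb by default); metaprofiles rescale each
gene body to a fixed number of slices plus fixed-width 50 bp flank bins
and average the step-function track at slice centres across genes — a
deliberately simple replacement for external metaprofile tools, since
the comparison it supports is qualitative.

## Statistics: numerical choices

- **Rank-sum**: exact enumeration (via the exact Mann-Whitney
  distribution) when the pooled sample has ≤ 20 values and no ties;
  otherwise the normal approximation with tie correction and
  continuity correction. The branch rule is deterministic, so p-values
  are bit-for-bit reproducible.
- **Size-matched permutations**: to compare a 180-gene class with a
  45-gene class, 180 permutations each draw 45 genes without
  replacement from the large class and run the one-sided deficiency
  rank-sum test against the reference scores; the spread (population
  sd) of the −log10 p values is the significance range. The sd is
  computed after subtracting the first value so the degenerate case
  (large class exactly subsample-sized) is exactly 0. −log10 p is used
  as the significance scale throughout.
- **Spearman correlation** (virtual 4C vs windowed signal): windows
  overlapping Xist ± 10 Mb are excluded (overlap, not containment);
  p by the large-sample t approximation, or exact permutation below
  n = 10. Genes map to windows by TSS position.
- **Virtual 4C**: a pair with both ends in the viewpoint bin counts
  once, toward the viewpoint bin.
- **PCA**: centred SVD; component signs fixed by making the
  largest-magnitude loading positive, so score plots are reproducible.
- **Expression groups**: genes sorted by FPKM with gene-id tie-break,
  split into k equal groups with remainders to the lower groups.
- **Degenerate inputs** raise rather than coerce: zero-read ratios,
  all-zero max-scaling, empty groups, single-class labels, zero
  spike-in libraries (naming the sample).

## Problem sizes

The test suite and the acceptance script run the pipeline at 120–500
genes, 180 permutations, 50-tree forests and ~160 1 Mb windows —
the scale of a single chromosome analysis, chosen so the full suite
completes in well under a minute while every statistic operates in the
regime (hundreds of genes, tens of windows) it was designed for.

## Known limitations

- The silencing model couples 3D proximity and silencing through one
  decay scale; real contact maps have domain structure the exponential
  ignores (TAD boundaries, compartments).
- The 4C-derived proximity feature and the generator's truth share the
  same decay family, so classifier recovery on synthetic data is an
  internal-consistency check, not external validation.
- Window-level silencing pools counts (unlike the gene-level ratio
  averaging), so deeply covered genes dominate their window.
- The classifier report's importances are descriptive; no attempt is
  made at significance testing of importance ranks.
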