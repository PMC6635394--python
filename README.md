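# xsilence

Chromosome-wide analysis of allele-specific gene silencing in
Xist-inducible mouse embryonic stem cell models.

When the long non-coding RNA Xist is induced on one chromosome of an
interspecific (129S × Cast) cell line, strain-specific SNPs let
chromatin RNA-seq reads be assigned to the Xist-bearing (Xi) or active
(Xa) allele. `xsilence` implements the downstream analysis of such
allele-split count tables:

- **Silencing scoring** — per-gene allelic ratio Xi/(Xi+Xa) and the
  silencing score *z* = [Xi/(Xi+Xa)]<sub>Dox</sub> −
  [Xi/(Xi+Xa)]<sub>NoDox</sub>, with genes classed *weak/none*
  (*z* > −0.05), *low* (−0.2 < *z* ≤ −0.05) or *high* (*z* ≤ −0.2) and
  binned into equal-size expression groups E1 < E2 < E3.
- **Feature engineering** — promoter chromatin state from a 12-state
  ChromHMM-style segmentation (predominant state in TSS ± 2 kb; state
  fractions over 4 kb TSS windows weighted by TSS usage), genomic (2D)
  and topological (3D) proximity to the Xist locus.
- **Silencing-efficiency classifier** — a random forest (50 trees,
  5-fold stratified CV) predicting High vs Low silencing from the 16
  features, exposed statsmodels-style:
  `SilencingEfficiencyModel(...).fit()` returns a results object with
  out-of-fold AUC, normalised feature importances and `summary()`.
- **Spike-in calibrated ChIP** — per-sample calibration factors
  referenced to an exogenous spike-in (reference scaled to 10 M reads),
  absolute allelic gain *G* = (Xi−Xa)<sub>Dox</sub> −
  (Xi−Xa)<sub>NoDox</sub>, region FPKM and gene-class metaprofiles.
- **Virtual 4C** — viewpoint contact profiles at 1 Mb resolution,
  Spearman correlation with 1 Mb-windowed silencing (excluding the
  Xist locus ± 10 Mb, windows with ≥ 20 allelic reads), and a
  densest-window locator for transgene integration sites.
- **Statistics** — exact/asymptotic Wilcoxon rank-sum, size-matched
  180-permutation group comparisons, hypergeometric set overlap,
  one-way ANOVA and replicate PCA.
- **Synthetic data** — a seeded generator producing allele-split count
  tables (beta-binomial noise, NoDox ratios centred on 0.5,
  distance-decaying Dox silencing, expression and chromatin-state
  effects, per-genotype pathway attenuation), segmentations, 4C
  profiles and spike-in ChIP counts with ground truth, so the whole
  pipeline is exercisable and testable end to end.

## Worked example

```python
import pandas as pd
from xsilence import simulate as sim, silencing as sil, features as ft, stats as xst

cfg = sim.SimulationConfig(n_genes=500, seed=7)
genes, truth, counts = sim.simulate_experiment(cfg)

table = sil.build_silencing_table(counts, fpkm=genes.set_index("gene_id")["fpkm"])
print(table["silencing_class"].value_counts().to_dict())
# {'low': 236, 'weak_none': 151, 'high': 97}

seg = ft.Segmentation(sim.simulate_segmentation(genes, cfg))
profile = sim.simulate_4c(cfg)
kept = genes[genes.gene_id.isin(table.gene_id)]
matrix = ft.build_feature_matrix(kept, seg, profile, cfg.xist_locus)
z = table.set_index("gene_id")["z"].reindex(matrix.index)
res = xst.SilencingEfficiencyModel.from_silencing(matrix, z).fit(seed=7)
print(res.summary())
```

```
Silencing-efficiency random forest
==================================
trees: 50   folds: 5   seed: 7
out-of-fold AUC: 0.833

feature importance (sums to 1):
  dist2d             0.2769
  dist3d             0.2545
  expr_maxscaled     0.1938
  expr_rankscaled    0.1695
  ...
```

Of 488 informative genes, roughly a fifth are highly silenced and the
classifier recovers the determinants built into the generator: the two
proximity features and the expression scalings carry the top importance
mass — silencing is most efficient close to the Xist locus and for
weakly expressed genes.

The same analysis is available from the shell:

```bash
xsilence simulate --seed 7 --n-genes 500 --out run/
xsilence silencing --counts run/counts.tsv --out run/silencing.tsv
xsilence run --seed 7 --out run_full/   # full pipeline incl. mutant contrast
```

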