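# pcttools

Analysis of the **precancer-to-cancer transition** in single-cell RNA-seq
atlases. The package is for computational biologists who have epithelial
single-cell profiles spanning healthy tissue, premalignant lesions and
carcinomas, and want to quantify where each sample and cell sits on the
road to malignancy — and which genes drive the trip.

It implements, as a tested and reusable pipeline:

- **Synthetic atlas generator** — multi-tissue, multi-stage negative-binomial
  count atlases with planted cell types, monotone transition genes,
  expression programs, CNV segments, doublets and full ground truth, for
  parameter-recovery benchmarking (`pcttools.synthetic`).
- **QC and doublets** — the standard cell filters (200–7,000 detected genes,
  ≤ 25% mitochondrial reads) and an artificial-doublet kNN detector
  (pN = 0.25, pK = 0.09, nExp = 0.08·n²/10⁴) (`pcttools.qc`).
- **Iterative-LSI reference projection** — a healthy epithelial reference
  built with four iterations of TF-IDF → rank-32 SVD → Leiden clustering
  (resolutions 0.1/0.2/0.4/0.8, top 3,200 variable genes), projection of
  diseased cells with the frozen IDF/SVD, and 25-nearest-neighbour label
  transfer (`pcttools.lsi`).
- **Malignancy index** — per-sample stem-cell DEGs vs pooled healthy stem
  cells (Wilcoxon, BH FDR ≤ 0.05, |log2FC| ≥ 0.5 in ≥ 2 samples), PCA of
  the sample × gene log2FC matrix, and a principal-curve ordering mapping
  each sample to a position in [0, 1] (`pcttools.axis`).
- **CNV score** — windowed reference-relative expression CNV profiles
  (100-gene moving average, ±3 clip, median re-centring) and the per-cell
  mean-of-squares CNV score (`pcttools.cnv`).
- **Meta-programs** — per-sample NMF (multiplicative updates, elbow rank
  selection over ranks 4–9), consensus modules by K-means over robust
  recurring programs, hypergeometric module-overlap tests, and AUCell
  gene-set activities (`pcttools.metaprograms`).
- **PCT signatures** — the four-way intersection of pseudo-bulk DEGs,
  trajectory subcluster DEGs (avg_log2FC ≥ 0.25, pct.1 ≥ 0.25,
  pct.ratio ≥ 1.5), pseudotime-correlated transition genes and
  meta-program genes, ranked by cross-tissue geometric-mean Spearman
  correlation and truncated to the top 100 per meta-program
  (`pcttools.pct`).

The core quantity is the **malignancy index**: with per-sample stem-cell
log2 fold changes **F** (samples × genes, healthy anchored at **0**), PCA
scores **Z = F·W**, and a principal curve **f(t)** fitted in the top-2 PC
plane, each sample's index is its normalised arc length
`position(s) = (t_s − t_healthy) / (t_max − t_healthy) ∈ [0, 1]`.
The per-cell CNV score is `mean_g v(g,c)²` over smoothed relative
expression `v`, and AUCell activity is the normalised area under a gene
set's recovery curve within the top 5% of each cell's expression ranking.

## Worked example

```python
import scipy.stats, numpy as np
from pcttools import (AtlasConfig, generate_atlas, sample_degs,
                      select_axis_genes, build_axis)
from pcttools.preprocess import lognorm

cfg = AtlasConfig(n_tissues=1,
                  samples_per_stage={"healthy": 10, "precancer": 10, "cancer": 10},
                  cells_per_sample=150, seed=1)
counts, meta, positions, truth = generate_atlas(cfg)

norm = lognorm(counts.matrix)
degs = sample_degs(norm, counts.gene_names, meta)
axis = build_axis(degs, select_axis_genes(degs))
stages = meta.groupby("sample_id")["stage"].first()
pos = axis.positions_for(stages.index.to_numpy(), stages.to_numpy())
planted = np.array([truth.sample_malignancy[s] for s in pos.index])
print(round(scipy.stats.spearmanr(pos, planted).statistic, 3))
```

This prints (on this machine):

```
0.975
```

— the rank agreement between the estimated malignancy index and the
planted per-sample malignancy over 30 samples: healthy samples sit at the
anchor (position 0), precancers at low positions (~0.13 on average here)
and carcinomas near 1 (~0.86), so the index reconstructs the planted
disease continuum almost perfectly. The `examples/` directory has one
narrative script per capability (simulation, QC/doublets, reference
projection, malignancy axis, CNV, meta-programs, full chain).

## Command line

Each stage is also a thin CLI over the library:

```bash
pcttools run-all --seed 1 --out my_run          # full chain on the default atlas
pcttools simulate --seed 7 --out my_run         # or stage by stage
pcttools qc --out my_run
```

A YAML config (`--config run.yaml`, schema in `pcttools.config.RunConfig`)
exposes every stage parameter; all defaults equal the procedure's canonical
values. `run-all` writes a `run_manifest.json` with per-stage
SHA-256 checksums; identical config + seed reproduces it byte-for-byte.

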