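"""Generate a small multi-stage synthetic atlas and summarise its truth.

The atlas has three disease stages with planted malignancy structure; the
printed table shows, per sample, how the stem-cell fraction and mean
pseudotime grow from healthy tissue to cancer — the signal every
downstream stage tries to recover.
"""

from pcttools import AtlasConfig, generate_atlas, truth_report

config = AtlasConfig(
    n_tissues=1,
    samples_per_stage={"healthy": 3, "precancer": 3, "cancer": 3},
    cells_per_sample=150,
    seed=7,
)
counts, cell_meta, gene_positions, truth = generate_atlas(config)

print(f"atlas: {counts.n_genes} genes x {counts.n_cells} cells")
print(f"planted doublet fraction: {truth.is_doublet.mean():.3f}")
print()
print(truth_report(truth).to_string(index=False, float_format=lambda v: f"{v:.3f}"))
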