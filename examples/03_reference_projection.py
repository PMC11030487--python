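"""Build a healthy iterative-LSI reference and project diseased cells.

The reference is built from healthy cells only (four TF-IDF/SVD/Leiden
iterations, 32 dimensions); diseased cells are projected with the stored
IDF and classified by their 25 nearest reference neighbours. The printed
accuracy compares transferred labels with the simulation truth, and the
distances show that cancer stem-like cells land near the reference stem
population — the projection behaviour the malignancy analyses build on.
"""

import numpy as np

from pcttools import (
    AtlasConfig,
    LSIParams,
    build_reference,
    classify_knn,
    generate_atlas,
    project,
)

config = AtlasConfig(
    n_tissues=1,
    samples_per_stage={"healthy": 4, "precancer": 3, "cancer": 3},
    cells_per_sample=150,
    seed=3,
)
counts, meta, _, truth = generate_atlas(config)

healthy = (meta["stage"] == "healthy").to_numpy() & ~truth.is_doublet
model = build_reference(
    counts.subset_cells(healthy),
    meta.loc[healthy, "cell_type"].to_numpy(object),
    LSIParams(seed=1),
)
print("iterations:", model.iteration_log)

diseased = (meta["stage"] != "healthy").to_numpy() & ~truth.is_doublet
result = classify_knn(model, project(model, counts.subset_cells(diseased)))
acc = (result.assigned_label == truth.cell_type[diseased]).mean()
print(f"label-transfer accuracy on diseased cells: {acc:.3f}")

stem_centroid = model.reference_embedding[model.reference_labels == "STM"].mean(axis=0)
cancer_stem = (truth.stage[diseased] == "cancer") & (truth.cell_type[diseased] == "STM")
d_stem = np.linalg.norm(result.embedding[cancer_stem] - stem_centroid, axis=1).mean()
print(f"mean distance of cancer stem cells to reference stem centroid: {d_stem:.4f}")
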