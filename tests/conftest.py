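import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from pcttools.io import CountMatrix
from pcttools.synthetic import AtlasConfig, generate_atlas


@pytest.fixture(scope="session")
def small_atlas():
    """One-tissue atlas, small enough for fast unit tests."""
    cfg = AtlasConfig(
        n_tissues=1,
        samples_per_stage={"healthy": 4, "precancer": 3, "cancer": 3},
        cells_per_sample=150,
        seed=7,
    )
    return cfg, *generate_atlas(cfg)


@pytest.fixture(scope="session")
def medium_atlas():
    """One-tissue atlas with enough samples for sample-level statistics."""
    cfg = AtlasConfig(n_tissues=1, seed=7)
    return cfg, *generate_atlas(cfg)


def toy_counts(dense, gene_names=None, barcodes=None, chromosomes=None):
    dense = np.asarray(dense)
    n_genes, n_cells = dense.shape
    names = gene_names if gene_names is not None else [f"G{i:03d}" for i in range(n_genes)]
    genes = pd.DataFrame(
        {
            "chromosome": chromosomes if chromosomes is not None else ["chr1"] * n_genes,
            "start": np.arange(1, n_genes + 1) * 1000,
        },
        index=pd.Index(names, name="gene_name"),
    )
    bcs = barcodes if barcodes is not None else [f"C{i:03d}" for i in range(n_cells)]
    return CountMatrix(sp.csr_matrix(dense), genes, np.asarray(bcs, dtype=object))
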