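"""Normalisation helpers shared by all stages.

Counts are genes x cells (CSR). "lognorm" means ln(1 + counts scaled to a
fixed library size per cell); the default scale of 10,000 is the standard
single-cell convention, while the CNV stage uses scale 100,000 (counts per
million divided by ten).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


def library_sizes(matrix: sp.spmatrix) -> np.ndarray:
    return np.asarray(matrix.sum(axis=0)).ravel()


def scale_to_depth(matrix: sp.spmatrix, scale: float = 1e4) -> sp.csr_matrix:
    """Depth-normalise columns to a common library size (zero columns stay zero)."""
    lib = library_sizes(matrix)
    inv = np.divide(scale, lib, out=np.zeros_like(lib, dtype=float), where=lib > 0)
    return (sp.csr_matrix(matrix).astype(float) @ sp.diags(inv)).tocsr()


def lognorm(matrix: sp.spmatrix, scale: float = 1e4) -> sp.csr_matrix:
    out = scale_to_depth(matrix, scale)
    out.data = np.log1p(out.data)
    return out


def detected_genes_per_cell(matrix: sp.spmatrix) -> np.ndarray:
    """Number of genes with count >= 1 per cell."""
    return np.asarray((sp.csr_matrix(matrix) > 0).sum(axis=0)).ravel()


def gene_variance(matrix: sp.spmatrix) -> np.ndarray:
    """Row-wise variance of a sparse matrix (population variance)."""
    m = sp.csr_matrix(matrix)
    n = m.shape[1]
    mean = np.asarray(m.mean(axis=1)).ravel()
    sq = m.copy()
    sq.data = sq.data**2
    mean_sq = np.asarray(sq.mean(axis=1)).ravel()
    var = mean_sq - mean**2
    return np.maximum(var, 0.0) * (n / max(n - 1, 1))
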