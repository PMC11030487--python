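"""Cell-level quality control and artificial-doublet kNN detection.

Filters follow the canonical thresholds: cells with fewer than 200 or more
than 7,000 detected genes, or more than 25% mitochondrial reads, are
removed (bounds inclusive for retention). Doublets are flagged per sample
with a simplified artificial-doublet procedure: averaged random cell pairs
are embedded together with the real cells (PCA of log-normalised counts,
20 components), and each real cell's pANN is the fraction of artificial
doublets among its k nearest neighbours (k = round(pK * n_total)); the
nExp highest-pANN cells are flagged, with nExp = round(0.08 * n^2 / 10^4)
by default or 8% of cells under the linear rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import CountMatrix
from .preprocess import detected_genes_per_cell, library_sizes, lognorm


@dataclass
class QCParams:
    min_genes: int = 200
    max_genes: int = 7000
    max_mito_fraction: float = 0.25
    pN: float = 0.25
    pK: float = 0.09
    doublet_rate_coefficient: float = 0.08  # per 10,000-cell unit in the nExp formula
    n_pcs: int = 20
    nexp_rule: str = "quadratic"  # canonical formula; "linear" = coefficient * n
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if not 0 < self.min_genes < self.max_genes:
            raise ValueError("need 0 < min_genes < max_genes")
        for name in ("max_mito_fraction", "pN", "pK"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.nexp_rule not in ("quadratic", "linear"):
            raise ValueError("nexp_rule must be 'quadratic' or 'linear'")


@dataclass
class QCReport:
    per_cell: pd.DataFrame  # indexed by barcode
    cells_in: int
    cells_out: int
    n_expected: int | None = None


def mito_mask(gene_names: np.ndarray, prefix: str = "MT-") -> np.ndarray:
    names = pd.Series(gene_names, dtype=object).str.upper()
    return names.str.startswith(prefix.upper()).to_numpy()


def expected_doublets(n_cells: int, params: QCParams | None = None) -> int:
    """Expected doublet count per sample (quadratic rule by default)."""
    params = params or QCParams()
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    if params.nexp_rule == "linear":
        return int(round(params.doublet_rate_coefficient * n_cells))
    return int(round(params.doublet_rate_coefficient * n_cells**2 / 10_000))


def filter_cells(counts: CountMatrix, params: QCParams | None = None) -> tuple[CountMatrix, QCReport]:
    """Apply the detected-gene and mitochondrial-fraction filters.

    Retention bounds are inclusive: a cell with exactly ``min_genes``
    detected genes or exactly the mitochondrial cutoff is kept. If no
    mitochondrial genes are present the mito filter is skipped with a
    warning.
    """
    params = params or QCParams()
    n_det = detected_genes_per_cell(counts.matrix)
    lib = library_sizes(counts.matrix)
    mito = mito_mask(counts.gene_names, params.mito_prefix)
    if mito.any():
        mito_counts = np.asarray(counts.matrix[mito].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.divide(mito_counts, lib, out=np.zeros_like(lib, float), where=lib > 0)
        high_mito = mito_frac > params.max_mito_fraction
    else:
        warnings.warn("no mitochondrial genes found; mito filter skipped", stacklevel=2)
        mito_frac = np.zeros(counts.n_cells)
        high_mito = np.zeros(counts.n_cells, dtype=bool)
    low = n_det < params.min_genes
    high = n_det > params.max_genes
    keep = ~(low | high | high_mito)
    per_cell = pd.DataFrame(
        {
            "n_genes_detected": n_det,
            "mito_fraction": mito_frac,
            "low_genes": low,
            "high_genes": high,
            "high_mito": high_mito,
            "qc_pass": keep,
        },
        index=pd.Index(counts.barcodes, name="barcode"),
    )
    report = QCReport(per_cell=per_cell, cells_in=counts.n_cells, cells_out=int(keep.sum()))
    return counts.subset_cells(keep), report


def flag_doublets(
    counts: CountMatrix,
    params: QCParams | None = None,
    seed: int = 0,
    n_expected: int | None = None,
) -> pd.DataFrame:
    """pANN doublet scores and flags for a single sample.

    Returns a per-cell DataFrame (indexed by barcode) with columns ``pann``
    and ``doublet``. Exactly ``n_expected`` cells are flagged (default from
    :func:`expected_doublets`), ties broken by barcode lexicographic order.
    Samples with fewer than 50 cells are skipped with a warning.
    """
    params = params or QCParams()
    n = counts.n_cells
    out = pd.DataFrame(
        {"pann": np.zeros(n), "doublet": np.zeros(n, dtype=bool)},
        index=pd.Index(counts.barcodes, name="barcode"),
    )
    if n < 50:
        warnings.warn(f"sample has {n} cells (< 50); doublet flagging skipped", stacklevel=2)
        return out
    if n_expected is None:
        n_expected = expected_doublets(n, params)
    n_expected = min(int(n_expected), n)

    rng = np.random.default_rng([int(seed), 11])
    n_art = int(round(params.pN / (1.0 - params.pN) * n))
    pairs_a = rng.integers(0, n, n_art)
    pairs_b = rng.integers(0, n, n_art)
    dense = np.asarray(counts.matrix.todense(), dtype=float)
    art = 0.5 * (dense[:, pairs_a] + dense[:, pairs_b])
    combined = sp.csr_matrix(np.concatenate([dense, art], axis=1))
    emb_input = lognorm(combined).T.toarray()

    n_total = n + n_art
    n_pcs = min(params.n_pcs, emb_input.shape[1], n_total - 1)
    pca = PCA(n_components=n_pcs, svd_solver="randomized", random_state=int(seed) % (2**31))
    emb = pca.fit_transform(emb_input)

    k = max(int(round(params.pK * n_total)), 1)
    nn = NearestNeighbors(n_neighbors=min(k + 1, n_total)).fit(emb)
    _, idx = nn.kneighbors(emb[:n])
    neigh = idx[:, 1:]  # drop self
    pann = (neigh >= n).mean(axis=1)
    out["pann"] = pann
    if n_expected > 0:
        order = sorted(range(n), key=lambda i: (-pann[i], str(counts.barcodes[i])))
        out.iloc[order[:n_expected], out.columns.get_loc("doublet")] = True
    return out
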