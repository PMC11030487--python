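"""Expression-based CNV profiles relative to a healthy reference.

Per gene the relative value is the cell's log-normalised expression minus
the mean over reference cells, clipped to [-3, 3]; a centred moving average
over 100 consecutive genes within each chromosome smooths the profile
(truncated at chromosome ends), and each cell is re-centred by subtracting
its median smoothed value. The per-cell CNV score is the mean of squared
smoothed values across the genome.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.metrics import roc_auc_score


@dataclass
class CNVMatrix:
    values: np.ndarray  # cells x genes (smoothed, re-centred)
    gene_order: np.ndarray
    chromosomes: np.ndarray
    window: int
    reference_means: np.ndarray
    barcodes: np.ndarray | None = None


def _chrom_sort_key(chrom: str) -> tuple:
    m = re.fullmatch(r"(?:chr)?(\d+)", str(chrom), flags=re.IGNORECASE)
    return (0, int(m.group(1)), "") if m else (1, 0, str(chrom))


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average along axis 1, truncated at both ends."""
    n = values.shape[1]
    half_left = (window - 1) // 2
    csum = np.cumsum(values, axis=1)
    csum = np.concatenate([np.zeros((values.shape[0], 1)), csum], axis=1)
    out = np.empty_like(values)
    for i in range(n):
        lo = max(0, i - half_left)
        hi = min(n, lo + window)
        lo = max(0, hi - window)
        out[:, i] = (csum[:, hi] - csum[:, lo]) / (hi - lo)
    return out


def infer_cnv(
    norm_expr: sp.spmatrix | np.ndarray,
    gene_positions: pd.DataFrame,
    reference_mask: np.ndarray,
    window: int = 100,
    clip: float = 3.0,
    barcodes: np.ndarray | None = None,
) -> CNVMatrix:
    """Windowed reference-relative CNV values.

    ``norm_expr`` is genes x cells (the CNV convention ln(1 + CPM/10) is a
    good input; any log-scale normalisation works); ``gene_positions`` is
    indexed by gene name with ``chromosome`` and ``start`` columns aligned
    with the rows. Chromosomes with fewer than ``window`` genes are
    excluded with a warning.
    """
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if reference_mask.sum() == 0:
        raise ValueError("reference_mask selects no cells")
    chroms = gene_positions["chromosome"].to_numpy()
    starts = gene_positions["start"].to_numpy()
    names = gene_positions.index.to_numpy(dtype=object)

    keep_chroms = []
    for c in sorted(set(chroms), key=_chrom_sort_key):
        if (chroms == c).sum() >= window:
            keep_chroms.append(c)
        else:
            warnings.warn(f"chromosome {c}: fewer than {window} genes; excluded")
    if not keep_chroms:
        raise ValueError("no chromosome has enough genes for the smoothing window")

    order = []
    for c in keep_chroms:
        idx = np.flatnonzero(chroms == c)
        order.append(idx[np.argsort(starts[idx], kind="stable")])
    order = np.concatenate(order)

    x = sp.csr_matrix(norm_expr)[order].toarray().T  # cells x genes
    ref_means = x[reference_mask].mean(axis=0)
    rel = np.clip(x - ref_means[None, :], -clip, clip)

    smoothed = np.empty_like(rel)
    offset = 0
    for c in keep_chroms:
        n_c = int((chroms == c).sum())
        smoothed[:, offset : offset + n_c] = _moving_average(rel[:, offset : offset + n_c], window)
        offset += n_c
    smoothed -= np.median(smoothed, axis=1, keepdims=True)
    return CNVMatrix(
        values=smoothed,
        gene_order=names[order],
        chromosomes=chroms[order],
        window=window,
        reference_means=ref_means,
        barcodes=barcodes,
    )


def cnv_score(cnv: CNVMatrix) -> pd.DataFrame:
    """Per-cell mean of squared CNV values across the genome."""
    scores = (cnv.values**2).mean(axis=1)
    idx = (
        pd.Index(cnv.barcodes, name="barcode")
        if cnv.barcodes is not None
        else pd.RangeIndex(len(scores))
    )
    return pd.DataFrame(
        {"cnv_score": scores, "n_genes_used": cnv.values.shape[1]}, index=idx
    )


def score_separation(scores: pd.DataFrame | np.ndarray, truth_labels: np.ndarray) -> float:
    """Rank-based AUROC of the CNV score separating aneuploid from diploid cells."""
    s = scores["cnv_score"].to_numpy() if isinstance(scores, pd.DataFrame) else np.asarray(scores)
    y = np.asarray(truth_labels).astype(bool)
    if y.all() or not y.any():
        return float("nan")
    return float(roc_auc_score(y, s))
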