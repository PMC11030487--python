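"""Sample-level malignancy index.

Per diseased sample, stem-like cells are contrasted with the pooled healthy
stem cells (two-sided Wilcoxon rank-sum per gene, BH FDR within sample,
log2FC on de-logged normalised means with pseudocount 1). Genes significant
in at least two samples (FDR <= 0.05 and |log2FC| >= 0.5) span a
sample x gene log2FC matrix; PCA of that matrix plus a zero "healthy
anchor" row defines a 2-D plane in which a principal curve is fitted, and
each sample's malignancy index is its normalised arc-length position along
the curve (healthy anchor at 0, most malignant at 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from statsmodels.nonparametric.smoothers_lowess import lowess

from ._stats import bh_fdr, log2fc, rank_sum_rows, spearman_rows

HEALTHY_ANCHOR = "__healthy__"


@dataclass
class MalignancyAxis:
    axis_genes: np.ndarray
    fc_matrix: pd.DataFrame  # samples (+ anchor row) x genes
    pc_scores: np.ndarray
    pc_loadings: np.ndarray
    curve: np.ndarray  # ordered control points in PC space
    position: pd.Series  # per sample in [0, 1]; anchor included
    fallback_pc1: bool = False

    def positions_for(self, sample_ids: np.ndarray, stages: np.ndarray) -> pd.Series:
        """Positions for arbitrary samples; healthy samples sit at the anchor (0)."""
        out = {}
        for sid, stage in zip(sample_ids, stages):
            if sid in self.position.index:
                out[sid] = float(self.position[sid])
            elif stage == "healthy":
                out[sid] = 0.0
        return pd.Series(out, name="position")


def sample_degs(
    norm_expr: sp.spmatrix,
    gene_names: np.ndarray,
    cell_meta: pd.DataFrame,
    stem_label: str = "STM",
    min_cells: int = 3,
) -> pd.DataFrame:
    """Per-sample stem-cell DEGs against pooled healthy stem cells.

    ``norm_expr`` is genes x cells log-normalised expression aligned with
    ``cell_meta`` rows. Returns a tidy table with one row per
    (sample, gene): log2fc, p_value, fdr and group sizes. Samples with too
    few stem cells are skipped with a warning.
    """
    meta = cell_meta.reset_index(drop=True)
    stem = (meta["cell_type"] == stem_label).to_numpy()
    healthy_pool = np.flatnonzero(stem & (meta["stage"] == "healthy").to_numpy())
    if healthy_pool.size < min_cells:
        raise ValueError(
            f"only {healthy_pool.size} pooled healthy stem cells (< {min_cells})"
        )
    x = sp.csr_matrix(norm_expr)
    healthy_dense = x[:, healthy_pool].toarray()
    mean_h = np.expm1(healthy_dense).mean(axis=1)
    frames = []
    diseased = meta.loc[meta["stage"] != "healthy", "sample_id"].unique()
    for sid in diseased:
        cols = np.flatnonzero(stem & (meta["sample_id"] == sid).to_numpy())
        if cols.size < min_cells:
            warnings.warn(f"sample {sid}: {cols.size} stem cells (< {min_cells}); skipped")
            continue
        dense = x[:, cols].toarray()
        p = rank_sum_rows(dense, healthy_dense)
        mean_d = np.expm1(dense).mean(axis=1)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": sid,
                    "gene": gene_names,
                    "log2fc": log2fc(mean_d, mean_h),
                    "p_value": p,
                    "fdr": bh_fdr(p),
                    "n_disease_cells": cols.size,
                    "n_healthy_cells": healthy_pool.size,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["sample_id", "gene", "log2fc", "p_value", "fdr", "n_disease_cells", "n_healthy_cells"]
        )
    return pd.concat(frames, ignore_index=True)


def select_axis_genes(
    degs: pd.DataFrame,
    fdr_cutoff: float = 0.05,
    lfc_cutoff: float = 0.5,
    min_samples: int = 2,
) -> np.ndarray:
    """Genes with FDR <= 0.05 and |log2FC| >= 0.5 in >= 2 distinct samples."""
    sig = degs[(degs["fdr"] <= fdr_cutoff) & (degs["log2fc"].abs() >= lfc_cutoff)]
    counts = sig.groupby("gene")["sample_id"].nunique()
    genes = counts[counts >= min_samples].index.to_numpy(dtype=object)
    if genes.size == 0:
        raise ValueError(
            "no gene is significant in >= 2 samples; increase effect sizes or sample count"
        )
    return np.sort(genes)


def _project_to_polyline(points: np.ndarray, line: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Arc-length position and squared distance of each point's projection."""
    seg = np.diff(line, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    pos = np.zeros(points.shape[0])
    d2 = np.full(points.shape[0], np.inf)
    for j in range(seg.shape[0]):
        a, v = line[j], seg[j]
        vv = seg_len[j] ** 2
        if vv == 0:
            t = np.zeros(points.shape[0])
        else:
            t = np.clip(((points - a) @ v) / vv, 0.0, 1.0)
        proj = a + t[:, None] * v
        dist2 = ((points - proj) ** 2).sum(axis=1)
        better = dist2 < d2
        d2[better] = dist2[better]
        pos[better] = cum[j] + t[better] * seg_len[j]
    return pos, d2


def principal_curve(
    points: np.ndarray, max_iter: int = 50, tol: float = 1e-6, frac: float = 0.6
) -> tuple[np.ndarray, np.ndarray]:
    """Principal curve by iterated projection and lowess smoothing.

    Returns (arc-length positions per point, curve control points). The
    curve is initialised on the first coordinate.
    """
    points = np.asarray(points, dtype=float)
    t = points[:, 0].copy()
    prev_sse = np.inf
    line = points[np.argsort(t, kind="stable")]
    for _ in range(max_iter):
        order = np.argsort(t, kind="stable")
        ts = t[order]
        smoothed = np.column_stack(
            [
                lowess(points[order, d], ts, frac=frac, it=0, return_sorted=False)
                for d in range(points.shape[1])
            ]
        )
        line = smoothed
        pos, d2 = _project_to_polyline(points, line)
        sse = float(d2.sum())
        t = pos
        if abs(prev_sse - sse) <= tol * max(sse, 1.0):
            break
        prev_sse = sse
    return t, line


def build_axis(
    degs: pd.DataFrame,
    axis_genes: np.ndarray,
    min_samples: int = 4,
) -> MalignancyAxis:
    """PCA + principal-curve ordering of the sample x gene log2FC matrix."""
    fc = degs.pivot_table(index="sample_id", columns="gene", values="log2fc", fill_value=0.0)
    fc = fc.reindex(columns=axis_genes, fill_value=0.0)
    if fc.shape[0] < min_samples:
        raise ValueError(f"need >= {min_samples} samples, got {fc.shape[0]}")
    fc.loc[HEALTHY_ANCHOR] = 0.0
    n_comp = min(2, fc.shape[0] - 1, fc.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(fc.to_numpy())
    sv = pca.singular_values_
    fallback = n_comp < 2 or sv[1] <= 1e-10 * max(sv[0], 1e-300)
    anchor_i = fc.index.get_loc(HEALTHY_ANCHOR)
    if fallback:
        s = scores[:, 0]
        curve = np.column_stack([np.sort(s), np.zeros(fc.shape[0])])
    else:
        s, curve = principal_curve(scores[:, :2])
    # orient so the healthy anchor sits at the near end, then normalise
    span = s.max() - s.min()
    if span == 0:
        pos = np.zeros_like(s)
    else:
        if s[anchor_i] - s.min() > s.max() - s[anchor_i]:
            s = s.max() - s  # flip direction
            curve = curve[::-1]
        denom = s.max() - s[anchor_i]
        if denom <= 0:
            pos = np.zeros_like(s)
        else:
            pos = np.clip((s - s[anchor_i]) / denom, 0.0, 1.0)
    position = pd.Series(pos, index=fc.index, name="position")
    return MalignancyAxis(
        axis_genes=np.asarray(axis_genes, dtype=object),
        fc_matrix=fc,
        pc_scores=scores,
        pc_loadings=pca.components_.T,
        curve=curve,
        position=position,
        fallback_pc1=bool(fallback),
    )


def expression_dynamics(
    axis: MalignancyAxis,
    degs: pd.DataFrame,
    gene: str,
    bandwidth: float = 0.5,
    n_grid: int = 100,
) -> pd.DataFrame:
    """Smoothed log2FC-vs-position curve for one gene.

    Local linear regression with tricube weights of the given bandwidth on
    a regular grid over [0, 1]. With a single sample the raw point is
    returned with a warning.
    """
    sub = degs[degs["gene"] == gene]
    if sub.empty:
        raise KeyError(f"gene {gene!r} absent from the DEG table")
    pos = axis.position.reindex(sub["sample_id"]).to_numpy()
    y = sub["log2fc"].to_numpy()
    ok = np.isfinite(pos)
    pos, y = pos[ok], y[ok]
    if pos.size == 1:
        warnings.warn("single sample; smoothing skipped")
        return pd.DataFrame({"position": pos, "smooth": y})
    grid = np.linspace(0.0, 1.0, n_grid)
    smooth = np.empty(n_grid)
    for i, g in enumerate(grid):
        u = np.abs(pos - g) / bandwidth
        w = np.clip(1.0 - u**3, 0.0, None) ** 3
        if w.sum() <= 0:
            smooth[i] = y[np.argmin(np.abs(pos - g))]
            continue
        xw = pos - g
        swx = np.sum(w * xw)
        swx2 = np.sum(w * xw**2)
        sw = np.sum(w)
        det = sw * swx2 - swx**2
        if det <= 1e-12 * max(sw, 1.0):
            smooth[i] = np.sum(w * y) / sw
        else:
            b = (sw * np.sum(w * xw * y) - swx * np.sum(w * y)) / det
            a = (np.sum(w * y) - b * swx) / sw
            smooth[i] = a
    return pd.DataFrame({"position": grid, "smooth": smooth})


def composition_trend(
    axis_positions: pd.Series,
    cell_meta: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell-type sample fractions and their Spearman trend vs position.

    Returns (fractions table: sample x cell type, trend table with rho and
    BH FDR per type; types with undefined correlation report NA).
    """
    meta = cell_meta[cell_meta["sample_id"].isin(axis_positions.index)]
    frac = (
        meta.groupby(["sample_id", "cell_type"]).size().unstack(fill_value=0).astype(float)
    )
    frac = frac.div(frac.sum(axis=1), axis=0)
    pos = axis_positions.reindex(frac.index).to_numpy()
    rho, p = spearman_rows(frac.to_numpy().T, pos)
    trend = pd.DataFrame({"cell_type": frac.columns, "rho": rho, "p_value": p})
    trend["fdr"] = bh_fdr(trend["p_value"].to_numpy())
    return frac, trend
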