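"""Malignant-transition (PCT) gene signatures.

Four candidate gene sets are derived per tissue — pseudo-bulk DEGs of
diseased vs healthy stem cells (sample-level Wilcoxon, FDR < 0.05,
log2FC > 0.25), stem-subcluster DEGs (avg_log2FC >= 0.25, pct.1 >= 0.25,
pct.ratio >= 1.5), pseudotime transition genes (Spearman FDR < 0.05) and
meta-program genes (Spearman vs AUCell activity, FDR < 0.05) — then
intersected within tissue and unioned across tissues. Each candidate gene
is scored by the geometric mean of its (non-negative) pseudotime Spearman
coefficients over the tissues that contribute it, and the 100 top-ranked
genes form the signature for that meta-program.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._stats import bh_fdr, log2fc, rank_sum_rows, spearman_rows


@dataclass
class CandidateSets:
    pseudo_bulk: set[str]
    subcluster: set[str]
    transition: pd.DataFrame  # gene, rho, fdr (kept genes only)
    mp: pd.DataFrame  # gene, rho, fdr (kept genes only)

    def intersection(self) -> set[str]:
        return (
            self.pseudo_bulk
            & self.subcluster
            & set(self.transition["gene"])
            & set(self.mp["gene"])
        )


@dataclass
class PCTSignature:
    mp_id: str
    genes: np.ndarray  # ordered, length <= 100
    gmean_score: np.ndarray
    per_tissue_rho: pd.DataFrame  # tissue x gene


def pseudo_bulk_degs(
    norm_expr: sp.spmatrix,
    gene_names: np.ndarray,
    cell_meta: pd.DataFrame,
    stem_label: str = "STM",
    fdr_cutoff: float = 0.05,
    lfc_cutoff: float = 0.25,
    min_samples: int = 3,
) -> tuple[set[str], pd.DataFrame]:
    """Sample-level pseudo-bulk DEGs of diseased vs healthy stem cells.

    Pseudo-bulk = mean de-logged normalised expression over each sample's
    stem cells; groups are compared gene-wise with the Wilcoxon rank-sum
    test across samples. Keeps FDR < 0.05 AND log2FC > 0.25 (strict).
    """
    meta = cell_meta.reset_index(drop=True)
    stem = meta["cell_type"] == stem_label
    x = sp.csr_matrix(norm_expr)
    profiles, stages = [], []
    for sid, rows in meta[stem].groupby("sample_id"):
        cols = rows.index.to_numpy()
        profiles.append(np.expm1(x[:, cols].toarray()).mean(axis=1))
        stages.append("healthy" if (rows["stage"] == "healthy").all() else "diseased")
    profiles = np.column_stack(profiles) if profiles else np.zeros((len(gene_names), 0))
    stages = np.asarray(stages)
    n_d, n_h = int((stages == "diseased").sum()), int((stages == "healthy").sum())
    if n_d < min_samples or n_h < min_samples:
        raise ValueError(f"need >= {min_samples} samples per side, got {n_d} diseased / {n_h} healthy")
    d, h = profiles[:, stages == "diseased"], profiles[:, stages == "healthy"]
    p = rank_sum_rows(d, h)
    lfc = log2fc(d.mean(axis=1), h.mean(axis=1))
    table = pd.DataFrame(
        {"gene": gene_names, "log2fc": lfc, "p_value": p, "fdr": bh_fdr(p)}
    )
    keep = table[(table["fdr"] < fdr_cutoff) & (table["log2fc"] > lfc_cutoff)]
    return set(keep["gene"]), table


def subcluster_degs(
    norm_expr: sp.spmatrix,
    gene_names: np.ndarray,
    cluster_labels: np.ndarray,
    pairs: list[tuple],
    lfc_cutoff: float = 0.25,
    pct1_cutoff: float = 0.25,
    ratio_cutoff: float = 1.5,
) -> tuple[set[str], pd.DataFrame]:
    """DEGs between pairs of stem-cell subclusters.

    Per (cluster1, cluster2) pair and gene: avg_log2FC on de-logged means
    (pseudocount 1), pct.1 / pct.2 = expressing fractions (count >= 1 on
    the normalised scale means value > 0), pct.ratio = pct.1 / max(pct.2,
    1/n2). A gene is kept when it passes all three thresholds in >= 1 pair.
    """
    labels = np.asarray(cluster_labels)
    known = set(labels)
    x = sp.csr_matrix(norm_expr)
    frames = []
    for c1, c2 in pairs:
        if c1 not in known or c2 not in known:
            raise ValueError(f"unknown cluster in pair ({c1!r}, {c2!r})")
        a = x[:, np.flatnonzero(labels == c1)].toarray()
        b = x[:, np.flatnonzero(labels == c2)].toarray()
        lfc = log2fc(np.expm1(a).mean(axis=1), np.expm1(b).mean(axis=1))
        pct1 = (a > 0).mean(axis=1)
        pct2 = (b > 0).mean(axis=1)
        ratio = pct1 / np.maximum(pct2, 1.0 / b.shape[1])
        frames.append(
            pd.DataFrame(
                {
                    "pair": f"{c1}|{c2}",
                    "gene": gene_names,
                    "avg_log2fc": lfc,
                    "pct_1": pct1,
                    "pct_2": pct2,
                    "pct_ratio": ratio,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    keep = table[
        (table["avg_log2fc"] >= lfc_cutoff)
        & (table["pct_1"] >= pct1_cutoff)
        & (table["pct_ratio"] >= ratio_cutoff)
    ]
    return set(keep["gene"]), table


def transition_genes(
    norm_expr: sp.spmatrix,
    gene_names: np.ndarray,
    pseudotime: np.ndarray,
    fdr_cutoff: float = 0.05,
    min_cells: int = 30,
) -> pd.DataFrame:
    """Genes whose expression tracks pseudotime across stem-like cells.

    Spearman rho per gene vs pseudotime, BH FDR < 0.05. Returns the kept
    genes with their rho and FDR; constant genes are excluded.
    """
    pt = np.asarray(pseudotime, dtype=float)
    if np.nanmax(pt) == np.nanmin(pt):
        raise ValueError("pseudotime is constant")
    if pt.size < min_cells:
        raise ValueError(f"need >= {min_cells} cells, got {pt.size}")
    x = np.asarray(sp.csr_matrix(norm_expr).todense(), dtype=float)
    rho, p = spearman_rows(x, pt)
    fdr = bh_fdr(p)
    keep = np.isfinite(rho) & (fdr < fdr_cutoff)
    return pd.DataFrame(
        {"gene": np.asarray(gene_names, dtype=object)[keep], "rho": rho[keep], "fdr": fdr[keep]}
    ).reset_index(drop=True)


def mp_genes(
    norm_expr: sp.spmatrix,
    gene_names: np.ndarray,
    activity: np.ndarray,
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Genes significantly correlated with a meta-program's AUCell activity."""
    act = np.asarray(activity, dtype=float)
    if np.nanmax(act) == np.nanmin(act):
        raise ValueError("activity is constant")
    x = np.asarray(sp.csr_matrix(norm_expr).todense(), dtype=float)
    rho, p = spearman_rows(x, act)
    fdr = bh_fdr(p)
    keep = np.isfinite(rho) & (fdr < fdr_cutoff)
    return pd.DataFrame(
        {"gene": np.asarray(gene_names, dtype=object)[keep], "rho": rho[keep], "fdr": fdr[keep]}
    ).reset_index(drop=True)


def derive_pct(
    candidates: Mapping[str, CandidateSets],
    mp_id: str,
    top_n: int = 100,
    use_mp_rho: bool = False,
) -> PCTSignature:
    """Cross-tissue PCT signature for one meta-program.

    Candidate genes are the union over tissues of the per-tissue four-way
    intersections. Each gene is scored by the geometric mean over
    contributing tissues of max(rho, 0), where rho is the pseudotime
    Spearman coefficient (optionally pooled with the meta-program rho);
    genes with no positive rho anywhere are dropped. The result is the
    ``top_n`` highest-scoring genes, ties at the cutoff broken by name.
    """
    per_tissue: dict[str, dict[str, float]] = {}
    for tissue, cand in candidates.items():
        inter = cand.intersection()
        if not inter:
            continue
        rho_t = dict(zip(cand.transition["gene"], cand.transition["rho"]))
        rho_m = dict(zip(cand.mp["gene"], cand.mp["rho"]))
        scores = {}
        for g in inter:
            vals = [max(rho_t.get(g, 0.0), 0.0)]
            if use_mp_rho:
                vals.append(max(rho_m.get(g, 0.0), 0.0))
            if min(vals) <= 0.0:
                scores[g] = 0.0
            else:
                scores[g] = float(np.exp(np.mean(np.log(vals))))
        per_tissue[tissue] = scores
    if not per_tissue:
        warnings.warn(f"{mp_id}: empty four-way intersection in every tissue")
        return PCTSignature(
            mp_id=mp_id,
            genes=np.array([], dtype=object),
            gmean_score=np.array([]),
            per_tissue_rho=pd.DataFrame(),
        )
    all_genes = sorted({g for s in per_tissue.values() for g in s})
    gmeans = {}
    for g in all_genes:
        contrib = [s[g] for s in per_tissue.values() if g in s]
        pos = [v for v in contrib if v > 0]
        if not pos or len(pos) < len(contrib):
            # a zero (clipped non-positive rho) in any contributing tissue
            # zeroes the geometric mean
            gmeans[g] = 0.0
        else:
            gmeans[g] = float(np.exp(np.mean(np.log(pos))))
    kept = [g for g in all_genes if gmeans[g] > 0]
    kept.sort(key=lambda g: (-gmeans[g], g))
    kept = kept[:top_n]
    rho_table = pd.DataFrame(
        {t: {g: s.get(g, np.nan) for g in kept} for t, s in per_tissue.items()}
    ).T
    return PCTSignature(
        mp_id=mp_id,
        genes=np.asarray(kept, dtype=object),
        gmean_score=np.asarray([gmeans[g] for g in kept]),
        per_tissue_rho=rho_table,
    )
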