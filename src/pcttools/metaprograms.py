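"""Per-sample NMF expression programs, consensus meta-programs and AUCell.

NMF uses multiplicative updates on the Frobenius objective (non-negative
input: log-normalised expression, per-gene centred, negatives clipped to
zero), run over a range of ranks with the optimal rank chosen at the
largest second-difference elbow of the reconstruction error. Each factor
is summarised by its 50 top-loading genes. Programs from all samples are
clustered into consensus meta-programs by K-means on the genes' binary
program-membership vectors (k chosen by silhouette), and per-cell activity
of a meta-program is the AUCell recovery-curve score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from ._stats import bh_fdr, hypergeom_overlap_p, spearman_rows


@dataclass
class NMFProgram:
    sample_id: str
    factor_index: int
    top_genes: np.ndarray  # ordered, length <= 50
    loadings: np.ndarray  # non-increasing, aligned with top_genes
    rank_used: int


@dataclass
class MetaProgramSet:
    modules: dict[str, list[str]]  # MP id -> gene list
    program_assignment: dict[tuple[str, int], str]  # (sample, factor) -> MP id
    overlap_pvalues: pd.DataFrame | None = None
    activity: pd.DataFrame | None = None  # MP x cell AUCell scores
    kmeans_k: int | None = None
    silhouette: float | None = None


def nmf_input(lognorm_expr: sp.spmatrix | np.ndarray) -> np.ndarray:
    """Per-gene centred log-normalised expression with negatives clipped to 0."""
    x = np.asarray(sp.csr_matrix(lognorm_expr).todense(), dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    return np.clip(x, 0.0, None)


def _nmf_mu(
    v: np.ndarray,
    rank: int,
    rng: np.random.Generator,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Multiplicative-update NMF; returns (W, H, error history).

    The Frobenius objective is recorded every 10 iterations; multiplicative
    updates guarantee it is non-increasing (checked by the test suite).
    """
    eps = 1e-10
    m, n = v.shape
    scale = np.sqrt(max(v.mean(), eps) / rank)
    w = rng.uniform(eps, scale, (m, rank))
    h = rng.uniform(eps, scale, (rank, n))
    norm_v = np.linalg.norm(v)
    history: list[float] = []
    prev = None
    for it in range(max_iter):
        h *= (w.T @ v) / (w.T @ w @ h + eps)
        w *= (v @ h.T) / (w @ (h @ h.T) + eps)
        if (it + 1) % 10 == 0 or it == max_iter - 1:
            err = np.linalg.norm(v - w @ h) / max(norm_v, eps)
            history.append(err)
            if prev is not None and abs(prev - err) < tol:
                break
            prev = err
    return w, h, history


def nmf_programs(
    expr: np.ndarray,
    gene_names: np.ndarray,
    sample_id: str,
    ranks: range | tuple[int, ...] = range(4, 10),
    seed: int = 0,
    n_top_genes: int = 50,
) -> list[NMFProgram]:
    """Extract NMF programs for one sample at the elbow-optimal rank.

    ``expr`` is a non-negative genes x cells matrix (see :func:`nmf_input`).
    Ranks >= min(n_genes, n_cells) are skipped with a warning; the optimal
    rank is the largest second-difference elbow of the reconstruction
    error (the smallest feasible rank when fewer than three ranks fit).
    """
    v = np.asarray(expr, dtype=float)
    if v.max() <= 0:
        raise ValueError("NMF input is all zero")
    gene_names = np.asarray(gene_names, dtype=object)
    feasible = [r for r in ranks if r < min(v.shape)]
    skipped = [r for r in ranks if r >= min(v.shape)]
    if skipped:
        warnings.warn(f"sample {sample_id}: ranks {skipped} >= matrix size; skipped")
    if not feasible:
        raise ValueError(f"sample {sample_id}: no feasible NMF rank")
    # an extra fit one rank below the range anchors the curvature estimate,
    # so an elbow at the smallest candidate rank is still visible
    anchor = feasible[0] - 1
    grid = ([anchor] if anchor >= 1 else []) + feasible
    fits = {}
    errors = {}
    for r in grid:
        rng = np.random.default_rng([int(seed), 23, r])
        w, h, hist = _nmf_mu(v, r, rng)
        fits[r] = (w, h)
        errors[r] = hist[-1]
    candidates = [r for r in feasible if r - 1 in errors and r + 1 in errors]
    if candidates:
        curvature = {r: errors[r - 1] - 2 * errors[r] + errors[r + 1] for r in candidates}
        best = max(candidates, key=lambda r: (curvature[r], -r))
    else:
        best = feasible[0]
    w, _ = fits[best]
    programs = []
    for j in range(best):
        order = np.argsort(-w[:, j], kind="stable")[:n_top_genes]
        programs.append(
            NMFProgram(
                sample_id=sample_id,
                factor_index=j,
                top_genes=gene_names[order],
                loadings=w[order, j],
                rank_used=best,
            )
        )
    return programs


def consensus_modules(
    programs: list[NMFProgram],
    k_range: range | tuple[int, ...] = range(2, 8),
    seed: int = 0,
    min_recurrence: int = 2,
    min_program_overlap: int = 10,
    blocklist: set[str] | None = None,
) -> MetaProgramSet:
    """Cluster recurrent program genes into consensus meta-programs.

    Programs are first filtered for robustness: a program is kept only if
    it shares at least ``min_program_overlap`` of its top genes with a
    program from a *different* sample (a random 50-gene factor from a
    ~1,500-gene pool shares ~2 genes by chance, a recurrent expression
    program shares most of them). Genes appearing in >= 2 robust programs
    are then embedded as binary membership vectors over those programs and
    clustered with K-means (k by maximal mean silhouette, 20 restarts).
    Each program is assigned to the module with which it shares the most
    genes. Modules dominated by block-listed genes (low-quality markers)
    are dropped.
    """
    if len(programs) < 2:
        raise ValueError("need at least 2 programs for consensus detection")
    sets = [set(map(str, p.top_genes)) for p in programs]
    robust = [
        i
        for i, p in enumerate(programs)
        if any(
            len(sets[i] & sets[j]) >= min_program_overlap
            for j in range(len(programs))
            if j != i and programs[j].sample_id != p.sample_id
        )
    ]
    if len(robust) >= 2:
        kept = [programs[i] for i in robust]
    else:
        warnings.warn("no robust recurring programs; clustering all programs")
        kept = programs
    membership: dict[str, set[int]] = {}
    for i, prog in enumerate(kept):
        for g in prog.top_genes:
            membership.setdefault(str(g), set()).add(i)
    genes = sorted(g for g, s in membership.items() if len(s) >= min_recurrence)
    programs = kept
    if len(genes) < 2:
        raise ValueError("fewer than 2 genes shared by >= 2 programs; provide more programs")
    mat = np.zeros((len(genes), len(programs)))
    for gi, g in enumerate(genes):
        for pi in membership[g]:
            mat[gi, pi] = 1.0

    best = None
    for k in k_range:
        if not 2 <= k <= len(genes) - 1:
            continue
        km = KMeans(n_clusters=k, n_init=20, random_state=int(seed) % (2**31))
        labels = km.fit_predict(mat)
        if len(set(labels)) < 2:
            continue
        sil = silhouette_score(mat, labels)
        if best is None or sil > best[0]:
            best = (sil, k, labels)
    if best is None:
        sil, k, labels = 0.0, 1, np.zeros(len(genes), dtype=int)
    else:
        sil, k, labels = best

    raw_modules = []
    for c in range(int(labels.max()) + 1):
        members = [genes[i] for i in np.flatnonzero(labels == c)]
        if members:
            raw_modules.append(sorted(members))
    raw_modules.sort(key=lambda m: (-len(m), m[0]))
    blocklist = blocklist or set()
    modules: dict[str, list[str]] = {}
    mp_i = 0
    for members in raw_modules:
        n_blocked = sum(g in blocklist for g in members)
        if blocklist and n_blocked > len(members) / 2:
            continue  # "unknown" module, dropped
        modules[f"MP{mp_i}"] = members
        mp_i += 1

    assignment: dict[tuple[str, int], str] = {}
    for prog in programs:
        pg = set(map(str, prog.top_genes))
        best_mp, best_shared = "unassigned", 0
        for mp_id, members in modules.items():
            shared = len(pg & set(members))
            if shared > best_shared:
                best_mp, best_shared = mp_id, shared
        assignment[(prog.sample_id, prog.factor_index)] = best_mp

    universe = len({str(g) for p in programs for g in p.top_genes})
    mp_ids = list(modules)
    pmat = np.ones((len(mp_ids), len(mp_ids)))
    for i, a in enumerate(mp_ids):
        for j, b in enumerate(mp_ids):
            pmat[i, j] = overlap_test(set(modules[a]), set(modules[b]), universe)
    overlap = pd.DataFrame(pmat, index=mp_ids, columns=mp_ids)
    return MetaProgramSet(
        modules=modules,
        program_assignment=assignment,
        overlap_pvalues=overlap,
        kmeans_k=k,
        silhouette=float(sil),
    )


def overlap_test(set_a: set, set_b: set, universe: int) -> float:
    """Upper-tail hypergeometric p-value of the overlap of two gene sets."""
    if not set_a or not set_b:
        warnings.warn("empty gene set in overlap test; p = 1 by convention")
        return 1.0
    return hypergeom_overlap_p(len(set_a & set_b), universe, len(set_a), len(set_b))


def aucell(
    expr: sp.spmatrix | np.ndarray,
    gene_names: np.ndarray,
    gene_set: set[str] | list[str],
    top_fraction: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """AUCell activity of a gene set per cell, in [0, 1].

    Genes are ranked per cell by descending expression (ties broken by a
    seeded random gene permutation); the score is the area under the
    gene-set recovery curve within the top ``top_fraction`` of ranks,
    normalised by the maximum possible area.
    """
    gene_names = np.asarray(gene_names, dtype=object)
    n_genes = gene_names.size
    threshold = int(np.ceil(top_fraction * n_genes))
    if threshold < 2:
        raise ValueError("top_fraction * n_genes must be >= 2")
    gene_set = {str(g) for g in gene_set}
    if not gene_set:
        raise ValueError("empty gene set")
    hits = np.isin(gene_names, list(gene_set))
    x = np.asarray(sp.csr_matrix(expr).todense(), dtype=float)
    n_cells = x.shape[1]
    if not hits.any():
        warnings.warn("gene set shares no genes with the matrix; scores are 0")
        return np.zeros(n_cells)
    m = int(hits.sum())
    rng = np.random.default_rng([int(seed), 31])
    tiebreak = rng.permutation(n_genes)
    max_area = np.sum(threshold - np.arange(min(m, threshold)))
    scores = np.empty(n_cells)
    for c in range(n_cells):
        order = np.lexsort((tiebreak, -x[:, c]))
        ranks = np.empty(n_genes, dtype=int)
        ranks[order] = np.arange(1, n_genes + 1)
        hit_ranks = ranks[hits]
        top = hit_ranks[hit_ranks <= threshold]
        scores[c] = np.sum(threshold - top + 1) / max_area
    return scores


def mp_correlations(
    activity: pd.DataFrame,
    covariate: pd.Series | np.ndarray,
    flag_cutoff: float = 0.7,
) -> pd.DataFrame:
    """Spearman correlation of each meta-program's activity with a covariate.

    Returns (MP, rho, p, BH FDR, flag) with flag = rho >= 0.7 (signed, as
    the strong-correlation rule). A constant covariate yields NA rows.
    """
    cov = np.asarray(covariate, dtype=float)
    rho, p = spearman_rows(activity.to_numpy(), cov)
    out = pd.DataFrame(
        {"mp": activity.index, "rho": rho, "p_value": p, "fdr": bh_fdr(p)}
    )
    out["flag"] = out["rho"] >= flag_cutoff
    out.loc[out["rho"].isna(), "flag"] = False
    return out
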