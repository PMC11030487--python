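"""Healthy-epithelium iterative-LSI reference and projection of diseased cells.

The reference is built with four iterations of (variable-gene selection ->
TF-IDF -> rank-32 truncated SVD -> SNN-graph Leiden clustering at
resolutions 0.1, 0.2, 0.4, 0.8). The final iteration's gene set, IDF
vector, gene loadings, singular values and cell embedding are frozen in an
:class:`LSIModel`, which supports projecting new cells with the *stored*
IDF (the query contributes only term frequencies) and 25-nearest-neighbour
label transfer in the 32-dimensional subspace.

TF(g, c) = x(g, c) / colsum(c) over the selected genes;
IDF(g) = ln(1 + n_cells / (1 + n_cells_expressing(g))) — a smoothed
document-frequency form that can never divide by zero.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.extmath import randomized_svd

from .io import CountMatrix
from .preprocess import scale_to_depth

EXCLUDED_GENE_PREFIXES = ("RPL", "RPS", "MRPL", "MRPS", "MT-", "HLA-")


@dataclass
class LSIParams:
    n_variable_genes: int = 3200
    n_components: int = 32
    resolutions: tuple[float, ...] = (0.1, 0.2, 0.4, 0.8)
    snn_k: int = 30
    seed: int = 0


@dataclass
class LSIModel:
    """Frozen reference: everything needed to project and classify new cells."""

    genes: np.ndarray  # ordered variable-gene names
    idf: np.ndarray
    loadings: np.ndarray  # genes x k, orthonormal columns
    singular_values: np.ndarray
    reference_embedding: np.ndarray  # cells x k
    reference_labels: np.ndarray
    reference_barcodes: np.ndarray
    row_nonzero: np.ndarray  # per model gene: reference TF-IDF rowSum > 0
    excluded_gene_patterns: tuple[str, ...] = EXCLUDED_GENE_PREFIXES
    iteration_log: list[dict] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {"gene": self.genes, "idf": self.idf, "row_nonzero": self.row_nonzero}
        ).to_csv(out / "genes.tsv", sep="\t", index=False)
        np.savetxt(out / "loadings.tsv", self.loadings, delimiter="\t")
        np.savetxt(out / "singular_values.tsv", self.singular_values, delimiter="\t")
        np.savetxt(out / "embedding.tsv", self.reference_embedding, delimiter="\t")
        pd.DataFrame(
            {"barcode": self.reference_barcodes, "label": self.reference_labels}
        ).to_csv(out / "labels.tsv", sep="\t", index=False)
        manifest = {
            "format_version": "1",
            "n_components": int(self.n_components),
            "excluded_gene_patterns": list(self.excluded_gene_patterns),
            "iteration_log": self.iteration_log,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, sort_keys=True, indent=1)
        return out

    @classmethod
    def load(cls, in_dir: str | Path) -> "LSIModel":
        d = Path(in_dir)
        gt = pd.read_csv(d / "genes.tsv", sep="\t")
        labels = pd.read_csv(d / "labels.tsv", sep="\t")
        with open(d / "manifest.json") as fh:
            manifest = json.load(fh)
        return cls(
            genes=gt["gene"].to_numpy(dtype=object),
            idf=gt["idf"].to_numpy(dtype=float),
            loadings=np.atleast_2d(np.loadtxt(d / "loadings.tsv", delimiter="\t")),
            singular_values=np.atleast_1d(np.loadtxt(d / "singular_values.tsv", delimiter="\t")),
            reference_embedding=np.atleast_2d(np.loadtxt(d / "embedding.tsv", delimiter="\t")),
            reference_labels=labels["label"].to_numpy(dtype=object),
            reference_barcodes=labels["barcode"].to_numpy(dtype=object),
            row_nonzero=gt["row_nonzero"].to_numpy(dtype=bool),
            excluded_gene_patterns=tuple(manifest["excluded_gene_patterns"]),
            iteration_log=manifest["iteration_log"],
        )


@dataclass
class ProjectionResult:
    barcodes: np.ndarray
    embedding: np.ndarray  # cells x k
    unassigned_flag: np.ndarray  # zero counts over model genes
    assigned_label: np.ndarray | None = None
    neighbor_votes: np.ndarray | None = None


def eligible_gene_mask(gene_names: np.ndarray) -> np.ndarray:
    """Genes not matching the ribosomal / mitochondrial / HLA exclusion list."""
    upper = pd.Series(gene_names, dtype=object).str.upper()
    mask = np.ones(len(upper), dtype=bool)
    for prefix in EXCLUDED_GENE_PREFIXES:
        mask &= ~upper.str.startswith(prefix).to_numpy()
    return mask


def tfidf(counts: sp.spmatrix) -> tuple[sp.csr_matrix, np.ndarray, np.ndarray]:
    """TF-IDF transform of a gene-subset count matrix.

    Returns (tfidf matrix, idf vector, all-zero-cell flags). All-zero cells
    keep an all-zero column and are flagged rather than raising.
    """
    x = sp.csr_matrix(counts, dtype=float)
    colsum = np.asarray(x.sum(axis=0)).ravel()
    zero_cells = colsum == 0
    inv = np.divide(1.0, colsum, out=np.zeros_like(colsum), where=colsum > 0)
    tf = (x @ sp.diags(inv)).tocsr()
    n_cells = x.shape[1]
    n_expr = np.asarray((x > 0).sum(axis=1)).ravel()
    idf = np.log(1.0 + n_cells / (1.0 + n_expr))
    out = (sp.diags(idf) @ tf).tocsr()
    return out, idf, zero_cells


def select_variable_genes(
    counts: CountMatrix,
    cluster_labels: np.ndarray | None = None,
    n: int = 3200,
) -> np.ndarray:
    """Top ``n`` most variable eligible genes.

    With no clusters: variance of ln(1 + CPM) across cells. With clusters:
    variance of ln(1 + CPM) of cluster-mean CPM pseudo-bulk profiles across
    clusters. Ties broken by gene-name order.
    """
    mask = eligible_gene_mask(counts.gene_names)
    cpm = scale_to_depth(counts.matrix, 1e6)
    if cluster_labels is None:
        log_cpm = cpm.copy()
        log_cpm.data = np.log1p(log_cpm.data)
        from .preprocess import gene_variance

        var = gene_variance(log_cpm)
    else:
        labels = np.asarray(cluster_labels)
        uniq = np.unique(labels)
        profiles = np.zeros((counts.n_genes, uniq.size))
        for j, lab in enumerate(uniq):
            cols = np.flatnonzero(labels == lab)
            profiles[:, j] = np.asarray(cpm[:, cols].mean(axis=1)).ravel()
        profiles = np.log1p(profiles)
        var = profiles.var(axis=1, ddof=1) if uniq.size > 1 else profiles.var(axis=1)
    names = counts.gene_names
    elig = np.flatnonzero(mask)
    if elig.size < n:
        warnings.warn(
            f"only {elig.size} eligible genes (< {n}); returning all", stacklevel=2
        )
    order = sorted(elig, key=lambda i: (-var[i], str(names[i])))
    return names[np.asarray(order[:n], dtype=int)]


def _truncated_svd(mat: sp.spmatrix, k: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Randomized rank-k SVD with a deterministic sign convention."""
    u, s, _ = randomized_svd(mat, n_components=k, random_state=int(seed) % (2**31))
    for j in range(k):
        i_star = int(np.argmax(np.abs(u[:, j])))
        if u[i_star, j] < 0:
            u[:, j] = -u[:, j]
    return u, s


def snn_leiden(embedding: np.ndarray, k: int, resolution: float, seed: int) -> np.ndarray:
    """Shared-nearest-neighbour graph + Leiden community detection."""
    n = embedding.shape[0]
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()
    adj = sp.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    adj = ((adj + adj.T) > 0).astype(float)
    shared = (adj @ adj.T).multiply(adj)  # shared-neighbour counts on kNN edges
    shared = sp.triu(shared, k=1).tocoo()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    union = deg[shared.row] + deg[shared.col] - shared.data
    weights = shared.data / np.maximum(union, 1.0)
    g = igraph.Graph(n=n, edges=list(zip(shared.row.tolist(), shared.col.tolist())))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights.tolist(),
        resolution_parameter=resolution,
        seed=int(seed) % (2**31),
        n_iterations=2,
    )
    return np.asarray(part.membership)


def build_reference(
    counts: CountMatrix,
    labels: np.ndarray | None = None,
    params: LSIParams | None = None,
) -> LSIModel:
    """Iterative-LSI reference from healthy, post-QC cells.

    ``labels`` are the reference cell-type annotations used later for kNN
    label transfer; if omitted, the final iteration's Leiden clusters are
    used as labels.
    """
    params = params or LSIParams()
    k = params.n_components
    if counts.n_cells <= k or counts.n_genes <= k:
        raise ValueError(
            f"need more than {k} cells and genes (got {counts.n_cells} x {counts.n_genes})"
        )
    clusters: np.ndarray | None = None
    log: list[dict] = []
    genes = idf = u = s = emb = None
    for it, res in enumerate(params.resolutions):
        genes = select_variable_genes(counts, clusters, params.n_variable_genes)
        sub = counts.subset_genes(genes)
        mat, idf, _ = tfidf(sub.matrix)
        u, s = _truncated_svd(mat, k, params.seed + it)
        emb = np.asarray((mat.T @ u))
        clusters = snn_leiden(emb, params.snn_k, res, params.seed + it)
        log.append({"iteration": it + 1, "resolution": res, "n_clusters": int(clusters.max()) + 1})
    sub = counts.subset_genes(genes)
    row_nonzero = np.asarray(sub.matrix.sum(axis=1)).ravel() > 0
    ref_labels = (
        np.asarray(labels, dtype=object)
        if labels is not None
        else np.array([f"cluster{c}" for c in clusters], dtype=object)
    )
    return LSIModel(
        genes=np.asarray(genes, dtype=object),
        idf=idf,
        loadings=u,
        singular_values=s,
        reference_embedding=emb,
        reference_labels=ref_labels,
        reference_barcodes=counts.barcodes,
        row_nonzero=row_nonzero,
        iteration_log=log,
    )


def project(model: LSIModel, counts: CountMatrix) -> ProjectionResult:
    """Project query cells through the frozen model.

    The query is restricted to the model genes (missing genes are zero
    rows), genes with zero reference row-sum are zeroed, term frequencies
    use the query column sums over model genes, and the stored IDF is
    applied; the embedding is TFIDF^T x loadings. Cells with no counts over
    the model genes get the zero vector and the unassigned flag.
    """
    pos = pd.Index(counts.gene_names).get_indexer(model.genes)
    if (pos >= 0).sum() == 0:
        raise ValueError("query shares no genes with the model")
    x = sp.lil_matrix((model.genes.size, counts.n_cells), dtype=float)
    present = pos >= 0
    x[np.flatnonzero(present)] = counts.matrix[pos[present]].astype(float)
    x = x.tocsr()
    x = sp.diags(model.row_nonzero.astype(float)) @ x
    colsum = np.asarray(x.sum(axis=0)).ravel()
    zero_cells = colsum == 0
    inv = np.divide(1.0, colsum, out=np.zeros_like(colsum), where=colsum > 0)
    tf = (x @ sp.diags(inv)).tocsr()
    mat = (sp.diags(model.idf) @ tf).tocsr()
    emb = np.asarray(mat.T @ model.loadings)
    emb[zero_cells] = 0.0
    return ProjectionResult(
        barcodes=counts.barcodes, embedding=emb, unassigned_flag=zero_cells
    )


def classify_knn(model: LSIModel, result: ProjectionResult, k: int = 25) -> ProjectionResult:
    """Majority-vote label transfer from the 25 nearest reference cells.

    Ties are broken by the smaller mean neighbour distance, then by label
    lexicographic order; cells flagged unassigned keep label "unassigned".
    """
    n_ref = model.reference_embedding.shape[0]
    if k > n_ref:
        raise ValueError(f"k={k} exceeds the {n_ref} reference cells")
    nn = NearestNeighbors(n_neighbors=k).fit(model.reference_embedding)
    dist, idx = nn.kneighbors(result.embedding)
    labels = model.reference_labels[idx]
    assigned = np.empty(result.embedding.shape[0], dtype=object)
    votes = np.zeros(result.embedding.shape[0], dtype=int)
    for i in range(labels.shape[0]):
        if result.unassigned_flag[i]:
            assigned[i] = "unassigned"
            continue
        row = labels[i]
        uniq, counts_ = np.unique(row, return_counts=True)
        best = counts_.max()
        tied = uniq[counts_ == best]
        if tied.size > 1:
            mean_d = {lab: dist[i][row == lab].mean() for lab in tied}
            tied = sorted(tied, key=lambda lab: (mean_d[lab], str(lab)))
        assigned[i] = tied[0]
        votes[i] = best
    result.assigned_label = assigned
    result.neighbor_votes = votes
    return result
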