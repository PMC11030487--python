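"""Reading and writing of 10x-style MTX bundles and per-cell metadata.

A bundle directory holds ``matrix.mtx`` (MatrixMarket coordinate, integer,
genes as rows and cells as columns), ``features.tsv`` (gene_id, gene_name,
chromosome, start), ``barcodes.tsv`` and optionally ``cell_meta.tsv`` and
``truth.json``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

FEATURE_COLUMNS = ["gene_id", "gene_name", "chromosome", "start"]


class FormatError(ValueError):
    """Raised when a bundle file violates the expected on-disk format."""


@dataclass
class CountMatrix:
    """Sparse gene-by-cell UMI count matrix with feature/barcode metadata.

    ``matrix`` is CSR, genes x cells, non-negative integers. ``genes`` is a
    DataFrame indexed by unique gene name with at least ``chromosome`` and
    ``start`` columns. ``barcodes`` is an array of unique cell barcodes.
    """

    matrix: sp.csr_matrix
    genes: pd.DataFrame
    barcodes: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.matrix.shape[0] != len(self.genes):
            raise FormatError(
                f"matrix has {self.matrix.shape[0]} rows but {len(self.genes)} features"
            )
        if self.matrix.shape[1] != len(self.barcodes):
            raise FormatError(
                f"matrix has {self.matrix.shape[1]} columns but {len(self.barcodes)} barcodes"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise FormatError("duplicate barcodes")
        if not self.genes.index.is_unique:
            raise FormatError("duplicate gene names")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    @property
    def gene_names(self) -> np.ndarray:
        return self.genes.index.to_numpy(dtype=object)

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(self.matrix[:, idx].tocsr(), self.genes, self.barcodes[idx])

    def subset_genes(self, names: np.ndarray) -> "CountMatrix":
        pos = self.genes.index.get_indexer(names)
        if (pos < 0).any():
            missing = np.asarray(names)[pos < 0][:3]
            raise KeyError(f"genes not present: {list(missing)}")
        return CountMatrix(self.matrix[pos].tocsr(), self.genes.iloc[pos], self.barcodes)


def write_mtx_bundle(
    out_dir: str | Path,
    counts: CountMatrix,
    cell_meta: pd.DataFrame | None = None,
    truth: dict | None = None,
) -> Path:
    """Write a bundle; returns the directory path.

    The matrix is written with the integer MatrixMarket field so that a
    byte-identical file is produced for identical inputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(counts.matrix)
    if not np.issubdtype(mat.dtype, np.integer):
        if not np.all(mat.data == np.round(mat.data)):
            raise FormatError("count matrix entries must be integers")
        mat = mat.astype(np.int64)
    scipy.io.mmwrite(str(out / "matrix.mtx"), mat, field="integer")
    feats = counts.genes.copy()
    feats.insert(0, "gene_name", feats.index.to_numpy())
    if "gene_id" not in feats.columns:
        feats.insert(0, "gene_id", feats["gene_name"])
    feats = feats[["gene_id", "gene_name"] + [c for c in ("chromosome", "start") if c in feats.columns]]
    feats.to_csv(out / "features.tsv", sep="\t", index=False)
    pd.Series(counts.barcodes, name="barcode").to_csv(out / "barcodes.tsv", sep="\t", index=False)
    if cell_meta is not None:
        cell_meta.to_csv(out / "cell_meta.tsv", sep="\t", index=False)
    if truth is not None:
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, sort_keys=True)
    return out


def read_mtx_bundle(in_dir: str | Path) -> tuple[CountMatrix, pd.DataFrame | None]:
    """Read a bundle; returns (CountMatrix, cell_meta or None).

    Gene positions travel on ``CountMatrix.genes`` (chromosome, start).
    """
    d = Path(in_dir)
    mtx_path = d / "matrix.mtx"
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise FormatError(f"{mtx_path}, line 1: not a readable MatrixMarket file ({exc})") from exc
    mat = sp.coo_matrix(mat)
    if not np.issubdtype(mat.dtype, np.integer):
        if not np.all(mat.data == np.round(mat.data)):
            raise FormatError(f"{mtx_path}: non-integer entries in count matrix")
        mat = mat.astype(np.int64)
    feats = pd.read_csv(d / "features.tsv", sep="\t")
    missing = [c for c in ("gene_id", "gene_name") if c not in feats.columns]
    if missing:
        raise FormatError(f"{d / 'features.tsv'}: missing columns {missing}")
    genes = feats.set_index("gene_name")
    barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t")["barcode"].to_numpy(dtype=object)
    if mat.shape[0] != len(genes):
        raise FormatError(
            f"{mtx_path}: {mat.shape[0]} rows but {len(genes)} features in features.tsv"
        )
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"{mtx_path}: {mat.shape[1]} columns but {len(barcodes)} barcodes in barcodes.tsv"
        )
    cm = CountMatrix(mat.tocsr(), genes, barcodes)
    meta_path = d / "cell_meta.tsv"
    meta = pd.read_csv(meta_path, sep="\t") if meta_path.exists() else None
    if meta is not None and meta["barcode"].duplicated().any():
        raise FormatError(f"{meta_path}: duplicate barcodes")
    return cm, meta


def read_truth(in_dir: str | Path) -> dict:
    with open(Path(in_dir) / "truth.json") as fh:
        return json.load(fh)
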