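"""Core data containers and on-disk formats.

The pipeline's raw input is a sparse nonnegative integer count matrix
(genes x nuclei) with gene and barcode identifiers, exchanged on disk in
the 10x convention: ``matrix.mtx`` (Matrix Market) plus ``genes.tsv`` and
``barcodes.tsv`` sidecars. Per-nucleus metadata travels as a TSV keyed by
barcode.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "cp10k_log1p",
    "read_10x_mtx",
    "write_10x_mtx",
]

#: required metadata columns for per-nucleus annotations
METADATA_COLUMNS = ("barcode", "patient_id", "arm", "dose_group", "modality", "sex")

ARMS = ("untreated", "CRT", "CRTL")
DOSE_GROUPS = ("none", "low", "high")
MODALITIES = ("none", "photon", "proton")


@dataclass
class CountMatrix:
    """Sparse nonnegative integer count matrix, genes x nuclei.

    Parameters
    ----------
    counts
        ``scipy.sparse`` matrix of shape (n_genes, n_nuclei); converted to CSR.
    gene_ids
        Gene symbols; uppercased and required to be unique afterwards.
    barcodes
        Nucleus barcodes, unique.
    """

    counts: sp.spmatrix
    gene_ids: np.ndarray
    barcodes: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray([str(g).upper() for g in self.gene_ids])
        self.barcodes = np.asarray([str(b) for b in self.barcodes])
        n_genes, n_nuclei = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.barcodes) != n_nuclei:
            raise ValueError(
                f"{len(self.barcodes)} barcodes for {n_nuclei} matrix columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene ids are not unique after uppercase normalization")
        if len(set(self.barcodes)) != n_nuclei:
            raise ValueError("barcodes are not unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("count matrix contains negative entries")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_nuclei(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, genes) -> np.ndarray:
        """Row indices of ``genes`` (uppercased); missing genes are dropped."""
        lut = {g: i for i, g in enumerate(self.gene_ids)}
        return np.asarray([lut[g.upper()] for g in genes if g.upper() in lut], dtype=int)

    def subset_nuclei(self, mask_or_idx) -> "CountMatrix":
        """Column subset; raw counts are carried over unchanged."""
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(self.counts[:, idx], self.gene_ids, self.barcodes[idx])

    def subset_genes(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(self.counts[idx, :], self.gene_ids[idx], self.barcodes)

    def total_umis(self) -> np.ndarray:
        """Total UMI count per nucleus (library size)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def to_anndata(self):
        """Interop: nuclei x genes AnnData view of the counts (optional dep)."""
        import anndata as ad

        return ad.AnnData(
            X=self.counts.T.tocsr(),
            obs=pd.DataFrame(index=self.barcodes),
            var=pd.DataFrame(index=self.gene_ids),
        )


def cp10k_log1p(X: CountMatrix) -> sp.csr_matrix:
    """log1p of counts-per-10k normalized expression (genes x nuclei, sparse).

    Nuclei with zero total counts are left at zero rather than dividing by 0.
    """
    totals = X.total_umis().astype(float)
    scale = np.divide(1e4, totals, out=np.zeros_like(totals), where=totals > 0)
    N = X.counts.astype(float) @ sp.diags(scale)
    N = N.tocsr()
    N.data = np.log1p(N.data)
    return N


def write_10x_mtx(out_dir: str, X: CountMatrix, metadata: pd.DataFrame | None = None) -> None:
    """Write ``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv`` (+ ``metadata.tsv``)."""
    os.makedirs(out_dir, exist_ok=True)
    scipy.io.mmwrite(os.path.join(out_dir, "matrix.mtx"), sp.coo_matrix(X.counts))
    pd.Series(X.gene_ids).to_csv(
        os.path.join(out_dir, "genes.tsv"), sep="\t", index=False, header=False
    )
    pd.Series(X.barcodes).to_csv(
        os.path.join(out_dir, "barcodes.tsv"), sep="\t", index=False, header=False
    )
    if metadata is not None:
        metadata.to_csv(os.path.join(out_dir, "metadata.tsv"), sep="\t", index=False)


def read_10x_mtx(in_dir: str) -> tuple[CountMatrix, pd.DataFrame | None]:
    """Read a directory written by :func:`write_10x_mtx`."""
    counts = scipy.io.mmread(os.path.join(in_dir, "matrix.mtx"))
    genes = pd.read_csv(os.path.join(in_dir, "genes.tsv"), sep="\t", header=None)[0].values
    barcodes = pd.read_csv(os.path.join(in_dir, "barcodes.tsv"), sep="\t", header=None)[0].values
    meta_path = os.path.join(in_dir, "metadata.tsv")
    metadata = pd.read_csv(meta_path, sep="\t") if os.path.exists(meta_path) else None
    return CountMatrix(counts, genes, barcodes), metadata
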