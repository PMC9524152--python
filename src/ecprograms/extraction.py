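"""Endothelial-cell identification from a typed or untyped count matrix.

Endothelial profiles are recognized by marker genes — general endothelial
(PECAM1, VWF), vascular (ESAM, FLT1, EPAS1) and lymphatic (FLT4, SEMA3A,
SEMA3D). The default extraction path consumes precomputed cell-type
labels; the fallback clusters nuclei (k-means on top principal components
of log-normalized expression) and annotates clusters whose mean
endothelial score exceeds every non-endothelial type score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import TruncatedSVD

from .containers import CountMatrix, cp10k_log1p

__all__ = [
    "MarkerPanel",
    "DEFAULT_EC_PANEL",
    "DECONVOLUTION_MARKERS",
    "score_markers",
    "extract_endothelial",
]

#: endothelial marker families
DEFAULT_EC_PANEL = {
    "endothelial": ("PECAM1", "VWF"),
    "vascular": ("ESAM", "FLT1", "EPAS1"),
    "lymphatic": ("FLT4", "SEMA3A", "SEMA3D"),
}

#: bulk deconvolution marker table. "CSM1" is stored verbatim from the
#: source marker list although it is not a standard HGNC symbol; a
#: validation warning is emitted when it is looked up.
DECONVOLUTION_MARKERS = {
    "endothelial": ("PECAM1", "VWF"),
    "epithelial": (
        "CFTR", "KRT19", "KRT7", "KRT17", "EPCAM", "CEACAM6", "COL17A1",
        "MECOM", "CPB1", "PRSS3", "AMY1A",
    ),
    "myeloid": (
        "CD68", "CD163", "MRC1", "CD80", "CD86", "TGFB1", "CSM1", "XCR1",
        "CST3", "CLEC9A", "LGALS2", "CD1A", "CD207", "CD1E", "FCER1A",
        "NDRG2", "FSCN1", "LAMP3", "CCL19", "CCR7", "IRF7", "LILRA4",
        "TCF4", "CXCR3", "IRF4", "CSF3R", "CXCL8",
    ),
    "lymphoid": (
        "CD4", "CD8A", "CD8B", "CD3D", "THEMIS", "CD96", "KZF1", "GZMA",
        "FOXP3", "BANK1", "CD19", "KLRD1", "KIR2DL3", "IL18R1", "KIR2DL1",
        "KIR3DL2", "SDC1", "IGLC2",
    ),
    "fibroblast": (
        "COL1A1", "FN1", "PDPN", "DCN", "VIM", "FAP", "ACTA2", "IL6", "C3",
        "LIF", "POSTN", "FBLN1",
    ),
    "pericyte": ("PDGFRB", "DLK1", "ACTA1", "RGS5", "CSPG4", "MCAM"),
    "schwann": ("SOX10", "S100B", "NGFR"),
    "endocrine": ("GCG", "INS", "APP", "SST", "PPY", "GHRL", "SYP", "CHGA", "VGF"),
    "neuron": ("TH", "CHAT", "ENO2", "TAC1"),
    "adipocyte": ("PLIN1", "LPL"),
}

NONSTANDARD_SYMBOLS = {"CSM1", "KZF1"}


@dataclass
class MarkerPanel:
    """Cell-type -> marker gene lists (uppercased, nonempty)."""

    panel: dict = field(default_factory=lambda: dict(DEFAULT_EC_PANEL))
    #: types counted as endothelial when annotating clusters
    ec_types: tuple = ("endothelial", "vascular", "lymphatic")

    def __post_init__(self) -> None:
        clean = {}
        for t, genes in self.panel.items():
            genes = tuple(str(g).upper() for g in genes)
            if not genes:
                raise ValueError(f"empty gene list for cell type {t!r}")
            odd = set(genes) & NONSTANDARD_SYMBOLS
            if odd:
                warnings.warn(
                    f"panel for {t!r} contains non-standard gene symbols: {sorted(odd)}"
                )
            clean[t] = genes
        self.panel = clean

    @classmethod
    def deconvolution_default(cls) -> "MarkerPanel":
        return cls(panel=dict(DECONVOLUTION_MARKERS), ec_types=("endothelial",))


def score_markers(X: CountMatrix, panel: MarkerPanel) -> pd.DataFrame:
    """Per-nucleus, per-type marker scores.

    Score = mean log1p(CP10K) expression over the panel genes present in
    the matrix. Missing genes are recorded in ``result.attrs['missing']``;
    a type with no present genes raises.
    """
    norm = cp10k_log1p(X)
    scores = {}
    missing = {}
    for t, genes in panel.panel.items():
        idx = X.gene_index(genes)
        missing[t] = sorted(set(genes) - set(X.gene_ids[idx]))
        if len(idx) == 0:
            raise ValueError(f"no panel genes present for cell type {t!r}")
        scores[t] = np.asarray(norm[idx, :].mean(axis=0)).ravel()
    out = pd.DataFrame(scores, index=X.barcodes)
    out.attrs["missing"] = missing
    return out


def _check_metadata(X: CountMatrix, metadata: pd.DataFrame) -> pd.DataFrame:
    if "barcode" in metadata.columns:
        meta = metadata.set_index("barcode")
    else:
        meta = metadata
    if not set(X.barcodes).issubset(meta.index):
        raise ValueError("metadata does not cover all matrix barcodes")
    return meta.loc[X.barcodes]


def extract_endothelial(
    X: CountMatrix,
    metadata: pd.DataFrame,
    panel: MarkerPanel | None = None,
    method: str = "precomputed_labels",
    n_clusters: int = 8,
    n_pcs: int = 15,
    min_genes: int = 0,
    random_state: int = 0,
):
    """Return the endothelial subset of (X, metadata).

    ``precomputed_labels`` keeps nuclei whose ``cell_type`` metadata equals
    "endothelial" (case-insensitive). ``cluster_then_annotate`` runs
    k-means on the top principal components of log-normalized expression
    and keeps clusters whose mean endothelial score (max over the panel's
    endothelial type families) exceeds every non-endothelial type score.
    Raw counts are never renormalized on subsetting. ``min_genes``
    optionally drops nuclei with fewer detected genes first.
    """
    panel = panel or MarkerPanel()
    meta = _check_metadata(X, metadata)

    if min_genes > 0:
        detected = np.asarray((X.counts > 0).sum(axis=0)).ravel()
        keep = detected >= min_genes
        X = X.subset_nuclei(keep)
        meta = meta.loc[X.barcodes]

    if method == "precomputed_labels":
        if "cell_type" not in meta.columns or meta["cell_type"].isna().all():
            raise ValueError("precomputed_labels requires populated cell_type metadata")
        mask = meta["cell_type"].astype(str).str.lower().eq("endothelial").values
    elif method == "cluster_then_annotate":
        norm = cp10k_log1p(X)
        n_comp = min(n_pcs, X.n_nuclei - 1, X.n_genes - 1)
        svd = TruncatedSVD(n_components=n_comp, random_state=random_state)
        pcs = svd.fit_transform(norm.T)
        km = KMeans(n_clusters=min(n_clusters, X.n_nuclei), n_init=10, random_state=random_state)
        labels = km.fit_predict(pcs)
        scores = score_markers(X, panel)
        cluster_means = scores.groupby(labels).mean()
        ec_cols = [t for t in panel.ec_types if t in cluster_means.columns]
        other_cols = [t for t in cluster_means.columns if t not in panel.ec_types]
        if not ec_cols:
            raise ValueError("panel contains no endothelial type families")
        ec_score = cluster_means[ec_cols].max(axis=1)
        if other_cols:
            is_ec_cluster = ec_score > cluster_means[other_cols].max(axis=1)
        else:
            # no competing types supplied: call clusters above the median score
            is_ec_cluster = ec_score > ec_score.median()
        mask = pd.Series(labels).map(is_ec_cluster).values
    else:
        raise ValueError(f"unknown extraction method {method!r}")

    if not mask.any():
        raise ValueError(
            "no endothelial nuclei found; review marker panel and score thresholds"
        )
    sub = X.subset_nuclei(mask)
    return sub, meta.loc[sub.barcodes].reset_index().rename(columns={"index": "barcode"})
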