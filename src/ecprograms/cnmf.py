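"""Consensus non-negative matrix factorization of endothelial expression.

A single NMF run depends on its random initialization, so programs are
discovered by repeating the factorization ``n_replicates`` times, pooling
all replicate spectra, filtering outlier components by local density,
clustering the survivors into ``k`` consensus programs (component-wise
median), and refitting per-nucleus usages by nonnegative least squares.
The mean silhouette of the component clustering ("stability") and the
refit Frobenius error drive the choice of ``k``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.decomposition import NMF
from sklearn.metrics import silhouette_samples
from sklearn.neighbors import NearestNeighbors

from .containers import CountMatrix, cp10k_log1p

__all__ = [
    "PreparedMatrix",
    "NMFReplicate",
    "ConsensusResult",
    "Program",
    "ProgramSet",
    "prepare_matrix",
    "run_replicates",
    "build_consensus",
    "ConsensusNMF",
    "select_k",
    "assign_nuclei",
]

TOP_GENES_DEFAULT = 200


@dataclass
class PreparedMatrix:
    """Normalized nonnegative matrix fed to the factorization.

    ``matrix`` is nuclei x genes: log1p(CP10K), restricted to the highest
    variance genes, scaled to unit variance per gene, negatives clipped at
    zero. ``gene_scale`` retains the per-gene standard deviations so that
    rate-space gene profiles (e.g. planted program spectra) can be mapped
    into the same feature space for comparison.
    """

    matrix: np.ndarray
    genes: np.ndarray
    gene_scale: np.ndarray
    barcodes: np.ndarray

    def map_rate_profiles(self, profiles: np.ndarray, gene_ids) -> np.ndarray:
        """Map rate-space profiles (rows sum to 1 over ``gene_ids``) into
        the prepared feature space: log1p of the pure-profile CP10K,
        restricted to the retained genes and scaled identically."""
        gene_ids = np.asarray([str(g).upper() for g in gene_ids])
        lut = {g: i for i, g in enumerate(gene_ids)}
        idx = np.asarray([lut[g] for g in self.genes])
        return np.log1p(1e4 * np.asarray(profiles)[:, idx]) / self.gene_scale


@dataclass
class NMFReplicate:
    """One factorization: spectra rows on the simplex, seed, fit error."""

    spectra: np.ndarray
    seed: int
    frobenius_error: float
    converged: bool = True


@dataclass
class ConsensusResult:
    k: int
    consensus_spectra: np.ndarray  # k x G, rows sum to 1
    usage: np.ndarray  # nuclei x k, rows sum to 1
    stability: float
    reconstruction_error: float
    n_replicates: int
    outlier_fraction_removed: float


def prepare_matrix(X: CountMatrix, n_hvg: int = 1500) -> PreparedMatrix:
    """CP10K + log1p, top-variance gene restriction, unit-variance scaling."""
    if X.n_genes == 0 or X.n_nuclei == 0:
        raise ValueError("empty count matrix")
    norm = cp10k_log1p(X).tocsr()
    dense = np.asarray(norm.todense(), dtype=np.float64).T  # nuclei x genes
    var = dense.var(axis=0)
    nonzero = np.flatnonzero(var > 0)
    if n_hvg > len(nonzero):
        raise ValueError(
            f"n_hvg={n_hvg} exceeds the {len(nonzero)} genes with nonzero variance"
        )
    order = nonzero[np.argsort(var[nonzero], kind="mergesort")[::-1][:n_hvg]]
    order = np.sort(order)  # keep original gene order
    sub = dense[:, order]
    scale = sub.std(axis=0)
    sub = np.clip(sub / scale, 0.0, None).astype(np.float32)
    return PreparedMatrix(sub, X.gene_ids[order], scale, X.barcodes)


def _random_init(M: np.ndarray, k: int, rng: np.random.Generator):
    """Random nonnegative init: random usages, data-driven spectra.

    H0 is induced from W0 and the data (a scaled ``W0^T M``), which makes
    the factorization equivariant under gene permutations.
    """
    n, G = M.shape
    W0 = np.abs(rng.standard_normal((n, k))).astype(M.dtype) + 1e-3
    H0 = (W0.T @ M) / n
    scale = np.sqrt(M.mean() / max(np.mean(W0 @ H0), 1e-12))
    return W0 * scale, np.maximum(H0 * scale, 1e-9)


def run_replicates(
    M: np.ndarray,
    k: int,
    n_replicates: int = 50,
    base_seed: int = 0,
    max_iter: int = 200,
    tol: float = 5e-4,
) -> list[NMFReplicate]:
    """Repeated Frobenius NMF with multiplicative updates.

    Each replicate minimizes ``||M - WH||_F`` (W, H >= 0) from a random
    nonnegative initialization seeded ``base_seed + i``. Spectra rows are
    L1-normalized with the scale absorbed into W. Non-converged replicates
    are kept but flagged.
    """
    M = np.asarray(M)
    if not 1 <= k <= min(M.shape):
        raise ValueError(f"k={k} outside [1, min(n, G)]")
    out = []
    for i in range(n_replicates):
        rng = np.random.default_rng(base_seed + i)
        W0, H0 = _random_init(M, k, rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sklearn warns on max_iter stops
            model = NMF(
                n_components=k,
                init="custom",
                solver="mu",
                beta_loss="frobenius",
                tol=tol,
                max_iter=max_iter,
                random_state=base_seed + i,
            )
            model.fit_transform(M, W=W0.copy(), H=H0.copy())
        H = model.components_.astype(np.float64)
        row_sums = H.sum(axis=1)
        row_sums[row_sums == 0] = 1.0
        H = H / row_sums[:, None]
        out.append(
            NMFReplicate(
                spectra=H,
                seed=base_seed + i,
                frobenius_error=float(model.reconstruction_err_),
                converged=model.n_iter_ < max_iter,
            )
        )
    return out


def _nnls_usage(M: np.ndarray, spectra: np.ndarray):
    """Per-nucleus nonnegative least-squares refit onto consensus spectra.

    Solved through the Cholesky factor of the spectra Gram matrix, which
    reduces each per-nucleus problem from G x k to k x k.
    """
    A = np.asarray(spectra, dtype=np.float64).T  # G x k
    k = A.shape[1]
    gram = A.T @ A + 1e-12 * np.eye(k)
    R = np.linalg.cholesky(gram).T  # upper triangular, R^T R = gram
    B = np.linalg.solve(R.T, A.T @ np.asarray(M, dtype=np.float64).T).T  # n x k
    W = np.empty((M.shape[0], k))
    for i in range(M.shape[0]):
        W[i], _ = nnls(R, B[i])
    return W


def build_consensus(
    replicates: list,
    k: int,
    M: np.ndarray,
    outlier_knn: int | None = None,
    outlier_quantile: float = 0.9,
    random_state: int = 0,
) -> ConsensusResult:
    """Aggregate replicate spectra into k consensus programs.

    Pooled replicate spectra rows are density-filtered (rows whose mean
    Euclidean distance to their ``outlier_knn`` nearest neighbors exceeds
    the ``outlier_quantile`` pool threshold are dropped), k-means
    clustered, and summarized by the component-wise median (renormalized
    to the simplex). Stability is the mean silhouette of the clustering;
    usages are refit by NNLS and row-renormalized; the reconstruction
    error comes from the unnormalized refit.
    """
    if len(replicates) < 2:
        raise ValueError("need at least 2 replicates for a consensus")
    pool = np.vstack([r.spectra for r in replicates])
    n_pool = pool.shape[0]
    if outlier_knn is None:
        outlier_knn = max(1, int(round(0.3 * n_pool)))
    outlier_knn = min(outlier_knn, n_pool - 1)
    nn = NearestNeighbors(n_neighbors=outlier_knn + 1).fit(pool)
    dists, _ = nn.kneighbors(pool)
    mean_dist = dists[:, 1:].mean(axis=1)  # exclude self
    thresh = np.quantile(mean_dist, outlier_quantile)
    keep = mean_dist <= thresh
    retained = pool[keep]
    removed_frac = 1.0 - keep.mean()

    km = KMeans(n_clusters=k, n_init=10, random_state=random_state)
    labels = km.fit_predict(retained)
    counts = np.bincount(labels, minlength=k)
    small = np.flatnonzero(counts < 2)
    if len(small):
        warnings.warn(
            f"{len(small)} consensus cluster(s) received < 2 components; "
            "stability reported with those clusters excluded"
        )
    consensus = np.vstack(
        [
            np.median(retained[labels == j], axis=0)
            if counts[j]
            else np.zeros(pool.shape[1])
            for j in range(k)
        ]
    )
    row_sums = consensus.sum(axis=1)
    row_sums[row_sums == 0] = 1.0
    consensus = consensus / row_sums[:, None]

    if len(np.unique(labels)) > 1:
        sil = silhouette_samples(retained, labels)
        ok = ~np.isin(labels, small)
        stability = float(sil[ok].mean()) if ok.any() else float("nan")
    else:  # degenerate single-cluster outcome
        stability = float("nan")

    W_raw = _nnls_usage(np.asarray(M, dtype=np.float64), consensus)
    recon_err = float(np.linalg.norm(M - W_raw @ consensus))
    sums = W_raw.sum(axis=1)
    usage = np.where(sums[:, None] > 0, W_raw / np.maximum(sums, 1e-300)[:, None], 1.0 / k)
    return ConsensusResult(
        k=k,
        consensus_spectra=consensus,
        usage=usage,
        stability=stability,
        reconstruction_error=recon_err,
        n_replicates=len(replicates),
        outlier_fraction_removed=float(removed_frac),
    )


class ConsensusNMF(BaseEstimator):
    """Consensus NMF estimator (scikit-learn style).

    Parameters
    ----------
    k : number of programs.
    n_replicates : NMF restarts pooled into the consensus (default 50).
    outlier_knn : neighborhood size for component density filtering;
        ``None`` uses 30% of the pool size.
    outlier_quantile : density threshold quantile for dropping outlier
        components.
    max_iter, tol : per-replicate multiplicative-update controls.
    random_state : base seed; replicate ``i`` uses ``random_state + i``.

    Attributes (after ``fit``)
    --------------------------
    spectra_ : (k, G) consensus spectra, rows on the simplex.
    usage_ : (n, k) refit usages, rows on the simplex.
    stability_, reconstruction_error_, outlier_fraction_removed_ : floats.
    replicates_ : list of :class:`NMFReplicate`.
    """

    def __init__(
        self,
        k: int = 9,
        n_replicates: int = 50,
        outlier_knn: int | None = None,
        outlier_quantile: float = 0.9,
        max_iter: int = 200,
        tol: float = 5e-4,
        random_state: int = 0,
    ):
        self.k = k
        self.n_replicates = n_replicates
        self.outlier_knn = outlier_knn
        self.outlier_quantile = outlier_quantile
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 2 or np.min(X) < 0:
            raise ValueError("X must be a nonnegative 2-D array (nuclei x genes)")
        self.replicates_ = run_replicates(
            X, self.k, self.n_replicates, self.random_state, self.max_iter, self.tol
        )
        res = build_consensus(
            self.replicates_,
            self.k,
            X,
            outlier_knn=self.outlier_knn,
            outlier_quantile=self.outlier_quantile,
            random_state=self.random_state,
        )
        self.result_ = res
        self.spectra_ = res.consensus_spectra
        self.components_ = res.consensus_spectra  # sklearn naming
        self.usage_ = res.usage
        self.stability_ = res.stability
        self.reconstruction_error_ = res.reconstruction_error
        self.outlier_fraction_removed_ = res.outlier_fraction_removed
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        """NNLS usages of new nuclei on the fitted consensus spectra."""
        if not hasattr(self, "spectra_"):
            raise ValueError("ConsensusNMF is not fitted")
        W = _nnls_usage(np.asarray(X, dtype=np.float64), self.spectra_)
        sums = W.sum(axis=1)
        return np.where(sums[:, None] > 0, W / np.maximum(sums, 1e-300)[:, None], 1.0 / self.k)

    def fit_transform(self, X, y=None):
        return self.fit(X).usage_


def select_k(results: dict, lam: float = 1.0):
    """Choose k balancing stability (max) against reconstruction error (min).

    Both diagnostics are min-max normalized over the grid; the returned k
    maximizes ``stability_norm - lam * error_norm`` (smallest k wins
    ties). The full diagnostics table is returned for manual override.
    """
    if len(results) < 3:
        raise ValueError("k grid must contain at least 3 values")
    ks = sorted(results)
    stab = np.asarray([results[k].stability for k in ks], dtype=float)
    err = np.asarray([results[k].reconstruction_error for k in ks], dtype=float)

    def norm01(v):
        rng_ = v.max() - v.min()
        return (v - v.min()) / rng_ if rng_ > 0 else np.zeros_like(v)

    score = norm01(stab) - lam * norm01(err)
    best = ks[int(np.argmax(score))]
    table = pd.DataFrame(
        {"k": ks, "stability": stab, "reconstruction_error": err, "score": score}
    )
    return best, table


@dataclass
class Program:
    name: str
    program_class: str  # "lineage" or "state"
    top_genes: tuple
    spectra_row: np.ndarray


@dataclass
class ProgramSet:
    """Named, classified programs with their top-weighted gene lists."""

    programs: list
    gene_ids: np.ndarray

    @classmethod
    def from_spectra(
        cls,
        spectra: np.ndarray,
        gene_ids,
        names=None,
        classes=None,
        n_top: int = TOP_GENES_DEFAULT,
    ) -> "ProgramSet":
        """Annotate spectra rows by their ``n_top`` highest-weight genes
        (ties broken lexicographically by gene symbol)."""
        gene_ids = np.asarray([str(g).upper() for g in gene_ids])
        k = spectra.shape[0]
        names = list(names) if names is not None else [f"program_{j + 1}" for j in range(k)]
        classes = list(classes) if classes is not None else ["lineage"] * k
        programs = []
        for j in range(k):
            order = sorted(range(len(gene_ids)), key=lambda i: (-spectra[j, i], gene_ids[i]))
            top = tuple(gene_ids[i] for i in order[: min(n_top, len(gene_ids))])
            programs.append(Program(names[j], classes[j], top, spectra[j]))
        return cls(programs, gene_ids)

    @property
    def names(self):
        return [p.name for p in self.programs]

    def by_class(self, program_class: str):
        return [p for p in self.programs if p.program_class == program_class]

    def gene_sets(self) -> dict:
        return {p.name: list(p.top_genes) for p in self.programs}

    def write_gmt(self, path: str) -> None:
        from .annotation import write_gmt

        write_gmt(path, {p.name: list(p.top_genes) for p in self.programs})


def assign_nuclei(usage: pd.DataFrame, program_set: ProgramSet) -> pd.DataFrame:
    """Per-nucleus lineage and state labels by top-weighted program.

    Labels are the argmax of usage restricted to each program class; exact
    ties go to the lowest program index and are flagged.
    """
    out = pd.DataFrame(index=usage.index)
    for cls_name in ("lineage", "state"):
        progs = [p.name for p in program_set.by_class(cls_name)]
        col, flag = f"{cls_name}_label", f"{cls_name}_tie"
        if not progs:
            out[col] = None
            out[flag] = False
            continue
        sub = usage[progs].values
        top = sub.argmax(axis=1)  # argmax returns the first (lowest) index on ties
        is_tie = (sub == sub[np.arange(len(sub)), top][:, None]).sum(axis=1) > 1
        out[col] = [progs[i] for i in top]
        out[flag] = is_tie
    return out
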