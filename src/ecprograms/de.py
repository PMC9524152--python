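"""Mixed-effects Poisson differential expression.

For each gene, nuclei assigned to a program are compared against all
other endothelial nuclei with a Poisson generalized linear mixed model:

    log E[y] = beta0 + beta_group * group + covariates + b_patient + offset,
    b_patient ~ Normal(0, sigma^2)

with the log-normalized total UMI count as the offset. The model is fit
by maximum likelihood with a Laplace approximation to the random-intercept
integral (inner penalized IRLS jointly over fixed effects and intercepts,
outer profile over the variance). Inference on the group coefficient is
Wald; p-values are Bonferroni-adjusted across tested genes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import norm
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .containers import CountMatrix
from .stats import adjust_pvalues

__all__ = ["compute_pcs", "PoissonGLMM", "fit_poisson_glmm", "log_norm_umi_offset"]

ETA_CLIP = 30.0


def compute_pcs(M: np.ndarray, n_pcs: int = 3) -> np.ndarray:
    """Principal components of a (nuclei x genes) normalized matrix.

    Deterministic sign convention: each component's largest-magnitude
    gene loading is made positive.
    """
    M = np.asarray(M, dtype=np.float64)
    if n_pcs > min(M.shape):
        raise ValueError(f"n_pcs={n_pcs} exceeds the matrix rank bound {min(M.shape)}")
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(M)
    for j in range(n_pcs):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1.0
    return scores


def log_norm_umi_offset(total_umis) -> np.ndarray:
    """log(total UMIs / median total UMIs) per nucleus."""
    t = np.asarray(total_umis, dtype=float)
    if (t <= 0).any():
        raise ValueError("total UMI counts must be positive for the offset")
    return np.log(t / np.median(t))


class PoissonGLMM(BaseEstimator):
    """Poisson regression with an optional Gaussian random intercept.

    ``fit(X, y, groups=, offset=)`` maximizes the Laplace-approximated
    marginal likelihood; with ``groups=None`` (or when the profiled
    variance collapses to its lower bound) the model degenerates to an
    ordinary Poisson GLM. An intercept column is always added internally.

    Attributes
    ----------
    intercept_, coef_ : fixed-effect estimates (coef_ aligned with X's
        columns).
    se_, intercept_se_ : Wald standard errors.
    sigma_ : random-intercept standard deviation (0 without groups).
    ranef_ : per-group posterior modes of the random intercept.
    loglik_ : Laplace-approximated marginal log-likelihood.
    converged_ : False on IRLS failure or separation (se set to inf).
    """

    def __init__(
        self,
        max_iter: int = 50,
        tol: float = 1e-8,
        var_lower: float = 1e-8,
        var_upper: float = 25.0,
    ):
        self.max_iter = max_iter
        self.tol = tol
        self.var_lower = var_lower
        self.var_upper = var_upper

    # -- internals ---------------------------------------------------------

    def _pirls(self, A, y, offset, q, tau, theta0):
        """Penalized IRLS over stacked (fixed, random) coefficients.

        Returns (theta, info_matrix, converged). ``q`` trailing columns of
        ``A`` are ridge-penalized with 1/tau.
        """
        n, d = A.shape
        pen = np.zeros(d)
        if q:
            pen[d - q :] = 1.0 / tau
        theta = theta0.copy()
        converged = False
        info = None
        for _ in range(self.max_iter):
            eta = np.clip(A @ theta + offset, -ETA_CLIP, ETA_CLIP)
            mu = np.exp(eta)
            W = mu
            z = (eta - offset) + (y - mu) / mu
            AW = A * W[:, None]
            info = A.T @ AW + np.diag(pen)
            rhs = AW.T @ z
            try:
                new = np.linalg.solve(info, rhs)
            except np.linalg.LinAlgError:
                return theta, info, False
            step = new - theta
            theta = new
            if not np.all(np.isfinite(theta)):
                return theta, info, False
            if np.max(np.abs(step)) < self.tol * (1.0 + np.max(np.abs(theta))):
                converged = True
                break
        return theta, info, converged

    def _laplace_loglik(self, A, y, offset, q, tau, theta):
        eta = np.clip(A @ theta + offset, -ETA_CLIP, ETA_CLIP)
        mu = np.exp(eta)
        ll = float(np.sum(y * eta - mu - gammaln(y + 1.0)))
        if q:
            b = theta[-q:]
            Zb_groups = self._group_index
            d_j = np.bincount(Zb_groups, weights=mu, minlength=q)
            ll += float(-0.5 * np.sum(b**2) / tau - 0.5 * np.sum(np.log1p(tau * d_j)))
        return ll

    # -- API ---------------------------------------------------------------

    def fit(self, X, y, groups=None, offset=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and X.shape[1] == len(y) and X.shape[0] != len(y):
            X = X.T
        y = np.asarray(y, dtype=float).ravel()
        n = len(y)
        offset = np.zeros(n) if offset is None else np.asarray(offset, dtype=float).ravel()
        if not np.all(np.isfinite(offset)):
            raise ValueError("offset must be finite")
        design = np.column_stack([np.ones(n), X])
        p = design.shape[1]

        if groups is not None:
            codes, uniques = pd.factorize(np.asarray(groups))
            q = len(uniques)
            self._group_index = codes
            Z = np.zeros((n, q))
            Z[np.arange(n), codes] = 1.0
            A = np.column_stack([design, Z])
        else:
            q = 0
            A = design
        d = A.shape[1]

        theta0 = np.zeros(d)
        theta0[0] = np.log(max(y.mean(), 1e-8)) - offset.mean()

        if q == 0:
            theta, info, ok = self._pirls(A, y, offset, 0, 1.0, theta0)
            tau_hat = 0.0
        else:
            cache = {"theta": theta0}

            def neg_marginal(log_tau):
                tau = float(np.exp(log_tau))
                th, _, ok_ = self._pirls(A, y, offset, q, tau, cache["theta"])
                if ok_:
                    cache["theta"] = th
                return -self._laplace_loglik(A, y, offset, q, tau, th)

            res = minimize_scalar(
                neg_marginal,
                bounds=(np.log(self.var_lower), np.log(self.var_upper)),
                method="bounded",
                options={"xatol": 1e-3},
            )
            tau_hat = float(np.exp(res.x))
            theta, info, ok = self._pirls(A, y, offset, q, tau_hat, cache["theta"])

        self.sigma_ = float(np.sqrt(tau_hat))
        self.loglik_ = self._laplace_loglik(A, y, offset, q, tau_hat, theta)
        self.intercept_ = float(theta[0])
        self.coef_ = theta[1:p].copy()
        self.ranef_ = theta[p:].copy() if q else np.zeros(0)

        separation = np.max(np.abs(theta[:p])) > 0.6 * ETA_CLIP
        se = np.full(p, np.inf)
        if ok and not separation and info is not None:
            try:
                cov = np.linalg.inv(info)
                diag = np.diag(cov)[:p]
                if np.all(diag > 0):
                    se = np.sqrt(diag)
                else:
                    ok = False
            except np.linalg.LinAlgError:
                ok = False
        self.converged_ = bool(ok and not separation)
        self.intercept_se_ = float(se[0])
        self.se_ = se[1:].copy()
        return self

    def wald_pvalues(self) -> np.ndarray:
        """Two-sided Wald p-values for the (non-intercept) coefficients."""
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(np.isfinite(self.se_), self.coef_ / self.se_, 0.0)
        return 2.0 * norm.sf(np.abs(z))


def fit_poisson_glmm(
    X,
    in_program,
    patient_ids,
    covariates: pd.DataFrame | None = None,
    offset=None,
    gene_ids=None,
    min_expr_frac: float = 0.01,
) -> pd.DataFrame:
    """Per-gene mixed-effects Poisson DE of in-program vs other nuclei.

    Parameters
    ----------
    X
        :class:`CountMatrix` or raw (genes x nuclei) array of counts.
    in_program
        Boolean per nucleus; the reported ``beta`` is its log-rate effect.
    patient_ids
        Random-intercept grouping (sample ID).
    covariates
        Numeric fixed-effect columns (treatment arm dummies, sex, PCs).
    offset
        Per-nucleus offset; defaults to log-normalized total UMIs.
    min_expr_frac
        Genes expressed in fewer than this fraction of nuclei are skipped.

    Returns a DataFrame with gene, beta, se, p, p_adj (Bonferroni across
    tested genes) and a convergence flag. Non-converged genes are kept.
    """
    if isinstance(X, CountMatrix):
        counts = X.counts
        gene_ids = X.gene_ids if gene_ids is None else np.asarray(gene_ids)
        totals = X.total_umis()
    else:
        counts = sp.csr_matrix(np.asarray(X))
        gene_ids = (
            np.asarray([f"G{i + 1}" for i in range(counts.shape[0])])
            if gene_ids is None
            else np.asarray(gene_ids)
        )
        totals = np.asarray(counts.sum(axis=0)).ravel()

    in_program = np.asarray(in_program, dtype=float).ravel()
    n = counts.shape[1]
    if len(in_program) != n:
        raise ValueError("in_program length does not match nuclei count")
    if in_program.sum() == 0 or in_program.sum() == n:
        raise ValueError("group indicator must have nuclei on both sides")
    if len(pd.unique(np.asarray(patient_ids))) < 2:
        raise ValueError("need at least 2 patients for a random intercept")
    if offset is None:
        offset = log_norm_umi_offset(totals)
    offset = np.asarray(offset, dtype=float).ravel()

    cols = [in_program]
    names = ["group"]
    if covariates is not None:
        for c in covariates.columns:
            cols.append(np.asarray(covariates[c], dtype=float))
            names.append(str(c))
    design = np.column_stack(cols)

    expr_frac = np.asarray((counts > 0).sum(axis=1)).ravel() / n
    tested = np.flatnonzero(expr_frac >= min_expr_frac)
    rows = []
    for gi in tested:
        y = np.asarray(counts[gi].todense()).ravel()
        model = PoissonGLMM().fit(design, y, groups=patient_ids, offset=offset)
        p = model.wald_pvalues()[0] if np.isfinite(model.se_[0]) else 1.0
        rows.append(
            {
                "gene": gene_ids[gi],
                "beta": model.coef_[0],
                "se": model.se_[0],
                "p": p,
                "sigma": model.sigma_,
                "converged": model.converged_,
            }
        )
    out = pd.DataFrame(rows, columns=["gene", "beta", "se", "p", "sigma", "converged"])
    if len(out):
        out["p_adj"] = adjust_pvalues(out["p"].values, procedure="bonferroni").adjusted
    else:
        out["p_adj"] = []
    if (~out["converged"]).any():
        warnings.warn(f"{int((~out['converged']).sum())} gene fits did not converge")
    return out
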