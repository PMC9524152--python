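"""Bulk-cohort program scoring, deconvolution and survival analysis.

Cell-type proportions are estimated from marker gene means; endothelial
program scores are sums of expression over each program's top-weighted
genes, z-normalized within each cohort to absorb batch effects; prognosis
is assessed with multivariable Cox regression (Efron tie handling, Wald
inference) on age, sex, grade, stage and the program z-scores, and nodal
status with Mann-Whitney U tests on the z-scores.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy.optimize import nnls
from sklearn.base import BaseEstimator

from .extraction import MarkerPanel
from .simulate import BulkCohort
from .stats import adjust_pvalues, mann_whitney_u

__all__ = [
    "MarkerDeconvolver",
    "deconvolve",
    "score_programs",
    "cox_regression",
    "node_association",
]


class MarkerDeconvolver(BaseEstimator):
    """Marker-based estimation of cell-type proportions in bulk samples.

    ``method='marker_mean'`` (default): per-type raw score = mean
    log1p(expression) of the present markers; scores are z-scored per
    type across samples, shifted per type so their minimum is zero, and
    normalized to the simplex per sample. The z-scoring makes types with
    markers of different absolute expression comparable; with exchangeable
    type proportions and near-linear marker response, the min-shifted
    scores are approximately proportional to the true fractions.

    ``method='nnls'``: nonnegative least squares of each sample's marker
    expression onto per-type signature columns (marker-mean magnitudes),
    rows then normalized to the simplex.

    Attributes: ``proportions_`` (samples x types, simplex rows) and
    ``marker_coverage_`` (fraction of markers present per type).
    """

    def __init__(self, method: str = "marker_mean"):
        self.method = method

    def fit(self, expression: pd.DataFrame, marker_panel: MarkerPanel | None = None):
        panel = (marker_panel or MarkerPanel.deconvolution_default()).panel
        cols_upper = {str(c).upper(): c for c in expression.columns}
        present = {}
        coverage = {}
        for t, genes in panel.items():
            hit = [cols_upper[g] for g in genes if g in cols_upper]
            coverage[t] = len(hit) / len(genes)
            if not hit:
                raise ValueError(f"no marker genes present for cell type {t!r}")
            present[t] = hit
        self.marker_coverage_ = pd.Series(coverage)

        logx = np.log1p(expression.astype(float))
        raw = pd.DataFrame(
            {t: logx[genes].mean(axis=1) for t, genes in present.items()},
            index=expression.index,
        )
        if self.method == "marker_mean":
            z = (raw - raw.mean()) / raw.std(ddof=0).replace(0.0, 1.0)
            shifted = z - z.min()
            sums = shifted.sum(axis=1)
            props = shifted.div(sums.where(sums > 0, 1.0), axis=0)
            uniform = sums <= 0
            if uniform.any():
                props.loc[uniform] = 1.0 / len(present)
        elif self.method == "nnls":
            sig_genes = [g for genes in present.values() for g in genes]
            S = np.zeros((len(sig_genes), len(present)))
            for j, (t, genes) in enumerate(present.items()):
                for g in genes:
                    S[sig_genes.index(g), j] = 1.0 / len(genes)
            B = logx[sig_genes].values
            W = np.vstack([nnls(S, b)[0] for b in B])
            sums = W.sum(axis=1, keepdims=True)
            W = np.where(sums > 0, W / np.where(sums > 0, sums, 1.0), 1.0 / len(present))
            props = pd.DataFrame(W, index=expression.index, columns=list(present))
        else:
            raise ValueError(f"unknown method {self.method!r}")
        self.proportions_ = props
        return self

    def fit_transform(self, expression: pd.DataFrame, marker_panel=None) -> pd.DataFrame:
        return self.fit(expression, marker_panel).proportions_


def deconvolve(bulk: BulkCohort, marker_panel: MarkerPanel | None = None, method: str = "marker_mean"):
    """Functional wrapper over :class:`MarkerDeconvolver`."""
    model = MarkerDeconvolver(method=method).fit(bulk.expression, marker_panel)
    return model.proportions_, model.marker_coverage_


def score_programs(
    bulk: BulkCohort,
    program_signatures: dict,
    cohort_col: str = "cohort",
    min_genes: int = 10,
) -> pd.DataFrame:
    """Summed top-gene program scores, z-normalized within each cohort.

    Raw score = sum of expression over the signature genes present in the
    bulk matrix (programs with fewer than ``min_genes`` present genes are
    skipped with a warning); scores are z-scored within each
    ``cohort_col`` label independently.
    """
    cols_upper = {str(c).upper(): c for c in bulk.expression.columns}
    raw = {}
    for name, genes in program_signatures.items():
        hit = [cols_upper[str(g).upper()] for g in genes if str(g).upper() in cols_upper]
        if len(hit) < min_genes:
            warnings.warn(
                f"program {name!r} skipped: only {len(hit)} signature genes present"
            )
            continue
        raw[name] = bulk.expression[hit].sum(axis=1)
    scores = pd.DataFrame(raw, index=bulk.expression.index)
    if cohort_col not in bulk.clinical.columns:
        raise ValueError(f"clinical table lacks cohort column {cohort_col!r}")
    z = scores.copy()
    for label in bulk.clinical[cohort_col].unique():
        m = (bulk.clinical[cohort_col] == label).values
        mu = scores.loc[m].mean()
        sd = scores.loc[m].std(ddof=0).replace(0.0, 1.0)
        z.loc[m] = (scores.loc[m] - mu) / sd
    return z


def _encode_clinical(clinical: pd.DataFrame, covariates) -> pd.DataFrame:
    out = pd.DataFrame(index=clinical.index)
    for c in covariates:
        col = clinical[c]
        if c == "sex":
            out[c] = col.map({"M": 0.0, "F": 1.0}).astype(float) if col.dtype == object else col.astype(float)
        else:
            out[c] = col.astype(float)  # grade/stage as ordinal integers
    return out


def cox_regression(
    bulk: BulkCohort,
    program_zscores: pd.DataFrame,
    endpoint: str = "OS",
    covariates=("age", "sex", "grade", "stage"),
    exclude_metastatic: bool = True,
    min_events: int = 10,
) -> pd.DataFrame:
    """Multivariable Cox regression of a survival endpoint.

    Covariates are the clinical variables plus every column of
    ``program_zscores``. Ties are handled by Efron's method; hazard
    ratios carry Wald 95% confidence intervals and p-values. Requires
    >= 10 events and no constant covariates.
    """
    if endpoint not in ("OS", "TTP"):
        raise ValueError("endpoint must be 'OS' or 'TTP'")
    clinical = bulk.clinical
    if exclude_metastatic and "metastatic" in clinical.columns:
        clinical = clinical[clinical["metastatic"] == 0]
    df = _encode_clinical(clinical, covariates)
    df = df.join(program_zscores, how="inner")
    df["time"] = clinical[f"{endpoint}_time"]
    df["event"] = clinical[f"{endpoint}_event"]
    df = df.dropna()
    if df["event"].sum() < min_events:
        raise ValueError(f"fewer than {min_events} events; Cox fit refused")
    const = [c for c in df.columns if c not in ("time", "event") and df[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariates: {const}")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")  # Efron ties
    summary = cph.summary
    out = pd.DataFrame(
        {
            "covariate": summary.index,
            "hazard_ratio": summary["exp(coef)"].values,
            "ci_low": summary["exp(coef) lower 95%"].values,
            "ci_high": summary["exp(coef) upper 95%"].values,
            "p": summary["p"].values,
        }
    )
    out["endpoint"] = endpoint
    return out


def node_association(program_zscores: pd.DataFrame, n_status, fdr_level: float = 0.1) -> pd.DataFrame:
    """Mann-Whitney U comparison of program z-scores by nodal status.

    ``n_status`` holds 'N+'/'N0' per sample; one test per program with BH
    adjustment across programs.
    """
    n_status = pd.Series(np.asarray(n_status), index=program_zscores.index)
    pos = n_status.isin(["N+", "N1", "1", 1, True])
    if pos.all() or (~pos).all():
        raise ValueError("both nodal groups must be nonempty")
    rows = []
    for prog in program_zscores.columns:
        res = mann_whitney_u(
            program_zscores.loc[pos, prog].dropna().values,
            program_zscores.loc[~pos, prog].dropna().values,
        )
        rows.append(
            {
                "program": prog,
                "statistic": res.statistic,
                "p": res.p_value,
                "n_positive": int(pos.sum()),
                "n_negative": int((~pos).sum()),
            }
        )
    out = pd.DataFrame(rows)
    adj = adjust_pvalues(out["p"].values, fdr_level=fdr_level)
    out["p_adj"] = adj.adjusted
    out["significant"] = adj.significant
    return out
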