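"""Patient-level association analyses.

Program assignments are aggregated to per-patient proportions, compared
across treatment strata (arm, radiation dose group, modality) with
two-sided Mann-Whitney U tests under Benjamini-Hochberg control
(FDR = 0.1), and related to microenvironment responses by top- versus
bottom-quartile comparisons. A paired targeted panel is scored by mean
expression of program genes and tested with the Wilcoxon signed-rank
test under Bonferroni control.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

from .stats import adjust_pvalues, mann_whitney_u, wilcoxon_signed_rank

__all__ = [
    "program_proportions",
    "compare_strata",
    "quartile_association",
    "stromal_to_ec_ratio",
    "score_panel",
    "patient_program_expression",
    "leave_patients_out",
]

FOLD_CHANGE_SENTINEL = float("inf")

STRATUM_ORDER = {
    "arm": ("untreated", "CRT", "CRTL"),
    "dose_group": ("none", "low", "high"),
    "modality": ("none", "photon", "proton"),
}


def program_proportions(assignments: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-patient fraction of EC nuclei assigned to each program.

    ``assignments`` carries ``lineage_label`` / ``state_label`` per
    nucleus (index = barcode); ``metadata`` maps barcodes to patients and
    strata. Lineage and state proportions each sum to 1 per patient.
    """
    meta = metadata.set_index("barcode") if "barcode" in metadata.columns else metadata
    missing = set(assignments.index) - set(meta.index)
    if missing:
        raise ValueError(f"{len(missing)} assigned nuclei missing from metadata")
    df = assignments.join(meta[["patient_id"]], how="left")
    out = pd.DataFrame(index=pd.Index(sorted(df["patient_id"].unique()), name="patient_id"))
    for cls_name in ("lineage", "state"):
        col = f"{cls_name}_label"
        if col not in df.columns or df[col].isna().all():
            continue
        tab = pd.crosstab(df["patient_id"], df[col], normalize="index")
        tab.columns = [str(c) for c in tab.columns]
        out = out.join(tab, how="left")
    out = out.fillna(0.0)
    out["n_ec_nuclei"] = df.groupby("patient_id").size()
    strata_cols = [c for c in ("arm", "dose_group", "modality", "sex") if c in meta.columns]
    if strata_cols:
        pat = meta.groupby("patient_id")[strata_cols].first()
        out = out.join(pat, how="left")
    return out


def patient_program_expression(usage: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-patient mean usage weight of each program across EC nuclei.

    This is the patient-level "program expression" score used for
    quartile analyses.
    """
    meta = metadata.set_index("barcode") if "barcode" in metadata.columns else metadata
    df = usage.join(meta[["patient_id"]], how="left")
    return df.groupby("patient_id").mean()


def _pairs_for(levels, stratification):
    order = [l for l in STRATUM_ORDER.get(stratification, ()) if l in levels]
    order += [l for l in levels if l not in order]
    return list(itertools.combinations(order, 2))


def compare_strata(
    table: pd.DataFrame,
    stratification: str = "arm",
    pairs=None,
    value_cols=None,
    fdr_level: float = 0.1,
) -> pd.DataFrame:
    """Mann-Whitney U comparisons of program proportions between strata.

    One test per (program, stratum pair); BH adjustment across the whole
    family for this stratification. Strata with < 2 patients are skipped
    with a warning.
    """
    if stratification not in table.columns:
        raise ValueError(f"stratification column {stratification!r} missing")
    if value_cols is None:
        reserved = {"n_ec_nuclei", "arm", "dose_group", "modality", "sex"}
        value_cols = [c for c in table.columns if c not in reserved]
    levels = [l for l in table[stratification].unique() if l != "none"]
    if pairs is None:
        pairs = _pairs_for(levels, stratification)
    rows = []
    for prog in value_cols:
        for a, b in pairs:
            xa = table.loc[table[stratification] == a, prog].values
            xb = table.loc[table[stratification] == b, prog].values
            if len(xa) < 2 or len(xb) < 2:
                warnings.warn(f"stratum pair ({a}, {b}) skipped: fewer than 2 patients")
                continue
            res = mann_whitney_u(xa, xb)
            rows.append(
                {
                    "program": prog,
                    "stratification": stratification,
                    "group_a": a,
                    "group_b": b,
                    "n_a": len(xa),
                    "n_b": len(xb),
                    "statistic": res.statistic,
                    "p": res.p_value,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=["program", "stratification", "group_a", "group_b", "n_a", "n_b", "statistic", "p"],
    )
    if len(out):
        adj = adjust_pvalues(out["p"].values, fdr_level=fdr_level)
        out["p_adj"] = adj.adjusted
        out["significant"] = adj.significant
    else:
        out["p_adj"] = []
        out["significant"] = []
    return out


def _quartile_membership(scores: pd.Series):
    n = len(scores)
    q = n // 4
    order = scores.reset_index()
    order.columns = ["patient_id", "score"]
    order = order.sort_values(["score", "patient_id"], kind="mergesort")
    bottom = order["patient_id"].iloc[:q].tolist()
    top = order["patient_id"].iloc[-q:].tolist()
    return top, bottom


def quartile_association(
    ec_scores: pd.Series, responses: pd.DataFrame, fdr_level: float = 0.1
) -> pd.DataFrame:
    """Top- vs bottom-quartile comparison of responses.

    Patients are ranked by ``ec_scores`` (ties broken by patient ID);
    the top and bottom floor(n/4) patients are compared on each response
    column with a Mann-Whitney U test; fold change is the ratio of means
    (infinite sentinel when the bottom mean is 0); BH across responses.
    """
    ec_scores = ec_scores.dropna()
    if len(ec_scores) < 8:
        raise ValueError("need at least 8 patients for quartile comparisons")
    if ec_scores.nunique() == 1:
        raise ValueError("constant scores: quartiles are undefined")
    top, bottom = _quartile_membership(ec_scores)
    rows = []
    for col in responses.columns:
        rt = responses.loc[responses.index.isin(top), col].dropna().values
        rb = responses.loc[responses.index.isin(bottom), col].dropna().values
        if len(rt) < 1 or len(rb) < 1:
            warnings.warn(f"response {col!r} skipped: empty quartile group")
            continue
        res = mann_whitney_u(rt, rb)
        top_mean, bottom_mean = float(np.mean(rt)), float(np.mean(rb))
        if bottom_mean == 0:
            warnings.warn(f"response {col!r}: bottom-quartile mean is 0; fold set to inf")
            fold = FOLD_CHANGE_SENTINEL if top_mean > 0 else 1.0
        else:
            fold = top_mean / bottom_mean
        rows.append(
            {
                "response": col,
                "top_quartile_mean": top_mean,
                "bottom_quartile_mean": bottom_mean,
                "fold_change": fold,
                "statistic": res.statistic,
                "p": res.p_value,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["response", "top_quartile_mean", "bottom_quartile_mean", "fold_change", "statistic", "p"],
    )
    if len(out):
        adj = adjust_pvalues(out["p"].values, fdr_level=fdr_level)
        out["p_adj"] = adj.adjusted
        out["significant"] = adj.significant
    return out


def stromal_to_ec_ratio(
    metadata: pd.DataFrame, ec_label: str = "endothelial"
) -> pd.DataFrame:
    """Per-patient ratio of each stromal/immune cell type count to ECs.

    Patients without endothelial nuclei are excluded with a warning. Feed
    the result to :func:`quartile_association` against a patient-level
    program score.
    """
    meta = metadata.copy()
    if "cell_type" not in meta.columns:
        raise ValueError("metadata must carry cell_type labels")
    counts = pd.crosstab(meta["patient_id"], meta["cell_type"])
    if ec_label not in counts.columns:
        raise ValueError(f"no nuclei labeled {ec_label!r}")
    zero_ec = counts.index[counts[ec_label] == 0]
    if len(zero_ec):
        warnings.warn(f"{len(zero_ec)} patient(s) without EC nuclei excluded")
        counts = counts.drop(index=zero_ec)
    ratios = counts.drop(columns=[ec_label]).div(counts[ec_label], axis=0)
    ratios.columns = [f"{c}_to_ec_ratio" for c in ratios.columns]
    return ratios


def score_panel(
    panel: pd.DataFrame,
    panel_meta: pd.DataFrame,
    signatures: dict,
    condition_col: str = "condition",
    pair_col: str = "pair_id",
    conditions: tuple = ("control", "irradiated"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Targeted-panel signature scores and paired signed-rank tests.

    Score = mean expression over the panel genes overlapping each
    signature; per signature, scores are paired by ``pair_col`` between
    the two conditions and tested with the two-sided Wilcoxon signed-rank
    test, Bonferroni-adjusted across signatures. Returns
    ``(scores, tests)``.
    """
    sigs = {k: [str(g).upper() for g in v] for k, v in signatures.items()}
    genes_upper = {str(g).upper(): g for g in panel.columns}
    scores = pd.DataFrame(index=panel.index)
    for name, genes in sigs.items():
        present = [genes_upper[g] for g in genes if g in genes_upper]
        if not present:
            warnings.warn(f"signature {name!r} has no genes on the panel; skipped")
            continue
        scores[name] = panel[present].mean(axis=1)
    rows = []
    for name in scores.columns:
        wide = (
            scores[[name]]
            .join(panel_meta[[condition_col, pair_col]])
            .pivot(index=pair_col, columns=condition_col, values=name)
        )
        if not set(conditions).issubset(wide.columns):
            raise ValueError(f"conditions {conditions} not found in panel metadata")
        wide = wide.dropna()
        res = wilcoxon_signed_rank(wide[conditions[0]].values, wide[conditions[1]].values)
        rows.append(
            {
                "signature": name,
                "mean_control": float(wide[conditions[0]].mean()),
                "mean_treated": float(wide[conditions[1]].mean()),
                "statistic": res.statistic,
                "p": res.p_value,
                "n_pairs": len(wide),
            }
        )
    tests = pd.DataFrame(
        rows, columns=["signature", "mean_control", "mean_treated", "statistic", "p", "n_pairs"]
    )
    if len(tests):
        tests["p_adj"] = adjust_pvalues(tests["p"].values, procedure="bonferroni").adjusted
    return scores, tests


def leave_patients_out(table: pd.DataFrame, patients, analysis, **kwargs):
    """Robustness harness: rerun ``analysis`` with ``patients`` removed.

    ``analysis`` is a callable taking the reduced patient table (e.g.
    :func:`compare_strata`). Mirrors sensitivity checks that drop
    influential treated patients.
    """
    reduced = table.drop(index=[p for p in patients if p in table.index])
    return analysis(reduced, **kwargs)
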