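"""Synthetic data generators with known ground truth.

Three generators emulate the three data modalities the pipeline consumes:

``simulate_snrnaseq``
    A single-nucleus count matrix generated from planted nonnegative
    program spectra and per-nucleus program usages, with patient random
    effects on library scale and arm-dependent program prevalence. The
    default configuration mirrors the study cohort: 37 patients
    (18 untreated, 14 chemoradiation [CRT], 5 chemoradiation + losartan
    [CRTL]), ~3,000 endothelial nuclei, 1,500 genes, 7 planted programs
    (5 lineage-like, 2 state-like), with one "reactive" lineage program
    whose prevalence rises from 0.10 to 0.35 under treatment.

``simulate_bulk_cohort``
    Bulk expression formed as cell-type mixtures (Dirichlet proportions
    over 10 cell types with exclusive marker genes) plus an endothelial
    program component; survival times follow a proportional-hazards model
    driven by the planted program scores, with independent censoring, and
    two cohort labels for within-cohort z-normalization.

``simulate_huvec_panel``
    A paired irradiated/control targeted panel with additive condition
    effects on the genes of designated signatures.

All generators are pure functions of their configuration (which carries
the seed); two calls with the same configuration are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .containers import ARMS, CountMatrix

__all__ = [
    "SimulationConfig",
    "BulkSimulationConfig",
    "PanelSimulationConfig",
    "GroundTruth",
    "BulkGroundTruth",
    "simulate_snrnaseq",
    "simulate_bulk_cohort",
    "simulate_huvec_panel",
    "simulate_glmm_counts",
]

LINEAGE_NAMES = ("lineage_1", "lineage_2", "lineage_3", "lineage_4", "lineage_5")
STATE_NAMES = ("state_1", "state_2")

#: default per-arm program prevalence (5 lineage + 2 state programs).
#: Treated arms up-weight the reactive program (lineage_5, index 4) from
#: 0.10 to 0.35 and deplete the capillary-like program (lineage_1); losartan
#: additionally depletes the lymphatic-like program (lineage_4, index 3).
DEFAULT_PREVALENCE = {
    "untreated": (0.24, 0.14, 0.14, 0.10, 0.10, 0.18, 0.10),
    "CRT": (0.10, 0.10, 0.10, 0.07, 0.35, 0.18, 0.10),
    "CRTL": (0.10, 0.11, 0.10, 0.03, 0.35, 0.20, 0.11),
}

#: endothelial identity markers planted into every endothelial program
EC_IDENTITY_GENES = ("PECAM1", "VWF", "ESAM", "FLT1", "EPAS1", "FLT4", "SEMA3A", "SEMA3D")

NON_EC_TYPES = ("fibroblast", "macrophage", "T_cell")
NON_EC_MARKERS = {
    "fibroblast": ("COL1A1", "FN1", "DCN", "PDPN", "POSTN", "FAP"),
    "macrophage": ("CD68", "CD163", "MRC1", "CST3", "LGALS2", "TGFB1"),
    "T_cell": ("CD3D", "CD4", "CD8A", "THEMIS", "CD96", "GZMA"),
}


@dataclass
class SimulationConfig:
    """Configuration for the single-nucleus simulator.

    ``nuclei_per_patient`` is an inclusive (low, high) range sampled
    uniformly per patient. ``usage_base_alpha``/``usage_boost`` define the
    arm-dependent Dirichlet mixture for usages: a nucleus first draws its
    dominant program from the arm's prevalence, then its usage row from
    ``Dirichlet(base + boost * onehot(program))``.
    """

    arm_sizes: dict = field(default_factory=lambda: {"untreated": 18, "CRT": 14, "CRTL": 5})
    nuclei_per_patient: tuple = (60, 102)
    n_genes: int = 1500
    k_true: int = 7
    n_state_programs: int = 2
    program_prevalence_by_arm: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    usage_base_alpha: float = 0.25
    usage_boost: float = 6.0
    markers_per_program: int = 30
    spectra_shape: float = 0.3
    spectra_scale: float = 1.0
    marker_shape: float = 4.0
    marker_scale: float = 1.5
    patient_effect_sd: float = 0.3
    library_size_log_mean: float = float(np.log(1500.0))
    library_size_log_sd: float = 0.3
    ec_fraction: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.k_true < 2:
            raise ValueError("k_true must be >= 2")
        if self.k_true > self.n_genes:
            raise ValueError("degenerate config: k_true > n_genes")
        if self.k_true * self.markers_per_program > self.n_genes:
            raise ValueError("not enough genes for exclusive marker blocks")
        if not 0 < self.ec_fraction <= 1:
            raise ValueError("ec_fraction must be in (0, 1]")
        if self.patient_effect_sd < 0:
            raise ValueError("patient_effect_sd must be >= 0")
        for arm, prev in self.program_prevalence_by_arm.items():
            prev = np.asarray(prev, dtype=float)
            if len(prev) != self.k_true:
                raise ValueError(f"prevalence for arm {arm} has wrong length")
            if abs(prev.sum() - 1.0) > 1e-9 or (prev < 0).any():
                raise ValueError(f"prevalence for arm {arm} is not on the simplex")

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path: str) -> None:
        d = asdict(self)
        d["nuclei_per_patient"] = list(self.nuclei_per_patient)
        d["program_prevalence_by_arm"] = {
            k: [float(x) for x in v] for k, v in self.program_prevalence_by_arm.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)


@dataclass
class GroundTruth:
    """Planted quantities of a single-nucleus simulation."""

    spectra_true: np.ndarray  # k_true x n_genes, rows sum to 1
    usage_true: np.ndarray  # n_ec_nuclei x k_true, rows sum to 1
    nucleus_program_label: np.ndarray  # argmax usage, per EC nucleus
    program_names: tuple
    program_classes: tuple  # "lineage" / "state"
    patient_arm: dict
    gene_ids: np.ndarray
    marker_genes: dict  # program name -> planted exclusive marker genes
    planted_de_genes: dict  # gene -> planted log effect for the reactive program

    def program_gene_sets(self) -> dict:
        """Planted marker gene lists per program (for annotation tests)."""
        return dict(self.marker_genes)


def _patient_frame(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic patient roster with stratified dose/modality.

    Treated patients (CRT + CRTL, in roster order) are stratified
    deterministically: the first 11 receive low-dose radiotherapy (7 photon,
    4 proton) and the remaining 8 high-dose photon, mirroring the cohort's
    subgroup sizes; untreated patients carry none/none.
    """
    rows = []
    i = 0
    for arm in ARMS:
        for _ in range(int(config.arm_sizes.get(arm, 0))):
            rows.append({"patient_id": f"P{i + 1:02d}", "arm": arm})
            i += 1
    df = pd.DataFrame(rows)
    df["dose_group"] = "none"
    df["modality"] = "none"
    treated = df.index[df["arm"] != "untreated"]
    n_treated = len(treated)
    n_low = min(11, n_treated) if n_treated >= 19 else int(round(n_treated * 11 / 19))
    for j, idx in enumerate(treated):
        if j < n_low:
            df.loc[idx, "dose_group"] = "low"
            df.loc[idx, "modality"] = "photon" if j < int(round(n_low * 7 / 11)) else "proton"
        else:
            df.loc[idx, "dose_group"] = "high"
            df.loc[idx, "modality"] = "photon"
    df["sex"] = ["F" if j % 2 else "M" for j in range(len(df))]
    return df


def _planted_spectra(config: SimulationConfig, rng: np.random.Generator, gene_ids: np.ndarray):
    """Planted program spectra: gamma background + exclusive marker blocks.

    Endothelial identity genes get a shared moderate weight in every
    program so the simulated nuclei score as endothelial.
    """
    k, G = config.k_true, config.n_genes
    spectra = rng.gamma(config.spectra_shape, config.spectra_scale, size=(k, G))
    marker_genes = {}
    names = LINEAGE_NAMES[: k - config.n_state_programs] + STATE_NAMES[: config.n_state_programs]
    # exclusive marker blocks occupy the tail of the gene list
    mpp = config.markers_per_program
    start = G - k * mpp
    for j in range(k):
        idx = np.arange(start + j * mpp, start + (j + 1) * mpp)
        spectra[j, idx] += rng.gamma(config.marker_shape, config.marker_scale, size=mpp)
        marker_genes[names[j]] = tuple(gene_ids[idx])
    ec_idx = [i for i, g in enumerate(gene_ids) if g in EC_IDENTITY_GENES]
    spectra[:, ec_idx] += 2.0
    spectra /= spectra.sum(axis=1, keepdims=True)
    return spectra, names, marker_genes


def simulate_snrnaseq(config: SimulationConfig):
    """Generate (CountMatrix, metadata, GroundTruth) from a planted model.

    Counts follow ``Poisson(L_c * exp(b_patient) * usage_c @ spectra)`` with
    lognormal library sizes ``L_c``, Gaussian patient effects ``b`` on the
    log scale, and usages from the arm-dependent Dirichlet mixture. If
    ``ec_fraction < 1`` the remaining nuclei are drawn from non-endothelial
    cell-type profiles (their own marker blocks, no EC identity genes) so
    extraction can be tested against planted labels.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    k = config.k_true
    gene_ids = np.asarray([f"G{i + 1:05d}" for i in range(G)], dtype=object)
    # name the first genes after the identity/marker panels so marker-based
    # modules can address them
    named = list(EC_IDENTITY_GENES) + [g for m in NON_EC_MARKERS.values() for g in m]
    gene_ids[: len(named)] = named
    gene_ids = np.asarray([str(g) for g in gene_ids])

    spectra, names, marker_genes = _planted_spectra(config, rng, gene_ids)
    classes = tuple(
        "lineage" if n.startswith("lineage") else "state" for n in names
    )

    patients = _patient_frame(config)
    b_patient = rng.normal(0.0, config.patient_effect_sd, size=len(patients))

    # non-EC profiles: background gamma + their own marker block weights
    non_ec_profiles = {}
    if config.ec_fraction < 1.0:
        for t in NON_EC_TYPES:
            prof = rng.gamma(config.spectra_shape, config.spectra_scale, size=G)
            idx = [i for i, g in enumerate(gene_ids) if g in NON_EC_MARKERS[t]]
            prof[idx] += 8.0
            non_ec_profiles[t] = prof / prof.sum()

    lo, hi = config.nuclei_per_patient
    counts_cols = []
    meta_rows = []
    usage_rows = []
    labels = []
    cell_types = []
    for p_idx, prow in patients.iterrows():
        n_c = int(rng.integers(lo, hi + 1))
        prev = np.asarray(config.program_prevalence_by_arm[prow["arm"]], dtype=float)
        lib = rng.lognormal(config.library_size_log_mean, config.library_size_log_sd, size=n_c)
        lib *= np.exp(b_patient[p_idx])
        is_ec = rng.random(n_c) < config.ec_fraction
        for c in range(n_c):
            if is_ec[c]:
                prog = int(rng.choice(k, p=prev))
                alpha = np.full(k, config.usage_base_alpha)
                alpha[prog] += config.usage_boost
                u = rng.dirichlet(alpha)
                rate = lib[c] * (u @ spectra)
                usage_rows.append(u)
                labels.append(int(np.argmax(u)))
                cell_types.append("endothelial")
            else:
                t = NON_EC_TYPES[c % len(NON_EC_TYPES)]
                rate = lib[c] * non_ec_profiles[t]
                cell_types.append(t)
            counts_cols.append(rng.poisson(rate))
            meta_rows.append(
                {
                    "barcode": f"{prow['patient_id']}-N{c + 1:04d}",
                    "patient_id": prow["patient_id"],
                    "arm": prow["arm"],
                    "dose_group": prow["dose_group"],
                    "modality": prow["modality"],
                    "sex": prow["sex"],
                    "cell_type": cell_types[-1],
                }
            )
    counts = np.stack(counts_cols, axis=1)  # genes x nuclei
    metadata = pd.DataFrame(meta_rows)
    X = CountMatrix(sp.csr_matrix(counts), gene_ids, metadata["barcode"].values)

    usage_true = np.asarray(usage_rows) if usage_rows else np.zeros((0, k))
    reactive = names[4] if k >= 5 else names[-1]
    other_mean = np.delete(spectra, names.index(reactive), axis=0).mean(axis=0)
    de = {}
    for g in marker_genes[reactive]:
        gi = int(np.where(gene_ids == g)[0][0])
        de[g] = float(np.log(spectra[names.index(reactive), gi] / max(other_mean[gi], 1e-12)))
    truth = GroundTruth(
        spectra_true=spectra,
        usage_true=usage_true,
        nucleus_program_label=np.asarray(labels, dtype=int),
        program_names=tuple(names),
        program_classes=classes,
        patient_arm=dict(zip(patients["patient_id"], patients["arm"])),
        gene_ids=gene_ids,
        marker_genes=marker_genes,
        planted_de_genes=de,
    )
    return X, metadata, truth


# ---------------------------------------------------------------------------
# bulk cohort
# ---------------------------------------------------------------------------

BULK_CELL_TYPES = (
    "endothelial",
    "epithelial",
    "myeloid",
    "lymphoid",
    "fibroblast",
    "pericyte",
    "schwann",
    "endocrine",
    "neuron",
    "adipocyte",
)


@dataclass
class BulkSimulationConfig:
    """Configuration for the bulk-cohort simulator.

    Expression is a linear mixture over cell types with exclusive marker
    genes; marker magnitudes are kept moderate (``marker_expr``) so that
    marker-mean deconvolution operates in its near-linear regime.
    Survival follows ``h0 * exp(sum_p beta_p z_p)`` on the within-cohort
    z-scores of the true endothelial program signal, with independent
    exponential censoring (~20% at the default rates).
    """

    cohort_sizes: dict = field(default_factory=lambda: {"cohortA": 135, "cohortB": 134})
    cell_types: tuple = BULK_CELL_TYPES
    markers_per_type: int = 8
    marker_expr: float = 5.0
    background_expr: float = 0.05
    proportion_alpha: float = 1.5
    program_activity_shape: float = 2.0
    program_activity_scale: float = 0.5
    program_expr_scale: float = 40.0
    noise_sd: float = 0.02
    survival_beta: dict = field(default_factory=lambda: {"lineage_4": float(np.log(2.0))})
    baseline_hazard: float = 0.08
    censor_rate: float = 0.02
    node_positive_frac: float = 210 / 279
    node_shift_sd: float = 0.5
    node_program: str = "lineage_4"
    seed: int = 0


@dataclass
class BulkGroundTruth:
    proportions_true: pd.DataFrame  # samples x cell types
    program_signal_true: pd.DataFrame  # samples x lineage programs (pre-noise)
    #: within-cohort z-scores of the true signal; these drive the hazard
    program_z_true: pd.DataFrame
    survival_beta: dict
    marker_panel: dict  # cell type -> exclusive marker genes


@dataclass
class BulkCohort:
    """Bulk expression with clinical covariates and survival endpoints."""

    expression: pd.DataFrame  # samples x genes, nonnegative
    clinical: pd.DataFrame  # indexed like expression

    def __post_init__(self) -> None:
        if not self.expression.index.equals(self.clinical.index):
            raise ValueError("expression and clinical tables must share sample index")
        if self.expression.index.duplicated().any():
            raise ValueError("duplicated sample IDs")
        for col in ("OS_time", "TTP_time"):
            if col in self.clinical and (self.clinical[col] <= 0).any():
                raise ValueError(f"{col} must be positive")
        for col in ("OS_event", "TTP_event"):
            if col in self.clinical and not self.clinical[col].isin([0, 1]).all():
                raise ValueError(f"{col} must be 0/1")


def simulate_bulk_cohort(config: BulkSimulationConfig, ground_truth: GroundTruth | None = None):
    """Generate a (BulkCohort, BulkGroundTruth) pair.

    If a single-nucleus ``GroundTruth`` is supplied, its planted lineage
    spectra contribute an endothelial program component to the expression
    (scaled by the sample's endothelial proportion and per-program
    activity), so that program scoring and survival modeling can be tested
    end to end against the same planted programs.
    """
    rng = np.random.default_rng(config.seed)
    types = tuple(config.cell_types)
    if "endothelial" not in types:
        raise ValueError("cell_types must include 'endothelial'")
    n_types = len(types)

    if ground_truth is not None:
        gene_ids = list(ground_truth.gene_ids)
        lineage_idx = [i for i, c in enumerate(ground_truth.program_classes) if c == "lineage"]
        lineage_names = [ground_truth.program_names[i] for i in lineage_idx]
        lineage_spectra = ground_truth.spectra_true[lineage_idx]
    else:
        gene_ids = [f"G{i + 1:05d}" for i in range(600)]
        lineage_names = list(LINEAGE_NAMES)
        spec = rng.gamma(0.3, 1.0, size=(5, len(gene_ids)))
        for j in range(5):
            spec[j, rng.choice(len(gene_ids), 40, replace=False)] += rng.gamma(4.0, 1.5, 40)
        lineage_spectra = spec / spec.sum(axis=1, keepdims=True)

    # exclusive bulk marker genes appended to the gene space
    marker_panel = {}
    marker_genes = []
    for t in types:
        ms = [f"{t.upper()}_MK{i + 1}" for i in range(config.markers_per_type)]
        marker_panel[t] = tuple(ms)
        marker_genes.extend(ms)
    all_genes = gene_ids + marker_genes
    G = len(all_genes)

    samples = []
    cohorts = []
    for label, size in config.cohort_sizes.items():
        for i in range(int(size)):
            samples.append(f"{label}-S{i + 1:03d}")
            cohorts.append(label)
    n = len(samples)

    props = rng.dirichlet(np.full(n_types, config.proportion_alpha), size=n)
    activity = rng.gamma(
        config.program_activity_shape, config.program_activity_scale, size=(n, len(lineage_names))
    )
    endo = props[:, types.index("endothelial")]
    signal = activity * endo[:, None]  # true bulk-level program signal

    expr = np.full((n, G), config.background_expr)
    for t_idx, t in enumerate(types):
        cols = [all_genes.index(m) for m in marker_panel[t]]
        expr[:, np.asarray(cols)] += np.outer(props[:, t_idx], np.full(len(cols), config.marker_expr))
    # endothelial program component over the single-nucleus gene space
    expr[:, : len(gene_ids)] += config.program_expr_scale * (signal @ lineage_spectra)
    if config.noise_sd > 0:
        expr = np.clip(expr + rng.normal(0.0, config.noise_sd, size=expr.shape), 0.0, None)

    clinical = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    clinical["cohort"] = cohorts
    clinical["age"] = np.round(rng.normal(65.0, 8.0, size=n), 1)
    clinical["sex"] = rng.choice(["M", "F"], size=n)
    clinical["grade"] = rng.integers(1, 4, size=n)
    clinical["stage"] = rng.integers(1, 5, size=n)
    clinical["metastatic"] = 0

    # nodal status shifts the designated program's signal (planted effect)
    node_pos = rng.random(n) < config.node_positive_frac
    clinical["N_status"] = np.where(node_pos, "N+", "N0")
    if config.node_program in lineage_names and config.node_shift_sd != 0:
        j = lineage_names.index(config.node_program)
        shift_amt = np.zeros((n, len(lineage_names)))
        shift_amt[node_pos, j] = config.node_shift_sd * signal[:, j].std()
        signal = signal + shift_amt
        expr[:, : len(gene_ids)] += config.program_expr_scale * (shift_amt @ lineage_spectra)

    # within-cohort z-scores of the true signal drive the hazard
    sig = pd.DataFrame(signal, index=clinical.index, columns=lineage_names)
    z = sig.copy()
    for label in config.cohort_sizes:
        m = clinical["cohort"] == label
        z.loc[m] = (sig.loc[m] - sig.loc[m].mean()) / sig.loc[m].std(ddof=0).replace(0, 1)
    lp = np.zeros(n)
    for prog, beta in config.survival_beta.items():
        if prog in z.columns:
            lp += beta * z[prog].values
    for endpoint, rate_mult in (("OS", 1.0), ("TTP", 1.4)):
        event_t = rng.exponential(1.0 / (config.baseline_hazard * rate_mult * np.exp(lp)))
        censor_t = rng.exponential(1.0 / config.censor_rate, size=n)
        t = np.minimum(event_t, censor_t)
        clinical[f"{endpoint}_time"] = np.maximum(t, 1e-3)
        clinical[f"{endpoint}_event"] = (event_t <= censor_t).astype(int)

    expression = pd.DataFrame(expr, index=clinical.index, columns=all_genes)
    truth = BulkGroundTruth(
        proportions_true=pd.DataFrame(props, index=clinical.index, columns=types),
        program_signal_true=sig,
        program_z_true=z,
        survival_beta=dict(config.survival_beta),
        marker_panel=marker_panel,
    )
    return BulkCohort(expression, clinical), truth


# ---------------------------------------------------------------------------
# paired targeted panel
# ---------------------------------------------------------------------------


@dataclass
class PanelSimulationConfig:
    """Paired irradiated/control targeted panel.

    ``signatures`` maps signature names to gene lists on the panel;
    ``effects`` gives the additive condition effect applied to every gene
    of the signature in irradiated samples. Pairing is explicit via
    ``pair_id``; a pair-level random intercept makes the pairing
    informative.
    """

    n_pairs: int = 24
    signatures: dict = field(default_factory=dict)
    effects: dict = field(default_factory=lambda: {"lineage_5": 1.0, "lineage_4": -0.8})
    baseline_mean: float = 5.0
    baseline_sd: float = 1.0
    pair_sd: float = 0.5
    noise_sd: float = 0.5
    extra_genes: int = 40
    seed: int = 0


def _default_panel_signatures(rng: np.random.Generator) -> dict:
    return {
        name: tuple(f"{name.upper()}_PG{i + 1}" for i in range(30))
        for name in LINEAGE_NAMES
    }


def simulate_huvec_panel(config: PanelSimulationConfig):
    """Generate (panel expression, sample metadata, signatures).

    Returns a samples x genes DataFrame, a metadata frame with
    ``condition`` in {control, irradiated} and ``pair_id``, and the
    signature dictionary actually used.
    """
    rng = np.random.default_rng(config.seed)
    signatures = {k: tuple(v) for k, v in config.signatures.items()} or _default_panel_signatures(rng)
    sig_genes = [g for genes in signatures.values() for g in genes]
    if len(set(sig_genes)) != len(sig_genes):
        raise ValueError("signature gene lists must be disjoint on the panel")
    for name in config.effects:
        if name not in signatures:
            raise ValueError(f"effect specified for unknown signature {name!r}")
    genes = list(dict.fromkeys(sig_genes)) + [f"PANEL_BG{i + 1}" for i in range(config.extra_genes)]
    G = len(genes)
    base = rng.normal(config.baseline_mean, config.baseline_sd, size=G)
    effect = np.zeros(G)
    for name, eff in config.effects.items():
        idx = [genes.index(g) for g in signatures[name]]
        effect[np.asarray(idx)] = eff

    rows, meta = [], []
    for i in range(config.n_pairs):
        pair_bias = rng.normal(0.0, config.pair_sd, size=G)
        for cond, eff in (("control", 0.0), ("irradiated", 1.0)):
            rows.append(base + pair_bias + eff * effect + rng.normal(0.0, config.noise_sd, size=G))
            meta.append({"sample_id": f"pair{i + 1:02d}-{cond}", "pair_id": f"pair{i + 1:02d}", "condition": cond})
    metadata = pd.DataFrame(meta).set_index("sample_id")
    panel = pd.DataFrame(rows, index=metadata.index, columns=genes)
    return panel, metadata, signatures


# ---------------------------------------------------------------------------
# dedicated generator for the Poisson mixed-model benchmarks
# ---------------------------------------------------------------------------


def simulate_glmm_counts(
    n_patients: int = 40,
    nuclei_per_patient: int = 200,
    n_genes: int = 50,
    beta: float = 0.8,
    patient_sd: float = 0.3,
    group_frac: float = 0.3,
    base_rate: float = 0.5,
    library_log_sd: float = 0.4,
    seed: int = 0,
):
    """Counts from ``Poisson(exp(a + beta*group + b_patient + log L))``.

    Returns ``(counts [genes x nuclei], design)`` where design carries the
    group indicator, patient IDs, sex/arm nuisance covariates (null) and
    library sizes. Every gene shares the same planted ``beta``; use
    ``beta=0`` for null calibration.
    """
    rng = np.random.default_rng(seed)
    n = n_patients * nuclei_per_patient
    patient = np.repeat(np.arange(n_patients), nuclei_per_patient)
    b = rng.normal(0.0, patient_sd, size=n_patients)
    group = (rng.random(n) < group_frac).astype(float)
    lib = rng.lognormal(0.0, library_log_sd, size=n)
    eta = np.log(base_rate) + beta * group + b[patient] + np.log(lib)
    mu = np.exp(eta)
    counts = rng.poisson(mu[None, :].repeat(n_genes, axis=0))
    design = pd.DataFrame(
        {
            "patient_id": [f"P{p + 1:02d}" for p in patient],
            "group": group,
            "library_size": lib,
            "sex": rng.choice([0.0, 1.0], size=n),
        }
    )
    return counts, design
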