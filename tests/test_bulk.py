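"""Bulk deconvolution, program scoring and survival analysis."""

import numpy as np
import pandas as pd
import pytest

import ecprograms as ep
from ecprograms.extraction import MarkerPanel
from ecprograms.simulate import BulkCohort


@pytest.fixture(scope="module")
def bulk_sim():
    cfg = ep.BulkSimulationConfig(cohort_sizes={"A": 80, "B": 80}, seed=17)
    return cfg, *ep.simulate_bulk_cohort(cfg)


class TestDeconvolution:
    def test_exclusive_marker_sample_maximal_proportion(self):
        genes = ["A_MK1", "B_MK1"]
        expr = pd.DataFrame(
            [[50.0, 0.0], [0.0, 50.0]], index=["s1", "s2"], columns=genes
        )
        panel = MarkerPanel(panel={"a": ("A_MK1",), "b": ("B_MK1",)}, ec_types=("a",))
        model = ep.MarkerDeconvolver().fit(expr, panel)
        props = model.proportions_
        assert props.loc["s1"].idxmax() == "a"
        assert props.loc["s2"].idxmax() == "b"

    def test_rows_on_simplex(self, bulk_sim):
        _, bulk, truth = bulk_sim
        props, coverage = ep.deconvolve(bulk, MarkerPanel(panel=truth.marker_panel, ec_types=("endothelial",)))
        assert np.allclose(props.sum(axis=1), 1.0, atol=1e-12)
        assert (props.values >= 0).all()
        assert (coverage == 1.0).all()

    def test_recovers_planted_proportions(self, bulk_sim):
        _, bulk, truth = bulk_sim
        props, _ = ep.deconvolve(bulk, MarkerPanel(panel=truth.marker_panel, ec_types=("endothelial",)))
        mae = (props[truth.proportions_true.columns] - truth.proportions_true).abs().values.mean()
        assert mae <= 0.05

    def test_nnls_variant_also_recovers(self, bulk_sim):
        _, bulk, truth = bulk_sim
        props, _ = ep.deconvolve(
            bulk, MarkerPanel(panel=truth.marker_panel, ec_types=("endothelial",)), method="nnls"
        )
        mae = (props[truth.proportions_true.columns] - truth.proportions_true).abs().values.mean()
        assert mae <= 0.1

    def test_absent_type_markers_raise(self, bulk_sim):
        _, bulk, _ = bulk_sim
        panel = MarkerPanel(panel={"ghost": ("NOT_A_GENE",)}, ec_types=("ghost",))
        with pytest.raises(ValueError, match="ghost"):
            ep.deconvolve(bulk, panel)

    def test_invariant_to_global_sample_scaling(self, bulk_sim):
        _, bulk, truth = bulk_sim
        panel = MarkerPanel(panel=truth.marker_panel, ec_types=("endothelial",))
        p1, _ = ep.deconvolve(bulk, panel)
        scaled = BulkCohort(bulk.expression * 2.0, bulk.clinical)
        p2, _ = ep.deconvolve(scaled, panel)
        assert np.abs(p1.values - p2.values).mean() <= 0.02


@pytest.fixture(scope="module")
def signatures(bulk_sim):
    _, bulk, _ = bulk_sim
    genes = [g for g in bulk.expression.columns if g.startswith("G")]
    rng = np.random.default_rng(0)
    return {f"lineage_{i+1}": list(rng.choice(genes, 60, replace=False)) for i in range(5)}


class TestScorePrograms:
    def test_within_cohort_zscores(self, bulk_sim, signatures):
        _, bulk, _ = bulk_sim
        z = ep.score_programs(bulk, signatures)
        for label in ("A", "B"):
            m = bulk.clinical.cohort == label
            assert np.allclose(z.loc[m.values].mean(), 0.0, atol=1e-9)
            assert np.allclose(z.loc[m.values].std(ddof=0), 1.0, atol=1e-9)

    def test_cross_cohort_scale_differences_absorbed(self, bulk_sim, signatures):
        _, bulk, _ = bulk_sim
        expr = bulk.expression.copy()
        mask = (bulk.clinical.cohort == "B").values
        expr.iloc[mask] *= 10.0  # gross batch effect in one cohort
        z = ep.score_programs(BulkCohort(expr, bulk.clinical), signatures)
        assert abs(z.values.mean()) <= 1e-9

    def test_gene_reordering_equivariance(self, bulk_sim, signatures):
        _, bulk, _ = bulk_sim
        z1 = ep.score_programs(bulk, signatures)
        shuffled = bulk.expression[list(bulk.expression.columns[::-1])]
        z2 = ep.score_programs(BulkCohort(shuffled, bulk.clinical), signatures)
        pd.testing.assert_frame_equal(z1, z2)

    def test_sparse_signature_skipped(self, bulk_sim):
        _, bulk, _ = bulk_sim
        with pytest.warns(UserWarning, match="skipped"):
            z = ep.score_programs(bulk, {"tiny": ["G00001", "G00002"]})
        assert "tiny" not in z.columns

    def test_planted_high_signal_samples_rank_high(self, bulk_sim, small_sim):
        # top-decile z-scores of the planted survival program coincide with
        # top-decile true signal
        _, bulk, truth = bulk_sim
        cfg2, X, meta, sn_truth = small_sim
        # rebuild with the single-nucleus truth to tie program genes to bulk
        bc = ep.BulkSimulationConfig(cohort_sizes={"A": 80, "B": 80}, seed=23)
        bulk2, bt2 = ep.simulate_bulk_cohort(bc, sn_truth)
        ps = ep.ProgramSet.from_spectra(
            sn_truth.spectra_true, sn_truth.gene_ids, names=sn_truth.program_names,
            classes=sn_truth.program_classes,
        )
        z = ep.score_programs(bulk2, {p.name: p.top_genes for p in ps.by_class("lineage")})
        n_top = len(z) // 10
        top_called = set(z["lineage_4"].nlargest(n_top).index)
        top_true = set(bt2.program_signal_true["lineage_4"].nlargest(n_top).index)
        overlap = len(top_called & top_true) / n_top
        assert overlap >= 0.6


def cox_partial_loglik(beta, times, events, x):
    """Hand-written partial log-likelihood, single covariate, no ties."""
    order = np.argsort(times)
    times, events, x = times[order], events[order], x[order]
    ll = 0.0
    for i in range(len(times)):
        if events[i]:
            risk = x[i:] * beta
            ll += beta * x[i] - np.log(np.sum(np.exp(risk)))
    return ll


class TestCoxRegression:
    def test_matches_brute_force_partial_likelihood(self):
        times = np.array([2.0, 3.0, 5.0, 7.0, 11.0])
        events = np.array([1, 1, 0, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0])
        grid = np.arange(-3.0, 3.0, 1e-4)
        lls = [cox_partial_loglik(b, times, events, x) for b in grid]
        beta_grid = grid[int(np.argmax(lls))]

        clin = pd.DataFrame(
            {
                "cohort": "A",
                "age": 60.0,
                "sex": ["M", "F", "M", "F", "M"],
                "grade": 2,
                "stage": 2,
                "OS_time": times,
                "OS_event": events,
            },
            index=[f"s{i}" for i in range(5)],
        )
        expr = pd.DataFrame(np.ones((5, 1)), index=clin.index, columns=["G1"])
        z = pd.DataFrame({"prog": x}, index=clin.index)
        out = ep.cox_regression(
            BulkCohort(expr, clin), z, endpoint="OS", covariates=(), min_events=1
        )
        beta_fit = np.log(out.set_index("covariate").loc["prog", "hazard_ratio"])
        assert beta_fit == pytest.approx(beta_grid, abs=1e-4)

    def test_time_unit_invariance(self, bulk_sim):
        _, bulk, truth = bulk_sim
        out1 = ep.cox_regression(bulk, truth.program_z_true, endpoint="OS")
        clin2 = bulk.clinical.copy()
        clin2["OS_time"] = clin2["OS_time"] * 365.25
        out2 = ep.cox_regression(BulkCohort(bulk.expression, clin2), truth.program_z_true, "OS")
        assert np.allclose(out1.hazard_ratio.values, out2.hazard_ratio.values, rtol=1e-8)

    def test_ci_ordering_and_endpoint_column(self, bulk_sim):
        _, bulk, truth = bulk_sim
        out = ep.cox_regression(bulk, truth.program_z_true, endpoint="TTP")
        assert (out.ci_low <= out.hazard_ratio).all()
        assert (out.hazard_ratio <= out.ci_high).all()
        assert (out.endpoint == "TTP").all()

    def test_constant_covariate_rejected(self, bulk_sim):
        _, bulk, truth = bulk_sim
        z = truth.program_z_true.copy()
        z["flat"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            ep.cox_regression(bulk, z, endpoint="OS")

    def test_too_few_events_rejected(self, bulk_sim):
        _, bulk, truth = bulk_sim
        clin = bulk.clinical.copy()
        clin["OS_event"] = 0
        clin.iloc[:3, clin.columns.get_loc("OS_event")] = 1
        with pytest.raises(ValueError, match="10 events"):
            ep.cox_regression(BulkCohort(bulk.expression, clin), truth.program_z_true, "OS")


class TestNodeAssociation:
    def test_label_swap_leaves_p_unchanged(self, bulk_sim):
        _, bulk, truth = bulk_sim
        z = truth.program_z_true
        n1 = ep.node_association(z, bulk.clinical["N_status"])
        swapped = bulk.clinical["N_status"].map({"N+": "N0", "N0": "N+"})
        n2 = ep.node_association(z, swapped)
        assert np.allclose(n1.p.values, n2.p.values)

    def test_planted_shift_detected(self, bulk_sim):
        _, bulk, truth = bulk_sim
        out = ep.node_association(truth.program_z_true, bulk.clinical["N_status"])
        assert out.set_index("program").loc["lineage_4", "p"] < 0.05

    def test_single_group_rejected(self, bulk_sim):
        _, bulk, truth = bulk_sim
        with pytest.raises(ValueError, match="nonempty"):
            ep.node_association(truth.program_z_true, ["N+"] * len(truth.program_z_true))
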