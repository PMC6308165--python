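"""Probe aggregation, quantile normalization, CNR and PAS scoring."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from amptox.pathways import (
    PathwayActivation,
    PathwayDB,
    ProbeMatrix,
    aggregate_probes,
    classify_pathways,
    compute_cnr,
    compute_pas,
    quantile_normalize,
)
from amptox.simulate import StudyDesign, gen_expression_study


def probe_matrix(signals: pd.DataFrame, gene_map: dict, samples: pd.DataFrame | None = None):
    if samples is None:
        samples = pd.DataFrame(
            {"group": ["control"] * signals.shape[1],
             "concentration_uM": 0.0, "replicate": 1},
            index=signals.columns)
    return ProbeMatrix(signals=signals,
                       probe_to_gene=pd.Series(gene_map),
                       samples=samples)


class TestAggregateProbes:
    def test_geometric_mean_of_two_probes(self):
        pm = probe_matrix(pd.DataFrame({"s1": [4.0, 9.0], "s2": [2.0, 2.0]},
                                       index=["p1", "p2"]),
                          {"p1": "gA", "p2": "gA"})
        expr = aggregate_probes(pm)
        assert expr.loc["gA", "s1"] == pytest.approx(6.0)
        assert expr.loc["gA", "s2"] == pytest.approx(2.0)

    def test_single_probe_gene_unchanged(self):
        pm = probe_matrix(pd.DataFrame({"s1": [7.3]}, index=["p1"]), {"p1": "gA"})
        assert aggregate_probes(pm).loc["gA", "s1"] == pytest.approx(7.3)

    def test_zero_signal_floored_before_averaging(self):
        pm = probe_matrix(pd.DataFrame({"s1": [0.0, 16.0]}, index=["p1", "p2"]),
                          {"p1": "gA", "p2": "gA"})
        # oracle: recompute with explicit flooring, gm(1, 16) = 4
        assert aggregate_probes(pm, floor=1.0).loc["gA", "s1"] == pytest.approx(4.0)

    def test_nonpositive_floor_rejected(self):
        pm = probe_matrix(pd.DataFrame({"s1": [1.0]}, index=["p1"]), {"p1": "gA"})
        with pytest.raises(ValueError, match="floor"):
            aggregate_probes(pm, floor=0.0)


class TestQuantileNormalize:
    def test_two_sample_hand_computed(self):
        expr = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [2.0, 4.0, 6.0]})
        out = quantile_normalize(expr)
        assert out["s1"].tolist() == [1.5, 3.0, 4.5]
        assert out["s2"].tolist() == [1.5, 3.0, 4.5]

    def test_matches_limma_normalize_quantiles_with_ties(self):
        # frozen oracle: limma::normalizeQuantiles(m, ties=TRUE) on this matrix
        expr = pd.DataFrame({"a": [5.0, 2.0, 3.0, 2.0],
                             "b": [4.0, 1.0, 4.0, 9.0],
                             "c": [7.0, 7.0, 2.0, 10.0]})
        expected = np.array([
            [8.0, 4.5, 4.5],
            [3.0, 5 / 3, 4.5],
            [14 / 3, 4.5, 5 / 3],
            [3.0, 8.0, 8.0],
        ])
        assert np.allclose(quantile_normalize(expr).to_numpy(), expected)

    def test_identical_columns_unchanged(self):
        expr = pd.DataFrame({"s1": [3.0, 1.0, 2.0], "s2": [3.0, 1.0, 2.0]})
        pd.testing.assert_frame_equal(quantile_normalize(expr), expr)

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(rng.lognormal(3, 1, size=(50, 6)))
        once = quantile_normalize(expr)
        twice = quantile_normalize(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(rng.lognormal(3, 1, size=(30, 4)),
                            index=[f"g{i}" for i in range(30)])
        perm = rng.permutation(30)
        out_direct = quantile_normalize(expr).iloc[perm]
        out_permuted = quantile_normalize(expr.iloc[perm])
        assert np.allclose(out_direct.to_numpy(), out_permuted.to_numpy())

    def test_single_sample_is_identity_with_warning(self):
        expr = pd.DataFrame({"s1": [3.0, 1.0]})
        with pytest.warns(UserWarning, match="single sample"):
            out = quantile_normalize(expr)
        pd.testing.assert_frame_equal(out, expr)


class TestCNR:
    EXPR = pd.DataFrame({"c1": [10.0, 10.0], "c2": [20.0, 10.0],
                         "c3": [30.0, 10.0], "t": [15.0, 20.0]},
                        index=["gA", "gB"])

    def test_case_over_control_mean(self):
        cnr = compute_cnr(self.EXPR, "t", ["c1", "c2", "c3"])
        assert cnr["gA"] == pytest.approx(0.75)  # 15 / mean(10,20,30)
        assert cnr["gB"] == pytest.approx(2.0)

    def test_case_equal_to_controls_gives_unity(self):
        expr = pd.DataFrame({"c1": [5.0], "c2": [5.0], "t": [5.0]}, index=["g"])
        assert compute_cnr(expr, "t", ["c1", "c2"])["g"] == pytest.approx(1.0)

    def test_case_in_controls_rejected(self):
        with pytest.raises(ValueError, match="control group"):
            compute_cnr(self.EXPR, "c1", ["c1", "c2"])

    def test_empty_controls_rejected(self):
        with pytest.raises(ValueError):
            compute_cnr(self.EXPR, "t", [])

    def test_control_vs_group_geometric_mean_is_unity_for_identical_controls(self):
        expr = pd.DataFrame({f"c{i}": [4.0, 7.0] for i in range(3)} | {"x": [1.0, 1.0]},
                            index=["gA", "gB"])
        logs = []
        for case in ("c0", "c1", "c2"):
            others = [c for c in ("c0", "c1", "c2") if c != case]
            logs.append(np.log(compute_cnr(expr, case, others)))
        assert np.allclose(np.exp(np.mean(logs, axis=0)), 1.0)


TOY_DB = PathwayDB({"p": {"A": 1, "B": -1, "C": 0.5, "D": 0}})


class TestPAS:
    def test_worked_toy_pathway(self):
        cnr = pd.Series({"A": 10.0, "B": 10.0, "C": 100.0, "D": 5.0})
        prof = compute_pas(cnr, TOY_DB)
        # brute force: (1*1 + (-1)*1 + 0.5*2 + 0*log10(5)) / 4
        assert prof.loc["p", "pas"] == pytest.approx(0.25)
        assert prof.loc["p", "n_genes_used"] == 4
        assert prof.loc["p", "call"] == "activated"

    def test_unity_cnr_gives_zero_everywhere(self):
        db = PathwayDB({"p1": {"A": 1, "B": -1}, "p2": {"C": 0.5}})
        cnr = pd.Series({"A": 1.0, "B": 1.0, "C": 1.0})
        assert (compute_pas(cnr, db)["pas"] == 0.0).all()

    def test_single_activator_tenfold(self):
        prof = compute_pas(pd.Series({"A": 10.0}), PathwayDB({"p": {"A": 1}}))
        assert prof.loc["p", "pas"] == pytest.approx(1.0)

    def test_missing_genes_excluded_from_sum_and_n(self):
        cnr = pd.Series({"A": 10.0})  # B, C, D unmeasured
        prof = compute_pas(cnr, TOY_DB)
        assert prof.loc["p", "pas"] == pytest.approx(1.0)
        assert prof.loc["p", "n_genes_used"] == 1

    def test_pathway_with_no_measured_gene_reported_missing(self):
        db = PathwayDB({"p": {"A": 1}, "q": {"Z": -1}})
        prof = compute_pas(pd.Series({"A": 2.0}), db)
        assert math.isnan(prof.loc["q", "pas"])
        assert prof.loc["q", "call"] == "missing"

    @given(st.floats(0.01, 100.0))
    def test_scaling_law(self, c):
        """Scaling every CNR by c shifts PAS by log10(c) * sum(ARR) / N exactly."""
        cnr = pd.Series({"A": 10.0, "B": 10.0, "C": 100.0, "D": 5.0})
        base = compute_pas(cnr, TOY_DB).loc["p", "pas"]
        shifted = compute_pas(cnr * c, TOY_DB).loc["p", "pas"]
        arr_sum = sum(TOY_DB.pathways["p"].values())
        assert shifted - base == pytest.approx(math.log10(c) * arr_sum / 4, abs=1e-12)

    def test_additive_over_disjoint_gene_subsets(self):
        rng = np.random.default_rng(6)
        genes_a = {f"a{i}": w for i, w in enumerate([1, -0.5, 0.5])}
        genes_b = {f"b{i}": w for i, w in enumerate([-1, 1, 0, 0.5, -0.5])}
        cnr = pd.Series(rng.lognormal(0, 0.5, 8),
                        index=list(genes_a) + list(genes_b))
        pas_a = compute_pas(cnr, PathwayDB({"pa": genes_a})).loc["pa", "pas"]
        pas_b = compute_pas(cnr, PathwayDB({"pb": genes_b})).loc["pb", "pas"]
        pas_union = compute_pas(cnr, PathwayDB({"pu": genes_a | genes_b})).loc["pu", "pas"]
        assert pas_union == pytest.approx((3 * pas_a + 5 * pas_b) / 8, abs=1e-12)

    def test_invalid_arr_weight_rejected(self):
        with pytest.raises(ValueError, match="ARR"):
            PathwayDB({"p": {"A": 0.7}})

    def test_empty_pathway_rejected(self):
        with pytest.raises(ValueError, match="no genes"):
            PathwayDB({"p": {}})


class TestClassify:
    def test_sign_calls(self):
        prof = pd.DataFrame({"pas": [0.3, -0.3, 0.0],
                             "n_genes_used": [3, 3, 3],
                             "call": ["activated", "repressed", "neutral"]},
                            index=pd.Index(["p1", "p2", "p3"], name="pathway"))
        calls, confusion = classify_pathways(
            prof, {"p1": "activated", "p2": "repressed", "p3": "activated"})
        assert confusion == {"correct": 2, "wrong_sign": 1, "missing": 0}

    def test_planted_directions_recovered_end_to_end(self):
        design = StudyDesign(n_genes=200, n_pathways=20, noise_sd=0.1, seed=12,
                             planted_effects={"pw0000": 1.0, "pw0001": -1.0})
        probes, db, truth = gen_expression_study(design)
        results = PathwayActivation(probes, db).fit()
        mean_pas = results.group_pas.mean(axis=1)
        assert mean_pas["pw0000"] > 0
        assert mean_pas["pw0001"] < 0


class TestModel:
    def test_fit_produces_per_sample_and_group_scores(self):
        design = StudyDesign(n_genes=60, n_pathways=6, noise_sd=0.2, seed=8,
                             planted_effects={"pw0000": 1.0})
        probes, db, _ = gen_expression_study(design)
        results = PathwayActivation(probes, db).fit()
        assert set(results.pas.columns) == {"pathway", "sample", "pas",
                                            "n_genes_used", "call"}
        # 6 pathways x 9 treated samples
        assert len(results.pas) == 54
        assert results.group_pas.shape == (6, 3)
        assert results.cnr.shape == (60, 9)
        text = results.summary()
        assert "pathways scored: 6" in text

    def test_requires_both_groups(self):
        design = StudyDesign(n_genes=30, n_pathways=3, seed=1)
        probes, db, _ = gen_expression_study(design)
        probes.samples["group"] = "treated"
        with pytest.raises(ValueError, match="control"):
            PathwayActivation(probes, db).fit()
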