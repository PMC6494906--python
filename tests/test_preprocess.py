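import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pentalayout.expression_io import ExpressionMatrix, SampleRecord
from pentalayout.panel import GenePanel
from pentalayout.preprocess import (
    CompositionMatrix,
    classify_profiles,
    correct_age,
    fold_enrichment,
    global_contribution,
    probe_consistency,
    proportional_contribution,
    select_probe_efa,
    select_probes,
)

from conftest import make_ontology, toy_matrix


def two_gene_panel():
    return GenePanel(
        symbols=("GA", "GB"),
        family={"GA": "alpha", "GB": "beta"},
        sum_membership={"GA": "SigmaAlpha", "GB": "SigmaBeta"},
    )


class TestSelectProbeEfa:
    def test_single_probe_returned(self):
        m = toy_matrix([[1.0, 2.0, 3.0]], row_ids=["pA"])
        assert select_probe_efa(m) == "pA"

    def test_two_probe_rule_higher_mean_wins(self):
        m = toy_matrix([[7.0, 7.0], [5.0, 5.0]], row_ids=["p1", "p2"],
                       scale="log2")
        assert select_probe_efa(m) == "p1"
        m2 = toy_matrix([[5.0, 5.0], [7.0, 7.0]], row_ids=["p1", "p2"],
                        scale="log2")
        assert select_probe_efa(m2) == "p2"

    def test_zero_probes_raises(self, panel):
        m = ExpressionMatrix([], [SampleRecord("s0")], np.empty((0, 1)), "log2")
        with pytest.raises(LookupError):
            select_probe_efa(m)

    def test_three_probe_fixture_recovers_faithful(self, probe_fixture):
        probe_mats, truth_map = probe_fixture
        concat = ExpressionMatrix(
            probe_mats[0].row_ids,
            [s for m in probe_mats for s in m.samples],
            np.concatenate([m.values for m in probe_mats], axis=1),
            probe_mats[0].scale, probe_mats[0].unit,
        )
        selected = select_probes(
            concat, {p: p.rsplit("_p", 1)[0] for p in concat.row_ids}
        )
        hits = sum(selected[g] == pid for g, pid in truth_map.items())
        assert hits >= 18


class TestProbeConsistency:
    def test_identical_profiles_score_one(self):
        ont = make_ontology(6)
        vals = np.array([[1.0, 4.0, 2.0, 8.0, 3.0, 5.0]])
        mats = []
        for k in range(3):
            samples = [SampleRecord(f"R{i:03d}", f"S{k}", f"R{i:03d}")
                       for i in range(6)]
            mats.append(ExpressionMatrix(["p1"], samples, vals, "log2"))
        scores = probe_consistency(mats, {"p1": "g1"})
        assert scores[0].consistency == pytest.approx(1.0)

    def test_shuffled_profiles_score_near_zero(self):
        rng = np.random.default_rng(1)
        base = rng.normal(8, 2, 100)
        mats = []
        for k in range(4):
            samples = [SampleRecord(f"R{i:03d}", f"S{k}", f"R{i:03d}")
                       for i in range(100)]
            mats.append(ExpressionMatrix(
                ["p1"], samples, rng.permutation(base)[None, :], "log2"))
        scores = probe_consistency(mats, {"p1": "g1"})
        assert abs(scores[0].consistency) < 0.2

    def test_faithful_ranks_first_per_gene(self, probe_fixture):
        probe_mats, truth_map = probe_fixture
        scores = probe_consistency(
            probe_mats, {p: p.rsplit("_p", 1)[0] for p in probe_mats[0].row_ids}
        )
        best_by_gene = {}
        for s in scores:  # already sorted by descending consistency
            best_by_gene.setdefault(s.gene, s.probe_id)
        hits = sum(best_by_gene[g] == pid for g, pid in truth_map.items())
        assert hits >= 18

    def test_needs_two_subjects(self, probe_fixture):
        probe_mats, _ = probe_fixture
        with pytest.raises(ValueError, match="2 subjects"):
            probe_consistency(probe_mats[:1], {})


class TestCorrectAge:
    def _matrix_with_ages(self, values, ages):
        samples = [SampleRecord(f"s{j}", age=a) for j, a in enumerate(ages)]
        return ExpressionMatrix(
            [f"g{i}" for i in range(values.shape[0])], samples, values, "log2"
        )

    def test_perfect_linear_fit_collapses_to_grand_mean(self):
        ages = np.array([20.0, 30.0, 40.0, 50.0])
        vals = (2.0 + 0.1 * ages)[None, :]
        m = self._matrix_with_ages(vals, ages)
        out = correct_age(m, "continuous")
        assert np.allclose(out.values, vals.mean())

    def test_age_independent_gene_unchanged(self):
        ages = np.array([20.0, 30.0, 40.0, 50.0])
        vals = np.array([[5.0, 5.0, 5.0, 5.0]])
        out = correct_age(self._matrix_with_ages(vals, ages), "continuous")
        centered = ages - ages.mean()
        refit = (out.values[0] @ centered) / (centered @ centered)
        assert abs(refit) < 1e-8

    def test_synthetic_slope_removed(self):
        rng = np.random.default_rng(1)
        ages = rng.uniform(20, 80, 100)
        vals = (3.0 + 0.1 * ages + rng.normal(0, 0.1, 100))[None, :]
        out = correct_age(self._matrix_with_ages(vals, ages), "continuous")
        centered = ages - ages.mean()
        refit = (out.values[0] @ centered) / (centered @ centered)
        assert abs(refit) < 0.02

    def test_constant_age_skips_with_warning(self, caplog):
        ages = np.array([30.0, 30.0, 30.0])
        vals = np.array([[1.0, 2.0, 3.0]])
        with caplog.at_level("WARNING"):
            out = correct_age(self._matrix_with_ages(vals, ages), "continuous")
        assert (out.values == vals).all()
        assert any("skipped" in r.message for r in caplog.records)

    def test_ordinal_mode_removes_category_means(self):
        samples = [
            SampleRecord(f"s{j}", extra={"age_category": cat})
            for j, cat in enumerate(["young", "young", "old", "old"])
        ]
        vals = np.array([[1.0, 3.0, 11.0, 13.0]])
        m = ExpressionMatrix(["g"], samples, vals, "log2")
        out = correct_age(m, "ordinal")
        # category means (2 and 12) replaced by the grand mean 7
        assert np.allclose(out.values, [[6.0, 8.0, 6.0, 8.0]])


class TestProportionalContribution:
    def test_linear_25_75(self):
        m = toy_matrix([[25.0], [75.0]], row_ids=["GA", "GB"])
        comp = proportional_contribution(m, two_gene_panel())
        assert np.allclose(comp.values[:, 0], [25.0, 75.0])

    def test_log2_equal_values_split_evenly(self):
        m = toy_matrix([[3.0], [3.0]], row_ids=["GA", "GB"], scale="log2")
        comp = proportional_contribution(m, two_gene_panel())
        assert np.allclose(comp.values[:, 0], [50.0, 50.0])

    def test_columns_sum_to_100(self, regional_fixture, panel):
        _, mats, _ = regional_fixture
        comp = proportional_contribution(mats[0], panel)
        assert np.abs(comp.values.sum(axis=0) - 100.0).max() < 1e-9

    def test_zero_total_column_excluded(self):
        m = toy_matrix([[25.0, 0.0], [75.0, 0.0]], row_ids=["GA", "GB"])
        comp = proportional_contribution(m, two_gene_panel())
        assert comp.shape == (2, 1)
        assert comp.excluded_samples == ["s1"]

    def test_missing_gene_rejected(self):
        m = toy_matrix([[1.0]], row_ids=["GA"])
        with pytest.raises(KeyError, match="GB"):
            proportional_contribution(m, two_gene_panel())

    @given(st.floats(0.01, 1000.0))
    @settings(max_examples=30, deadline=None)
    def test_invariant_to_column_scaling(self, factor):
        m = toy_matrix([[2.0, 4.0], [6.0, 1.0]], row_ids=["GA", "GB"])
        scaled = toy_matrix(m.values * factor, row_ids=["GA", "GB"])
        a = proportional_contribution(m, two_gene_panel()).values
        b = proportional_contribution(scaled, two_gene_panel()).values
        assert np.allclose(a, b)


class TestGlobalContribution:
    def test_single_gene_carries_all(self):
        m = toy_matrix([[5.0, 7.0], [0.0, 0.0]], row_ids=["GA", "GB"])
        contrib = global_contribution(m, two_gene_panel())
        assert contrib["GA"] == pytest.approx(100.0)
        assert contrib["GB"] == pytest.approx(0.0)

    def test_uniform_panel(self, panel):
        m = toy_matrix(np.ones((19, 4)), row_ids=list(panel.symbols))
        contrib = global_contribution(m, panel)
        for g in panel.symbols:
            assert contrib[g] == pytest.approx(100.0 / 19)

    def test_sums_to_100(self, regional_fixture, panel):
        _, mats, _ = regional_fixture
        contrib = global_contribution(mats[0], panel)
        assert sum(contrib.values()) == pytest.approx(100.0)


class TestFoldEnrichment:
    def _substructure_matrix(self, values, row_ids, n_regions):
        ont = make_ontology(n_regions)
        samples = [SampleRecord(f"R{j:03d}", "group", f"R{j:03d}")
                   for j in range(n_regions)]
        return ExpressionMatrix(row_ids, samples, values, "linear"), ont

    def test_uniform_gene_fold_one(self, panel):
        vals = np.ones((1, 10)) * 3.0
        m, ont = self._substructure_matrix(vals, ["GABRA1"], 10)
        table = fold_enrichment(m, panel, ont)
        assert all(r.fold == pytest.approx(1.0) for r in table.rows)

    def test_single_hot_region(self, panel):
        vals = np.ones((1, 10))
        vals[0, 3] = 2.0
        m, ont = self._substructure_matrix(vals, ["GABRA1"], 10)
        table = fold_enrichment(m, panel, ont)
        assert table.fold("GABRA1", "R003") == pytest.approx(2.0 / 1.1)
        sub, fold = table.max_fold("GABRA1")
        assert sub == "R003"

    def test_folds_average_to_one(self, regional_fixture, panel):
        truth, mats, ont = regional_fixture
        table = fold_enrichment(mats[0], panel, ont)
        n_regions = mats[0].shape[1]
        for g in table.genes():
            folds = [r.fold for r in table.rows if r.gene == g]
            assert np.mean(folds) == pytest.approx(1.0)
            assert len(folds) == n_regions

    def test_planted_enrichment_recovered(self, regional_fixture, panel):
        truth, mats, ont = regional_fixture
        table = fold_enrichment(mats[0], panel, ont)
        sub, fold = table.max_fold("GABRA6")
        assert sub == "PV-V"
        assert fold > 50  # planted 200-fold, diluted by the global mean shift

    def test_zero_mean_gene_flagged(self, panel):
        vals = np.vstack([np.zeros((1, 5)), np.ones((1, 5))])
        m, ont = self._substructure_matrix(vals, ["GABRA1", "GABRA2"], 5)
        with pytest.warns(UserWarning, match="zero brain-wide mean"):
            table = fold_enrichment(m, panel, ont)
        assert "GABRA1" not in table.genes()


class TestClassifyProfiles:
    def _toy(self, log2_rows, row_ids, panel):
        n = log2_rows.shape[1]
        ont = make_ontology(n)
        samples = [SampleRecord(f"R{j:03d}", "group", f"R{j:03d}")
                   for j in range(n)]
        m = ExpressionMatrix(row_ids, samples, log2_rows, "log2")
        table = fold_enrichment(m, panel, ont)
        return m, table

    def test_constant_low_gene_is_noise(self, panel):
        m, table = self._toy(np.full((1, 10), 3.0), ["GABRR1"], panel)
        assert classify_profiles(m, table)["GABRR1"] == "noise"

    def test_constant_high_gene_is_global_high(self, panel):
        m, table = self._toy(np.full((1, 10), 10.0), ["GABRA1"], panel)
        assert classify_profiles(m, table)["GABRA1"] == "global_high"

    def test_low_gene_with_hot_region_is_region_specific(self, panel):
        rows = np.full((1, 10), 3.0)
        rows[0, 4] = 10.0
        m, table = self._toy(rows, ["GABRA6"], panel)
        # enrichment oracle on the toy input: linear fold in the hot region
        linear = 2.0 ** rows[0]
        fold = linear[4] / linear.mean()
        assert fold >= 5.0
        assert classify_profiles(m, table)["GABRA6"] == "region_specific"


class TestCompositionMatrix:
    def test_rejects_bad_column_sum(self, panel):
        vals = np.full((19, 1), 1.0)
        with pytest.raises(ValueError, match="sums to"):
            CompositionMatrix(panel, [SampleRecord("s0")], vals)

    def test_rejects_out_of_range(self, panel):
        vals = np.zeros((19, 1))
        vals[0] = 120.0
        vals[1] = -20.0
        with pytest.raises(ValueError, match=r"\[0, 100\]"):
            CompositionMatrix(panel, [SampleRecord("s0")], vals)
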