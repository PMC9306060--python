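"""Bias-analysis tests: tail deltas, diagonal projection, decile binning,
fold changes, the KS implementation against oracles, and the planted-truth
behaviour of the fitted model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import ks_2samp

import polyadrift as pa
from polyadrift.bias import replicate_variability_report, technique_bias_report
from tests._oracles import ks_bruteforce_d, ks_p_series


def summary_frame(mean_tails: dict, rpm: dict | None = None, counts: int = 100):
    genes = sorted(mean_tails)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "library_id": "x",
            "read_count": counts,
            "rpm": [rpm[g] for g in genes] if rpm else 1.0,
            "mean_tail": [mean_tails[g] for g in genes],
            "passes_min_reads": True,
        }
    )


class TestTailDeltas:
    def test_identical_summaries_give_zero(self):
        s = summary_frame({"g1": 50.0, "g2": 80.0})
        assert (pa.tail_length_differences(s, s) == 0).all()

    def test_arithmetic(self):
        sel = summary_frame({"g1": 90.0})
        uns = summary_frame({"g1": 60.0})
        assert pa.tail_length_differences(sel, uns)["g1"] == pytest.approx(30.0)

    def test_only_passing_genes_enter(self):
        sel = summary_frame({"g1": 90.0, "g2": 50.0})
        sel.loc[sel["gene_id"] == "g2", "passes_min_reads"] = False
        uns = summary_frame({"g1": 60.0, "g2": 50.0})
        assert list(pa.tail_length_differences(sel, uns).index) == ["g1"]

    def test_no_shared_passing_genes_rejected(self):
        sel = summary_frame({"g1": 90.0})
        uns = summary_frame({"g2": 60.0})
        with pytest.raises(ValueError):
            pa.tail_length_differences(sel, uns)


class TestDiagonalProjection:
    def test_average_of_replicates(self):
        d1 = pd.Series({"g": 20.0})
        d2 = pd.Series({"g": 10.0})
        assert pa.diagonal_projection(d1, d2)["g"] == pytest.approx(15.0)

    def test_identity_on_the_diagonal(self):
        d = pd.Series({"a": 4.0, "b": -2.0})
        pd.testing.assert_series_equal(
            pa.diagonal_projection(d, d), d.rename("projected")
        )

    def test_rank_equivalent_to_orthogonal_projection(self):
        rng = np.random.default_rng(0)
        d1 = pd.Series(rng.normal(size=50), index=[f"g{i}" for i in range(50)])
        d2 = pd.Series(rng.normal(size=50), index=d1.index)
        avg = pa.diagonal_projection(d1, d2)
        orth = (d1 + d2) / np.sqrt(2.0)
        assert (avg.rank() == orth.rank()).all()


class TestDecileBins:
    def test_hundred_genes_ten_each(self):
        s = pd.Series(np.arange(100.0), index=[f"g{i:03d}" for i in range(100)])
        lab = pa.decile_bins(s)
        assert lab.value_counts().eq(10).all()

    def test_remainder_spread_and_coverage(self):
        s = pd.Series(np.arange(105.0), index=[f"g{i:03d}" for i in range(105)])
        lab = pa.decile_bins(s)
        sizes = lab.value_counts()
        assert set(sizes) <= {10, 11} and sizes.sum() == 105

    def test_extremal_gene_lands_in_decile_ten(self):
        rng = np.random.default_rng(1)
        s = pd.Series(rng.normal(size=57), index=[f"g{i}" for i in range(57)])
        lab = pa.decile_bins(s)
        assert lab[s.idxmax()] == 10
        assert lab[s.idxmin()] == 1

    def test_tied_values_break_by_gene_id(self):
        s = pd.Series(0.0, index=[f"g{i:02d}" for i in range(20)])
        lab = pa.decile_bins(s)
        assert (lab.sort_index().to_numpy() == np.repeat(np.arange(1, 11), 2)).all()

    def test_fewer_than_ten_rejected(self):
        with pytest.raises(ValueError):
            pa.decile_bins(pd.Series(np.arange(9.0), index=[f"g{i}" for i in range(9)]))


class TestFoldChange:
    def test_equal_rpm_gives_unit_fc(self):
        a = summary_frame({"g": 50.0}, rpm={"g": 123.0})
        fc = pa.rpm_fold_change(a, a)
        assert fc["fc"].iloc[0] == pytest.approx(1.0)
        assert fc["log2_fc"].iloc[0] == pytest.approx(0.0)

    def test_ratio_arithmetic_without_pseudocount(self):
        num = summary_frame({"g": 50.0}, rpm={"g": 200.0})
        den = summary_frame({"g": 50.0}, rpm={"g": 100.0})
        assert pa.rpm_fold_change(num, den)["fc"].iloc[0] == pytest.approx(2.0)

    def test_zero_rpm_excluded_without_pseudocount(self):
        num = summary_frame({"g": 50.0, "h": 10.0}, rpm={"g": 200.0, "h": 0.0})
        den = summary_frame({"g": 50.0, "h": 10.0}, rpm={"g": 100.0, "h": 5.0})
        fc = pa.rpm_fold_change(num, den, pseudocount_rpm=0.0)
        assert list(fc["gene_id"]) == ["g"]
        fc2 = pa.rpm_fold_change(num, den, pseudocount_rpm=1.0)
        assert len(fc2) == 2


class TestKsTwoSample:
    def test_identical_multisets_give_zero(self):
        r = pa.ks_two_sample([1, 2, 2, 3], [1, 2, 2, 3])
        assert r.statistic == 0.0 and r.p_value == pytest.approx(1.0)

    def test_disjoint_supports_give_one(self):
        r = pa.ks_two_sample([1, 2, 3], [4, 5, 6])
        assert r.statistic == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            pa.ks_two_sample([], [1.0])

    def test_matches_bruteforce_oracle_on_fixture(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=30), rng.normal(0.4, 1.2, size=40)
        r = pa.ks_two_sample(a, b)
        assert r.statistic == pytest.approx(ks_bruteforce_d(a, b), abs=0)
        assert r.p_value == pytest.approx(ks_p_series(r.statistic, 30, 40), abs=1e-8)

    def test_exact_p_matches_scipy_lattice_count(self):
        rng = np.random.default_rng(8)
        for n1, n2 in ((5, 7), (12, 9), (20, 30)):
            a, b = rng.normal(size=n1), rng.normal(0.3, 1.0, size=n2)
            ours = pa.ks_two_sample(a, b, method="exact")
            ref = ks_2samp(a, b, method="exact")
            assert ours.statistic == pytest.approx(ref.statistic, abs=1e-12)
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_statistic_matches_scipy_crosscheck(self):
        rng = np.random.default_rng(9)
        a, b = rng.exponential(size=85), rng.exponential(1.5, size=60)
        assert pa.ks_two_sample(a, b).statistic == pytest.approx(
            ks_2samp(a, b).statistic, abs=1e-14
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=st.lists(st.integers(-20, 20), min_size=1, max_size=30),
        b=st.lists(st.integers(-20, 20), min_size=1, max_size=30),
    )
    def test_bruteforce_agreement_property(self, a, b):
        r = pa.ks_two_sample(a, b)
        assert r.statistic == pytest.approx(ks_bruteforce_d(a, b), abs=0)
        assert 0.0 <= r.p_value <= 1.0


class TestReports:
    def _world(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i:03d}" for i in range(60)]
        deciles = pa.decile_bins(pd.Series(rng.normal(size=60), index=genes))
        fc = pd.DataFrame(
            {"gene_id": genes, "fc": np.exp(rng.normal(size=60))}
        )
        fc["log2_fc"] = np.log2(fc["fc"])
        return deciles, fc

    def test_technique_report_shapes(self):
        deciles, fc = self._world()
        cdf, ks = technique_bias_report(deciles, fc)
        assert set(cdf["group"]) == set(range(1, 11))
        assert ks.n1 == 6 and ks.n2 == 54
        # each decile's ECDF ends at 1
        assert (cdf.groupby("group")["ecdf"].max() == 1.0).all()

    def test_single_group_against_itself_is_null(self):
        deciles, fc = self._world()
        top = fc.loc[fc["gene_id"].isin(deciles[deciles == 10].index), "log2_fc"]
        r = pa.ks_two_sample(top, top)
        assert r.statistic == 0.0

    def test_replicate_report_identical_reps_give_null(self):
        deciles, _ = self._world()
        s = summary_frame(
            {g: 50.0 for g in deciles.index},
            rpm={g: 10.0 + i for i, g in enumerate(deciles.index)},
        )
        fc, cdf, ks = replicate_variability_report(s, s, deciles)
        assert (fc["fc"] == 1.0).all()
        assert ks.statistic == 0.0


class TestModelOnPlantedTruth:
    def test_planted_genes_shift_more_than_unimodal_background(self, study_run):
        """Planted bimodal genes' projected deltas exceed the unimodal
        median delta (selection strips their short-tail subpopulation)."""
        res = study_run["results"]
        truth = study_run["truth"]
        genes = study_run["genes"]
        planted = set(genes.loc[truth.variable_tail, "gene_id"])
        td = res.tail_deltas.set_index("gene_id")
        planted_in = td.index.intersection(planted)
        background = td.index.difference(planted)
        assert td.loc[planted_in, "projected"].min() > td.loc[background, "projected"].median()

    def test_direction_median_delta_positive(self, study_run):
        assert study_run["results"].median_projected_delta > 0

    def test_decile10_fold_change_depressed(self, study_run):
        res = study_run["results"]
        for sample in res.technique_fold_changes:
            fc = res.technique_fold_changes[sample].set_index("gene_id")["log2_fc"]
            top = fc.index.intersection(res.decile10_genes)
            rest = fc.index.difference(res.decile10_genes)
            assert fc.loc[top].median() < fc.loc[rest].median()

    def test_summary_renders(self, study_run):
        text = study_run["results"].summary()
        assert "decile 10" in text and "KS" in text

    def test_design_validation(self, study_run):
        design = study_run["design"]
        bad = pd.concat([design, design.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="unique"):
            pa.SelectionBiasModel(study_run["summaries"], bad)
        with pytest.raises(ValueError, match="2 samples"):
            pa.SelectionBiasModel(
                study_run["summaries"], design[design["sample_id"] == "A"]
            )
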