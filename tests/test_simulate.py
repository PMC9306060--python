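"""Simulator tests: capture model, annotation layout, planted-truth
recovery at the distribution level, and serialization round-trips."""

import numpy as np
import pandas as pd
import pytest

import polyadrift as pa
from polyadrift.io import read_reads_tsv, write_reads_tsv


@pytest.fixture(scope="module")
def cfg():
    return pa.CaptureConfig(depth=5000, seed=3)


class TestCaptureProbability:
    def test_below_splint_threshold_is_zero(self, cfg):
        assert pa.capture_probability(0.0, True, cfg) == 0.0
        assert pa.capture_probability(cfg.splint_min_a - 1e-9, False, cfg) == 0.0

    def test_logistic_midpoint_gives_half_base_capture(self, cfg):
        p = pa.capture_probability(cfg.selection_midpoint, True, cfg)
        assert p == pytest.approx(cfg.base_capture / 2)

    def test_saturates_at_base_capture(self, cfg):
        assert pa.capture_probability(1e4, True, cfg) == pytest.approx(cfg.base_capture)
        assert pa.capture_probability(cfg.splint_min_a, False, cfg) == cfg.base_capture

    @pytest.mark.parametrize("selected", [True, False])
    def test_monotone_nondecreasing_in_tail_length(self, selected, cfg):
        grid = np.linspace(0, 400, 2001)
        p = pa.capture_probability(grid, selected, cfg)
        assert (np.diff(p) >= -1e-15).all()

    def test_negative_tail_rejected(self, cfg):
        with pytest.raises(ValueError):
            pa.capture_probability(-1.0, True, cfg)


class TestAnnotation:
    def test_single_gene_degenerate_layout(self):
        g = pa.generate_annotation(1, seed=0)
        assert len(g) == 1
        assert (g["tx_start"] < g["tx_end"]).all()
        assert (g["cds_start"] >= g["tx_start"]).all()
        assert (g["cds_end"] <= g["tx_end"]).all()

    def test_default_layout_is_pairwise_disjoint(self):
        g = pa.generate_annotation(100, seed=4).sort_values("tx_start")
        assert (g["tx_start"].to_numpy()[1:] >= g["tx_end"].to_numpy()[:-1]).all()
        assert g["gene_id"].is_unique

    def test_overlap_fraction_produces_overlaps(self):
        g = pa.generate_annotation(200, seed=4, overlap_frac=0.3).sort_values("tx_start")
        assert (g["tx_start"].to_numpy()[1:] < g["tx_end"].to_numpy()[:-1]).any()

    def test_seeded_regeneration_is_identical(self, tmp_path):
        a = pa.generate_annotation(500, seed=11)
        b = pa.generate_annotation(500, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_impossible_layout_raises(self):
        with pytest.raises(ValueError, match="chrom_length"):
            pa.generate_annotation(1000, seed=0, chrom_length=10_000)


class TestTailDistribution:
    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            pa.TailDistribution((0.5, 0.6), (10, 100), (5, 5))

    def test_variable_flag_requires_mixture(self):
        genes = pa.generate_annotation(3, seed=0)
        with pytest.raises(ValueError, match="variable_tail"):
            pa.GroundTruth(
                genes=genes,
                abundance=np.full(3, 1 / 3),
                tails=[pa.TailDistribution((1.0,), (70.0,), (10.0,))] * 3,
                variable_tail=np.array([True, False, False]),
                three_prime_offset=np.zeros(3, dtype=int),
            )


@pytest.fixture(scope="module")
def world():
    genes = pa.generate_annotation(40, seed=3)
    truth = pa.make_ground_truth(genes, seed=3)
    return genes, truth


class TestSimulateLibrary:
    def test_splint_floor_in_both_modes(self, world, cfg):
        genes, truth = world
        for selected in (True, False):
            reads = pa.simulate_library(genes, truth, selected, cfg, "L")
            assert (reads["tail_true"] >= cfg.splint_min_a).all()

    def test_seed_determinism_byte_identical(self, world, cfg, tmp_path):
        genes, truth = world
        paths = []
        for tag in ("a", "b"):
            rng = np.random.default_rng(123)
            reads = pa.simulate_library(genes, truth, True, cfg, "L", rng=rng)
            p = tmp_path / f"{tag}.tsv"
            write_reads_tsv(reads, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_zero_truncation_reads_span_their_transcript(self, world):
        genes, truth = world
        cfg0 = pa.CaptureConfig(depth=2000, seed=5, truncation_rate=0.0)
        reads = pa.simulate_library(genes, truth, False, cfg0, "L")
        spans = genes.set_index("gene_id")
        expected = (
            spans["tx_end"].reindex(reads["gene_id_true"]).to_numpy()
            - spans["tx_start"].reindex(reads["gene_id_true"]).to_numpy()
            + truth.three_prime_offset[
                spans.index.get_indexer(reads["gene_id_true"])
            ]
        )
        assert (reads["read_length"].to_numpy() == expected).all()

    def test_empty_truth_rejected(self, world, cfg):
        genes, _ = world
        with pytest.raises(ValueError):
            pa.simulate_library(genes.iloc[:0], None, True, cfg, "L")

    def test_selection_off_equalizes_expected_gene_counts(self):
        """With a flat selection curve and no splint floor, selected and
        unselected libraries have equal per-gene count expectations
        (checked within 3 SE over 20 replicate pairs)."""
        genes = pa.generate_annotation(30, seed=9)
        truth = pa.make_ground_truth(genes, seed=9, bimodal_fraction=0.1)
        cfg0 = pa.CaptureConfig(
            depth=3000, seed=9, selection_slope=0.0, splint_min_a=0.0
        )
        n_rep = 20
        tot = {True: np.zeros(30), False: np.zeros(30)}
        sq = {True: np.zeros(30), False: np.zeros(30)}
        gids = genes["gene_id"]
        for rep in range(n_rep):
            for selected in (True, False):
                rng = np.random.default_rng(1000 + 2 * rep + selected)
                reads = pa.simulate_library(genes, truth, selected, cfg0, "L", rng=rng)
                c = reads["gene_id_true"].value_counts().reindex(gids).fillna(0).to_numpy()
                tot[selected] += c
                sq[selected] += c**2
        mean_s, mean_u = tot[True] / n_rep, tot[False] / n_rep
        var_s = sq[True] / n_rep - mean_s**2
        var_u = sq[False] / n_rep - mean_u**2
        se = np.sqrt((var_s + var_u) / n_rep)
        z = np.abs(mean_s - mean_u) / np.maximum(se, 1e-9)
        assert (z < 3).mean() > 0.9
        assert abs(tot[True].sum() - tot[False].sum()) < 3 * np.sqrt(
            tot[True].sum() + tot[False].sum()
        )

    def test_post_selection_mixture_reweighting_matches_analytic(self):
        """Selected libraries re-weight a bimodal gene's components as
        w'_i ∝ w_i * E[capture | component i]; checked by classifying
        called tails against the analytic weights within Monte-Carlo error,
        and the selected mean tail exceeds the unselected one."""
        genes = pa.generate_annotation(1, seed=2)
        dist = pa.TailDistribution((0.5, 0.5), (20.0, 120.0), (6.0, 10.0))
        truth = pa.GroundTruth(
            genes=genes,
            abundance=np.array([1.0]),
            tails=[dist],
            variable_tail=np.array([True]),
            three_prime_offset=np.zeros(1, dtype=int),
        )
        cfg = pa.CaptureConfig(
            depth=20_000, seed=4, selection_midpoint=60.0, splint_min_a=0.0,
            tail_call_fail_rate=0.0,
        )
        sel = pa.simulate_library(genes, truth, True, cfg, "S")
        uns = pa.simulate_library(genes, truth, False, cfg, "U")
        assert len(sel) > 500 and len(uns) > 500
        assert sel["tail_called"].mean() > uns["tail_called"].mean()

        caps = [
            pa.expected_capture(pa.TailDistribution((1.0,), (m,), (s,)), True, cfg)
            for m, s in zip(dist.means, dist.sds)
        ]
        w = np.array(dist.weights) * np.array(caps)
        w_short = w[0] / w.sum()
        observed_short = (sel["tail_true"] < 70).mean()
        se = np.sqrt(w_short * (1 - w_short) / len(sel))
        assert abs(observed_short - w_short) < 4 * se


class TestReadsTsv:
    def test_header_only_for_zero_reads(self, tmp_path):
        reads = pa.simulate_library(
            pa.generate_annotation(1, seed=0),
            pa.make_ground_truth(pa.generate_annotation(1, seed=0), seed=0),
            True,
            pa.CaptureConfig(depth=1, seed=0),
            "L",
        ).iloc[:0]
        p = tmp_path / "empty.tsv"
        write_reads_tsv(reads, p)
        lines = p.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("read_id\t")

    def test_roundtrip_preserves_records_and_missing_tails(self, tmp_path):
        genes = pa.generate_annotation(5, seed=6)
        truth = pa.make_ground_truth(genes, seed=6)
        cfg = pa.CaptureConfig(depth=200, seed=6, tail_call_fail_rate=0.0)
        reads = pa.simulate_library(genes, truth, False, cfg, "L").head(10)
        reads.loc[reads.index[3], "tail_called"] = np.nan
        p = tmp_path / "reads.tsv"
        write_reads_tsv(reads, p)
        assert "\tNA\t" in p.read_text()
        back = read_reads_tsv(p)
        assert back["tail_called"].isna().sum() == 1
        pd.testing.assert_series_equal(
            back["tail_called"].round(3), reads["tail_called"].round(3),
            check_index=False, check_names=False,
        )
        assert (back["start"].to_numpy() == reads["start"].to_numpy()).all()
        assert (back["unique_best"].to_numpy() == reads["unique_best"].to_numpy()).all()


def test_marginal_tail_distribution_shifts_up_under_selection(study_run):
    """Stochastic dominance: the selected library's called-tail marginal sits
    to the right of the unselected one (one-sided two-sample test)."""
    from scipy.stats import mannwhitneyu

    sel = study_run["reads"]["Selected-1"]["tail_called"].dropna().to_numpy()[:10_000]
    uns = study_run["reads"]["Unselected-1"]["tail_called"].dropna().to_numpy()[:10_000]
    res = mannwhitneyu(sel, uns, alternative="greater")
    assert res.pvalue < 1e-6
    assert np.median(sel) > np.median(uns)
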