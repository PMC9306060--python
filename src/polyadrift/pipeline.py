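"""End-to-end orchestration: simulate (optional) -> assign -> summarize ->
bias + complexity + read-length reports, with a provenance manifest.

The configuration is a flat mapping with per-stage sections; every output
TSV is re-derivable from the manifest (parameters, seeds, versions) alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assign import assign_reads
from .bias import SelectionBiasModel
from .complexity import (
    identified_genes,
    overlap_table,
    saturation_subsample,
    unidentified_fraction_curve,
    unique_genes_by_biotype,
)
from .io import (
    read_annotation,
    read_design,
    read_reads_table,
    write_annotation,
    write_reads_tsv,
    write_summary_tsv,
)
from .readlength import paired_length_comparison, read_length_cdf, spanning_cds_classification
from .simulate import (
    CaptureConfig,
    default_design,
    generate_annotation,
    make_ground_truth,
    simulate_experiment,
)
from .summaries import summarize_experiment

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "default_demo_config", "simulate_to_dir"]


def default_demo_config() -> dict:
    """Small self-contained demonstration configuration (runs in seconds)."""
    return {
        "seed": 0,
        "simulate": {
            "n_genes": 150,
            "depth": 20_000.0,
            "bimodal_fraction": 0.10,
        },
        "assign": {"min_overlap_frac": 0.5},
        "summarize": {"min_reads": 80},
        "bias": {"pseudocount_rpm": 0.0},
        "complexity": {"n_repeats": 25, "percents": list(range(5, 101, 5))},
        "readlen": {},
    }


def _capture_config(sim_cfg: dict, seed: int) -> CaptureConfig:
    fields = {
        k: sim_cfg[k]
        for k in (
            "splint_min_a", "selection_midpoint", "selection_slope", "base_capture",
            "depth", "tail_call_sd_frac", "tail_call_fail_rate", "truncation_rate",
            "multimap_rate",
        )
        if k in sim_cfg
    }
    return CaptureConfig(seed=seed, **fields)


def simulate_to_dir(config: dict, out_dir: Path, seed: int):
    """Run the simulation stage; writes annotation, design and read TSVs."""
    sim = dict(config.get("simulate", {}))
    n_genes = int(sim.get("n_genes", 2000))
    genes = generate_annotation(
        n_genes,
        seed,
        **{k: sim[k] for k in ("overlap_frac", "single_transcript_frac", "mean_tx_len", "intergenic_mean") if k in sim},
    )
    truth = make_ground_truth(
        genes,
        seed,
        **{
            k: sim[k]
            for k in (
                "bimodal_fraction", "abundance_sigma", "bimodal_short_weight",
                "bimodal_modes", "offset_fraction",
            )
            if k in sim
        },
    )
    cap = _capture_config(sim, seed)
    design = default_design()
    depths = sim.get("depths")
    reads = simulate_experiment(genes, truth, cap, design, seed=seed, depths=depths)

    write_annotation(genes, out_dir / "annotation.bed")
    design.to_csv(out_dir / "design.tsv", sep="\t", index=False)
    for lib, df in reads.items():
        write_reads_tsv(df, out_dir / f"reads_{lib}.tsv")
    truth_table = truth.genes[["gene_id"]].copy()
    truth_table["abundance"] = truth.abundance
    truth_table["variable_tail"] = truth.variable_tail
    truth_table["true_mean_tail"] = [t.mean() for t in truth.tails]
    truth_table.to_csv(out_dir / "ground_truth.tsv", sep="\t", index=False)
    return genes, truth, design, reads


def run_pipeline(config: dict, out_dir, seed: int | None = None) -> Path:
    """Execute the full workflow; returns the report directory.

    ``config`` either contains a ``simulate`` section or names real inputs
    (``reads`` mapping library_id -> path, ``annotation``, ``design``
    paths). Any stage failure aborts with the stage name; the bias stage is
    skipped with a log message when the design lacks the paired libraries
    it needs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)

    stage = "simulate"
    try:
        if "simulate" in config:
            genes, truth, design, reads = simulate_to_dir(config, out_dir, seed)
        else:
            genes = read_annotation(config["annotation"])
            design = read_design(config["design"])
            reads = {lib: read_reads_table(p) for lib, p in config["reads"].items()}

        stage = "assign"
        min_ov = float(config.get("assign", {}).get("min_overlap_frac", 0.5))
        assigned = {}
        discard_log = {}
        for lib, df in reads.items():
            res = assign_reads(df, genes, min_overlap_frac=min_ov)
            assigned[lib] = res.assigned
            discard_log[lib] = res.discarded
            write_reads_tsv(res.assigned, out_dir / f"assigned_{lib}.tsv")
            logger.info("library %s: discards %s", lib, res.discarded)

        stage = "summarize"
        min_reads = int(config.get("summarize", {}).get("min_reads", 80))
        summaries = summarize_experiment(assigned, min_reads=min_reads)
        for lib, s in summaries.items():
            write_summary_tsv(s, out_dir / f"summary_{lib}.tsv")

        stage = "bias"
        bias_outputs = {}
        techniques = design.groupby("sample_id")["technique"].nunique()
        if (techniques >= 2).sum() >= 2:
            model = SelectionBiasModel(
                summaries, design,
                pseudocount_rpm=float(config.get("bias", {}).get("pseudocount_rpm", 0.0)),
            )
            results = model.fit()
            results.tail_deltas.to_csv(out_dir / "tail_deltas.tsv", sep="\t", index=False)
            fc_rows = []
            for sample, fc in results.technique_fold_changes.items():
                fc = fc.copy()
                fc.insert(0, "comparison", "technique")
                fc.insert(1, "sample_id", sample)
                fc_rows.append(fc)
            for sample, fc in results.replicate_fold_changes.items():
                fc = fc.copy()
                fc.insert(0, "comparison", "replicate")
                fc.insert(1, "sample_id", sample)
                fc_rows.append(fc)
            pd.concat(fc_rows, ignore_index=True).to_csv(
                out_dir / "fold_changes.tsv", sep="\t", index=False
            )
            ks_rows = [
                {
                    "comparison": comp, "sample_id": sample, "statistic": ks.statistic,
                    "p_value": ks.p_value, "n1": ks.n1, "n2": ks.n2,
                }
                for comp, d in (("technique", results.technique_ks), ("replicate", results.replicate_ks))
                for sample, ks in d.items()
            ]
            pd.DataFrame(ks_rows).to_csv(out_dir / "ks_results.tsv", sep="\t", index=False)
            pd.concat(
                [t.assign(sample_id=s) for s, t in results.technique_cdf.items()],
                ignore_index=True,
            ).to_csv(out_dir / "technique_cdf.tsv", sep="\t", index=False)
            (out_dir / "bias_summary.txt").write_text(results.summary() + "\n")
            bias_outputs = {"median_projected_delta": results.median_projected_delta}
        else:
            logger.warning("bias stage skipped: design lacks >=2 samples with both techniques")

        stage = "complexity"
        comp_cfg = config.get("complexity", {})
        pd.DataFrame(
            [
                {"library_id": lib, **unique_genes_by_biotype(s, genes)}
                for lib, s in summaries.items()
            ]
        ).to_csv(out_dir / "biotype_counts.tsv", sep="\t", index=False)
        sat = pd.concat(
            [
                saturation_subsample(
                    df,
                    n_repeats=int(comp_cfg.get("n_repeats", 100)),
                    seed=seed,
                    percents=comp_cfg.get("percents"),
                    library_id=lib,
                )
                for lib, df in assigned.items()
            ],
            ignore_index=True,
        )
        sat.to_csv(out_dir / "saturation.tsv", sep="\t", index=False)
        if len(summaries) >= 2:
            overlap_table({lib: identified_genes(s) for lib, s in summaries.items()}).to_csv(
                out_dir / "overlap.tsv", sep="\t", index=False
            )
            unid_rows = []
            libs = sorted(summaries)
            for x in libs:
                for y in libs:
                    if x == y:
                        continue
                    curve = unidentified_fraction_curve(summaries[x], summaries[y])
                    curve.insert(0, "x_library", x)
                    curve.insert(1, "y_library", y)
                    unid_rows.append(curve)
            pd.concat(unid_rows, ignore_index=True).to_csv(
                out_dir / "unidentified.tsv", sep="\t", index=False
            )

        stage = "readlen"
        cdf_rows, means = [], {}
        for lib, df in reads.items():
            table, mean = read_length_cdf(df)
            table.insert(0, "library_id", lib)
            cdf_rows.append(table)
            means[lib] = mean
        pd.concat(cdf_rows, ignore_index=True).to_csv(
            out_dir / "length_cdf.tsv", sep="\t", index=False
        )
        span_rows = []
        for lib, df in assigned.items():
            table = spanning_cds_classification(df, genes)
            table.insert(0, "library_id", lib)
            span_rows.append(table)
        pd.concat(span_rows, ignore_index=True).to_csv(
            out_dir / "spanning.tsv", sep="\t", index=False
        )
        pairing = [
            (sel, uns)
            for _, sel, uns in _sample_pairs(design)
        ]
        paired = None
        if len(pairing) >= 2:
            paired = paired_length_comparison(means, pairing)
            pd.DataFrame(
                [
                    {
                        "statistic": paired.statistic, "p_value": paired.p_value,
                        "n_pairs": paired.n_pairs, "mean_difference": paired.mean_difference,
                    }
                ]
            ).to_csv(out_dir / "paired_test.tsv", sep="\t", index=False)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest = {
        "polyadrift_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": seed,
        "config": _jsonable(config),
        "libraries": sorted(reads),
        "discarded_reads": discard_log,
        "mean_read_length": means,
        "bias": bias_outputs,
        "outputs": sorted(p.name for p in out_dir.iterdir() if p.suffix in {".tsv", ".txt", ".bed"}),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out_dir


def _sample_pairs(design: pd.DataFrame):
    pairs = []
    for sample, grp in design.groupby("sample_id", sort=True):
        sel = grp[grp["technique"] == "selected"].sort_values("replicate")
        uns = grp[grp["technique"] == "unselected"].sort_values("replicate")
        if len(sel) and len(uns):
            pairs.append((sample, sel["library_id"].iloc[0], uns["library_id"].iloc[0]))
    return pairs


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, range)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
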