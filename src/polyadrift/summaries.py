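"""Per-gene, per-library summary statistics and depth normalization."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "summarize_library",
    "compute_rpm",
    "apply_min_reads_filter",
    "pairwise_gene_correlation",
    "summarize_experiment",
]

SUMMARY_COLUMNS = [
    "gene_id",
    "library_id",
    "read_count",
    "rpm",
    "mean_read_length",
    "sd_read_length",
    "mean_tail",
    "sd_tail",
    "passes_min_reads",
]


def summarize_library(assigned: pd.DataFrame, library_id: str | None = None) -> pd.DataFrame:
    """Collapse assigned reads of one library into per-gene summaries.

    Means are arithmetic; SDs are sample SDs (n-1) and are NaN for
    single-read genes. Raises on reads from more than one library.
    """
    libs = assigned["library_id"].unique()
    if len(libs) > 1:
        raise ValueError(f"reads from mixed libraries: {sorted(libs)}")
    if library_id is None:
        library_id = str(libs[0]) if len(libs) else "unknown"
    if assigned["gene_id"].isna().any() or assigned["tail_called"].isna().any():
        raise ValueError("summarize_library requires assigned reads with tail calls")

    grp = assigned.groupby("gene_id", sort=True)
    out = pd.DataFrame(
        {
            "read_count": grp.size(),
            "mean_read_length": grp["read_length"].mean(),
            "sd_read_length": grp["read_length"].std(ddof=1),
            "mean_tail": grp["tail_called"].mean(),
            "sd_tail": grp["tail_called"].std(ddof=1),
        }
    )
    if "mapq" in assigned.columns:
        out["mean_mapq"] = grp["mapq"].mean()
        out["sd_mapq"] = grp["mapq"].std(ddof=1)
    out.insert(0, "library_id", library_id)
    out = out.reset_index()
    return out


def compute_rpm(summaries: pd.DataFrame) -> pd.DataFrame:
    """Reads Per gene per Million: count / (library assigned depth) * 1e6.

    The denominator is the total assigned-read count of the library, which
    keeps RPM comparable across selected/unselected libraries despite
    differing non-mRNA content.
    """
    total = summaries["read_count"].sum()
    if total <= 0:
        raise ValueError("library has zero assigned reads")
    out = summaries.copy()
    out["rpm"] = out["read_count"] / total * 1e6
    return out


def apply_min_reads_filter(summaries: pd.DataFrame, min_reads: int = 80) -> pd.DataFrame:
    """Flag genes with ``read_count >= min_reads`` (boundary inclusive);
    downstream tail-length analyses use only passing genes."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    out = summaries.copy()
    out["passes_min_reads"] = out["read_count"] >= min_reads
    return out


def summarize_experiment(
    assigned: dict[str, pd.DataFrame], min_reads: int = 80
) -> dict[str, pd.DataFrame]:
    """summarize + RPM + min-reads flag for every library."""
    return {
        lib: apply_min_reads_filter(compute_rpm(summarize_library(df, lib)), min_reads)
        for lib, df in assigned.items()
    }


def pairwise_gene_correlation(x: pd.DataFrame, y: pd.DataFrame, field: str) -> float:
    """Spearman rank correlation of a per-gene field across two libraries,
    on the intersection of their gene sets (ties get average ranks)."""
    if field not in {"mean_read_length", "mean_tail", "rpm", "read_count"}:
        raise ValueError(f"unsupported field {field!r}")
    merged = x.set_index("gene_id")[[field]].join(
        y.set_index("gene_id")[[field]], how="inner", lsuffix="_x", rsuffix="_y"
    )
    merged = merged.dropna()
    if len(merged) < 3:
        raise ValueError("need >= 3 shared genes for a rank correlation")
    rho = spearmanr(merged.iloc[:, 0], merged.iloc[:, 1]).statistic
    return float(rho)
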