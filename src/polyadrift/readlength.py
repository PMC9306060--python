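"""Read-length quality analyses: length ECDFs, spanning-CDS
classification stratified by CDS length, and the paired selected-vs-
unselected comparison of library mean lengths."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ttest_rel

logger = logging.getLogger(__name__)

__all__ = [
    "read_length_cdf",
    "spanning_cds_classification",
    "paired_length_comparison",
    "PairedTestResult",
]


def read_length_cdf(reads: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """ECDF of read lengths plus the mean length.

    Returns a (table, mean) pair; the table has one row per distinct
    length with the right-continuous ECDF value, reaching 1 at the maximum
    observed length.
    """
    if len(reads) == 0:
        raise ValueError("no reads")
    lengths = np.sort(reads["read_length"].to_numpy())
    uniq, counts = np.unique(lengths, return_counts=True)
    ecdf = np.cumsum(counts) / len(lengths)
    table = pd.DataFrame({"read_length": uniq, "ecdf": ecdf})
    return table, float(lengths.mean())


def _quintile_edges(values: np.ndarray) -> np.ndarray:
    edges = np.quantile(values, [0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
    edges[-1] = edges[-1] + 1  # half-open top bin keeps the max inside
    return np.unique(edges)


def spanning_cds_classification(
    assigned: pd.DataFrame,
    genes: pd.DataFrame,
    bins=None,
    span_slack: int = 0,
) -> pd.DataFrame:
    """Percent of CDS-spanning reads per gene, aggregated in CDS-length bins.

    Only single-transcript protein-coding genes enter; a read spans when its
    genomic interval contains the annotated CDS
    (``start <= cds_start + slack`` and ``end >= cds_end - slack``). Bins
    default to quintiles of the observed CDS lengths; genes falling outside
    explicit bins are dropped with a log note.
    """
    g = genes[(genes["n_transcripts"] == 1) & (genes["cds_end"] > genes["cds_start"])]
    g = g.set_index("gene_id")
    sub = assigned[assigned["gene_id"].isin(g.index)]
    if len(sub) == 0:
        raise ValueError("no reads on single-transcript coding genes")
    cds_start = g["cds_start"].reindex(sub["gene_id"]).to_numpy()
    cds_end = g["cds_end"].reindex(sub["gene_id"]).to_numpy()
    spans = (sub["start"].to_numpy() <= cds_start + span_slack) & (
        sub["end"].to_numpy() >= cds_end - span_slack
    )
    per_gene = (
        pd.DataFrame({"gene_id": sub["gene_id"].to_numpy(), "spanning": spans})
        .groupby("gene_id")
        .agg(n_reads=("spanning", "size"), pct=("spanning", lambda s: 100.0 * s.mean()))
    )
    cds_len = (g["cds_end"] - g["cds_start"]).reindex(per_gene.index)

    edges = _quintile_edges(cds_len.to_numpy()) if bins is None else np.asarray(bins, dtype=float)
    labels = pd.cut(cds_len, edges, right=False, include_lowest=True)
    outside = labels.isna()
    if outside.any():
        logger.info("spanning analysis: %d genes outside the CDS-length bins", int(outside.sum()))
    per_gene = per_gene[~outside.to_numpy()]
    labels = labels[~outside]

    rows = []
    for interval in labels.cat.categories:
        mask = (labels == interval).to_numpy()
        if not mask.any():
            continue
        rows.append(
            {
                "cds_bin_left": interval.left,
                "cds_bin_right": interval.right,
                "genes": int(mask.sum()),
                "n_reads": int(per_gene["n_reads"].to_numpy()[mask].sum()),
                "percent_spanning": float(per_gene["pct"].to_numpy()[mask].mean()),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    p_value: float
    n_pairs: int
    mean_difference: float


def paired_length_comparison(
    per_library_means: dict[str, float], pairing: list[tuple[str, str]]
) -> PairedTestResult:
    """Two-sided paired t-test on per-library mean read lengths.

    ``pairing`` lists (selected, unselected) library ids. Degenerate
    variance conventions: all differences zero -> t = 0, p = 1; equal
    nonzero differences -> t = +/-inf, p = 0.
    """
    if len(pairing) < 2:
        raise ValueError("need >= 2 library pairs")
    a = np.asarray([per_library_means[s] for s, _ in pairing], dtype=float)
    b = np.asarray([per_library_means[u] for _, u in pairing], dtype=float)
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            return PairedTestResult(0.0, 1.0, len(pairing), 0.0)
        return PairedTestResult(float(np.sign(diff.mean()) * np.inf), 0.0, len(pairing), float(diff.mean()))
    t = ttest_rel(a, b)
    return PairedTestResult(float(t.statistic), float(t.pvalue), len(pairing), float(diff.mean()))
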