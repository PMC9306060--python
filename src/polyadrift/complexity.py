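"""Transcriptome-complexity analyses: biotype counts, saturation
subsampling, multi-library overlap tables and unidentified-fraction
curves."""

from __future__ import annotations

import logging
import zlib

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "unique_genes_by_biotype",
    "saturation_subsample",
    "overlap_table",
    "unidentified_fraction_curve",
    "identified_genes",
]


def identified_genes(summaries: pd.DataFrame) -> set[str]:
    """Genes with one or more reads in the library."""
    return set(summaries.loc[summaries["read_count"] >= 1, "gene_id"])


def unique_genes_by_biotype(summaries: pd.DataFrame, annotation: pd.DataFrame) -> dict[str, int]:
    """Count identified genes (>= 1 read) per biotype.

    Every biotype present in the annotation appears in the result, zero or
    not; a summarized gene missing from the annotation is an error.
    """
    bt = annotation.set_index("gene_id")["biotype"]
    idents = summaries.loc[summaries["read_count"] >= 1, "gene_id"]
    unknown = set(idents) - set(bt.index)
    if unknown:
        raise ValueError(f"summarized genes absent from annotation: {sorted(unknown)[:5]}")
    counts = {b: 0 for b in pd.unique(annotation["biotype"])}
    for b, k in bt.loc[idents].value_counts().items():
        counts[b] = int(k)
    return counts


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5))


def saturation_subsample(
    assigned: pd.DataFrame,
    n_repeats: int = 100,
    seed: int = 0,
    percents=None,
    library_id: str | None = None,
) -> pd.DataFrame:
    """Unique-gene saturation curve by repeated subsampling without
    replacement.

    For each integer percent p, draw ``n_repeats`` subsamples of size
    round(p/100 * N) and record mean and SD of the unique gene count; at
    p = 100 the subsample is the full read set (SD exactly 0). Each
    (library, percent) pair gets its own child random stream, so curves are
    reproducible point-by-point and repeats are independent.
    """
    n = len(assigned)
    if n < 100:
        raise ValueError(f"need >= 100 reads for a percent grid, got {n}")
    if library_id is None:
        library_id = str(assigned["library_id"].iloc[0])
    if percents is None:
        percents = range(1, 101)
    codes = pd.factorize(assigned["gene_id"])[0]
    n_genes_full = int(codes.max()) + 1
    lib_key = zlib.crc32(library_id.encode())

    rows = []
    for p in percents:
        if not (1 <= p <= 100):
            raise ValueError("percents must lie in 1..100")
        m = _round_half_away(p / 100 * n)
        if p == 100 or m >= n:
            rows.append((library_id, p, float(len(np.unique(codes))), 0.0, n_repeats))
            continue
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), lib_key, int(p)]))
        uniq = np.empty(n_repeats)
        for r in range(n_repeats):
            take = rng.choice(n, size=m, replace=False)
            seen = np.zeros(n_genes_full, dtype=bool)
            seen[codes[take]] = True
            uniq[r] = seen.sum()
        rows.append((library_id, p, float(uniq.mean()), float(uniq.std(ddof=1)), n_repeats))
    return pd.DataFrame(
        rows, columns=["library_id", "percent", "mean_unique_genes", "sd_unique_genes", "n_repeats"]
    )


def overlap_table(identified_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Exact-subset gene counts over all nonempty library subsets.

    The signature column marks membership per library (sorted ids,
    '1'/'0'); subset counts sum to the size of the union.
    """
    if len(identified_sets) < 2:
        raise ValueError("need >= 2 libraries for an overlap table")
    libs = sorted(identified_sets)
    union = set().union(*identified_sets.values())
    sig_counts: dict[str, int] = {}
    for g in union:
        sig = "".join("1" if g in identified_sets[l] else "0" for l in libs)
        sig_counts[sig] = sig_counts.get(sig, 0) + 1
    rows = sorted(sig_counts.items(), key=lambda kv: (-kv[0].count("1"), kv[0]), reverse=False)
    out = pd.DataFrame(rows, columns=["signature", "count"])
    out.attrs["libraries"] = libs
    return out


def unidentified_fraction_curve(
    x_lib: pd.DataFrame, y_lib: pd.DataFrame, x_max: int | None = None
) -> pd.DataFrame:
    """Fraction of genes with more than X reads in the x library that have
    zero reads in the y library, for X = 0..x_max.

    The curve is truncated (with a log note) at the first X whose
    denominator is empty. The attribute ``first_zero_x`` records the
    smallest X at which the fraction reaches zero, or None.
    """
    cx = x_lib.set_index("gene_id")["read_count"]
    cx = cx[cx >= 1]
    if len(cx) == 0:
        raise ValueError("x library identifies no genes")
    identified_y = identified_genes(y_lib)
    if x_max is None:
        x_max = int(cx.max())
    rows = []
    for X in range(0, x_max + 1):
        denom = cx[cx > X]
        if len(denom) == 0:
            logger.info("unidentified-fraction curve truncated at X=%d (empty denominator)", X)
            break
        missing = sum(1 for g in denom.index if g not in identified_y)
        rows.append((X, len(denom), missing / len(denom)))
    out = pd.DataFrame(rows, columns=["x_threshold", "n_genes", "fraction_unidentified"])
    zero = out.loc[out["fraction_unidentified"] == 0.0, "x_threshold"]
    out.attrs["first_zero_x"] = int(zero.iloc[0]) if len(zero) else None
    return out
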