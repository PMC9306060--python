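"""Gene assignment for long mapped reads.

Each read is assigned by two complementary strand-aware methods:

1. **overlap** — the gene whose transcript span shares the most nucleotides
   with the read, provided the overlap covers at least ``min_overlap_frac``
   of the read length (ties are ambiguous and yield no call);
2. **five_prime_end** — fallback for truncated/abortive reads: the unique
   gene whose span contains the read's 5'-most nucleotide.

Reads failing both, or lacking a tail-length call, are discarded with a
tallied reason (the completeness filter: mapping + gene + tail call are all
required downstream).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AssignmentResult",
    "filter_unique_best",
    "assign_by_overlap",
    "assign_by_five_prime_end",
    "combine_assignments",
    "assign_reads",
]


@dataclass
class AssignmentResult:
    """Assigned reads plus discard tallies; assigned + discarded = input."""

    assigned: pd.DataFrame
    discarded: dict[str, int] = field(
        default_factory=lambda: {"not_unique_best": 0, "no_gene": 0, "no_tail_call": 0}
    )

    @property
    def n_input(self) -> int:
        return len(self.assigned) + sum(self.discarded.values())


def filter_unique_best(reads: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Keep reads with a unique best mapping position; stable order.

    Returns (kept, n_discarded)."""
    mask = reads["unique_best"].astype(bool).to_numpy()
    return reads.loc[mask].reset_index(drop=True), int((~mask).sum())


class _StrandIndex:
    """Sorted interval index for one (chrom, strand) gene group.

    Genes sorted by start; a cumulative max of ends allows a narrow
    candidate window [lo, hi) per query interval even with overlaps.
    """

    def __init__(self, genes: pd.DataFrame):
        order = np.lexsort((genes["gene_id"].to_numpy(), genes["tx_start"].to_numpy()))
        self.starts = genes["tx_start"].to_numpy()[order]
        self.ends = genes["tx_end"].to_numpy()[order]
        self.ids = genes["gene_id"].to_numpy()[order]
        self.cummax_end = np.maximum.accumulate(self.ends)

    def window(self, qstart: np.ndarray, qend: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        hi = np.searchsorted(self.starts, qend, side="left")
        lo = np.searchsorted(self.cummax_end, qstart, side="right")
        return lo, hi


def _build_indexes(genes: pd.DataFrame) -> dict[tuple[str, str], _StrandIndex]:
    if len(genes) == 0:
        raise ValueError("empty annotation")
    return {
        key: _StrandIndex(grp) for key, grp in genes.groupby(["chrom", "strand"], sort=True)
    }


def _best_overlap(idx: _StrandIndex, start: int, end: int, lo: int, hi: int):
    """(gene_id, overlap) with max overlap in window; ties -> (None, best)."""
    best_id, best, tied = None, 0, False
    for j in range(lo, hi):
        ov = min(end, idx.ends[j]) - max(start, idx.starts[j])
        if ov <= 0:
            continue
        if ov > best:
            best_id, best, tied = idx.ids[j], ov, False
        elif ov == best and best > 0:
            tied = True
    if tied:
        return None, best
    return best_id, best


def assign_by_overlap(
    read, genes: pd.DataFrame, min_overlap_frac: float = 0.5
) -> str | None:
    """Largest same-strand transcript-span overlap covering at least
    ``min_overlap_frac`` of the read length; ties are ambiguous (None)."""
    idx = _build_indexes(genes).get((read["chrom"], read["strand"]))
    if idx is None:
        return None
    lo, hi = idx.window(np.asarray([read["start"]]), np.asarray([read["end"]]))
    gid, ov = _best_overlap(idx, read["start"], read["end"], int(lo[0]), int(hi[0]))
    if gid is None or ov < min_overlap_frac * read["read_length"]:
        return None
    return gid


def _five_prime_pos(start: np.ndarray, end: np.ndarray, strand: np.ndarray) -> np.ndarray:
    # dRNA-seq is stranded: the 5'-most nucleotide is `start` on +, `end-1` on -
    return np.where(strand == "+", start, end - 1)


def assign_by_five_prime_end(read, genes: pd.DataFrame) -> str | None:
    """Unique same-strand gene containing the read's 5'-most nucleotide;
    zero or multiple containing genes yield None."""
    idx = _build_indexes(genes).get((read["chrom"], read["strand"]))
    if idx is None:
        return None
    pos = int(_five_prime_pos(np.asarray([read["start"]]), np.asarray([read["end"]]), np.asarray([read["strand"]]))[0])
    lo, hi = idx.window(np.asarray([pos]), np.asarray([pos + 1]))
    hits = [idx.ids[j] for j in range(int(lo[0]), int(hi[0])) if idx.starts[j] <= pos < idx.ends[j]]
    return hits[0] if len(hits) == 1 else None


def _assign_group(
    idx: _StrandIndex,
    start: np.ndarray,
    end: np.ndarray,
    read_length: np.ndarray,
    min_overlap_frac: float,
    five_prime: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized dual assignment for one (chrom, strand) read group."""
    n = len(start)
    gene = np.full(n, None, dtype=object)
    method = np.full(n, "unassigned", dtype=object)

    lo, hi = idx.window(start, end)
    width = hi - lo
    # fast path: at most one candidate gene
    single = width == 1
    if single.any():
        j = lo[single]
        ov = np.minimum(end[single], idx.ends[j]) - np.maximum(start[single], idx.starts[j])
        ok = (ov > 0) & (ov >= min_overlap_frac * read_length[single])
        tgt = np.nonzero(single)[0][ok]
        gene[tgt] = idx.ids[j[ok]]
        method[tgt] = "overlap"
    for i in np.nonzero(width > 1)[0]:
        gid, ov = _best_overlap(idx, start[i], end[i], int(lo[i]), int(hi[i]))
        if gid is not None and ov >= min_overlap_frac * read_length[i]:
            gene[i] = gid
            method[i] = "overlap"

    # 5'-end fallback for the remainder
    rest = np.nonzero(gene == None)[0]  # noqa: E711  (elementwise on object array)
    if len(rest):
        pos = five_prime[rest]
        plo, phi = idx.window(pos, pos + 1)
        pw = phi - plo
        one = pw == 1
        if one.any():
            j = plo[one]
            contains = (idx.starts[j] <= pos[one]) & (pos[one] < idx.ends[j])
            tgt = rest[np.nonzero(one)[0][contains]]
            gene[tgt] = idx.ids[j[contains]]
            method[tgt] = "five_prime_end"
        for k in np.nonzero(pw > 1)[0]:
            p = pos[k]
            hits = [
                idx.ids[j]
                for j in range(int(plo[k]), int(phi[k]))
                if idx.starts[j] <= p < idx.ends[j]
            ]
            if len(hits) == 1:
                gene[rest[k]] = hits[0]
                method[rest[k]] = "five_prime_end"
    return gene, method


def combine_assignments(
    reads: pd.DataFrame, genes: pd.DataFrame, min_overlap_frac: float = 0.5
) -> AssignmentResult:
    """Dual assignment (overlap, then 5'-end fallback) plus the completeness
    filter. Input reads must already have passed the unique-best filter.

    Discard reasons: ``no_gene`` (both methods failed) and ``no_tail_call``
    (gene found but the tail caller returned nothing).
    """
    indexes = _build_indexes(genes)
    reads = reads.reset_index(drop=True)
    n = len(reads)
    gene = np.full(n, None, dtype=object)
    method = np.full(n, "unassigned", dtype=object)

    start = reads["start"].to_numpy()
    end = reads["end"].to_numpy()
    strand = reads["strand"].to_numpy()
    rl = reads["read_length"].to_numpy()
    fp = _five_prime_pos(start, end, strand)

    for key, sub in reads.groupby(["chrom", "strand"], sort=False):
        idx = indexes.get(key)
        if idx is None:
            continue
        sel = sub.index.to_numpy()
        g, m = _assign_group(idx, start[sel], end[sel], rl[sel], min_overlap_frac, fp[sel])
        gene[sel] = g
        method[sel] = m

    has_gene = gene != None  # noqa: E711
    has_tail = reads["tail_called"].notna().to_numpy()
    keep = has_gene & has_tail
    discarded = {
        "not_unique_best": 0,
        "no_gene": int((~has_gene).sum()),
        "no_tail_call": int((has_gene & ~has_tail).sum()),
    }
    out = reads.loc[keep].copy()
    out["gene_id"] = gene[keep]
    out["assignment_method"] = method[keep]
    logger.info(
        "assigned %d/%d reads (no_gene=%d, no_tail_call=%d, five_prime_rescued=%d)",
        len(out),
        n,
        discarded["no_gene"],
        discarded["no_tail_call"],
        int((out["assignment_method"] == "five_prime_end").sum()),
    )
    return AssignmentResult(assigned=out.reset_index(drop=True), discarded=discarded)


def assign_reads(
    reads: pd.DataFrame, genes: pd.DataFrame, min_overlap_frac: float = 0.5
) -> AssignmentResult:
    """Full assignment stage: unique-best filter, dual assignment,
    completeness filter."""
    kept, n_multi = filter_unique_best(reads)
    result = combine_assignments(kept, genes, min_overlap_frac=min_overlap_frac)
    result.discarded["not_unique_best"] = n_multi
    return result
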