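"""Poly(A)-selection bias statistics.

The core question: which genes' mRNAs shift in mean tail length between a
poly(A)-selected and an unselected library, and are those genes also
differentially *captured* (under-represented after selection)?

Workflow (per the analysis this package reproduces):

1. per-gene delta = selected mean tail - unselected mean tail, in each
   biological sample, restricted to genes with enough reads in all
   contributing libraries;
2. the two replicate deltas are averaged ("projected along the diagonal" of
   the replicate-vs-replicate scatter; the average is rank-equivalent to the
   orthogonal projection, which only rescales by sqrt(2));
3. genes are cut into equal-frequency deciles of the projected delta;
   decile 10 holds the most variable tails;
4. RPM fold changes (selected/unselected, and selected replicate 2 /
   replicate 1) are compared between decile 10 and deciles 1-9 with a
   two-sample Kolmogorov-Smirnov test.

``SelectionBiasModel`` bundles the workflow statsmodels-style: construct it
from per-library gene summaries plus a library design table, call
``fit()``, and read the estimates off the ``SelectionBiasResults``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

logger = logging.getLogger(__name__)

__all__ = [
    "KSResult",
    "tail_length_differences",
    "diagonal_projection",
    "decile_bins",
    "rpm_fold_change",
    "ks_two_sample",
    "technique_bias_report",
    "replicate_variability_report",
    "SelectionBiasModel",
    "SelectionBiasResults",
]


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov machinery

@dataclass(frozen=True)
class KSResult:
    statistic: float
    p_value: float
    n1: int
    n2: int
    groups: tuple[str, str] = ("a", "b")

    def __post_init__(self):
        if not (0.0 <= self.statistic <= 1.0):
            raise ValueError("KS statistic must lie in [0, 1]")


def _ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    a = np.sort(a)
    b = np.sort(b)
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / len(a)
    cdf_b = np.searchsorted(b, pooled, side="right") / len(b)
    return float(np.max(np.abs(cdf_a - cdf_b)))


def _ks_p_asymptotic(d: float, n1: int, n2: int) -> float:
    en = n1 * n2 / (n1 + n2)
    return float(special.kolmogorov(np.sqrt(en) * d))


def _ks_p_exact(d: float, n1: int, n2: int) -> float:
    """Exact two-sided P(D >= d) under H0 by lattice-path counting.

    Counts the fraction of the C(n1+n2, n1) orderings whose ECDF path stays
    strictly inside the band |i/n1 - j/n2| < d; assumes no ties across
    samples (falls back to the asymptotic form when ties are present).
    """
    # integer lattice: a path cell (i, j) violates the band when
    # |i*n2 - j*n1| >= d*n1*n2 (tolerance guards float round-off in d)
    lim = d * n1 * n2 - 1e-9
    if lim <= 0:
        return 1.0
    inside = np.zeros((n1 + 1, n2 + 1))
    inside[0, 0] = 1.0
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            if i == 0 and j == 0:
                continue
            if abs(i * n2 - j * n1) >= lim:
                continue
            acc = inside[i - 1, j] if i > 0 else 0.0
            if j > 0:
                acc += inside[i, j - 1]
            inside[i, j] = acc
    total = special.comb(n1 + n2, n1, exact=False)
    return float(max(0.0, min(1.0, 1.0 - inside[n1, n2] / total)))


def ks_two_sample(a, b, method: str = "asymp", groups: tuple[str, str] = ("a", "b")) -> KSResult:
    """Two-sided two-sample KS test: D = sup |ECDF_a - ECDF_b|.

    ``method``: "asymp" (Kolmogorov limiting distribution), "exact"
    (lattice-path count, only for n1*n2 <= 10_000 and tie-free data), or
    "auto" (exact when admissible).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    d = _ks_statistic(a, b)
    n1, n2 = len(a), len(b)
    use_exact = method == "exact" or (method == "auto" and n1 * n2 <= 10_000)
    if method not in {"asymp", "exact", "auto"}:
        raise ValueError(f"unknown method {method!r}")
    if use_exact:
        has_ties = len(np.intersect1d(a, b)) > 0
        if has_ties and method == "auto":
            use_exact = False
        elif has_ties:
            raise ValueError("exact p-value requires tie-free samples")
    p = _ks_p_exact(d, n1, n2) if use_exact else _ks_p_asymptotic(d, n1, n2)
    return KSResult(statistic=d, p_value=p, n1=n1, n2=n2, groups=groups)


# ---------------------------------------------------------------------------
# Tail-length deltas, diagonal projection, deciles, fold changes

def tail_length_differences(selected: pd.DataFrame, unselected: pd.DataFrame) -> pd.Series:
    """Per-gene mean-tail difference (selected - unselected), over genes
    passing the min-reads filter in both libraries."""
    s = selected.loc[selected["passes_min_reads"]].set_index("gene_id")["mean_tail"]
    u = unselected.loc[unselected["passes_min_reads"]].set_index("gene_id")["mean_tail"]
    shared = s.index.intersection(u.index)
    if len(shared) == 0:
        raise ValueError("no genes pass the min-reads filter in both libraries")
    delta = (s.loc[shared] - u.loc[shared]).rename("delta")
    return delta.sort_index()


def diagonal_projection(deltas_rep1: pd.Series, deltas_rep2: pd.Series) -> pd.Series:
    """Average of the two replicate deltas per gene (diagonal projection up
    to the sqrt(2) scale factor, hence rank-identical)."""
    shared = deltas_rep1.index.intersection(deltas_rep2.index)
    return ((deltas_rep1.loc[shared] + deltas_rep2.loc[shared]) / 2.0).rename("projected")


def decile_bins(projected: pd.Series) -> pd.Series:
    """Equal-frequency decile labels 1..10 of the projected delta.

    Genes are sorted ascending (ties broken by gene_id for determinism) and
    split into 10 contiguous bins whose sizes differ by at most one; decile
    10 holds the largest projected differences.
    """
    n = len(projected)
    if n < 10:
        raise ValueError(f"need >= 10 genes to form deciles, got {n}")
    order = sorted(projected.index, key=lambda g: (projected[g], g))
    labels = pd.Series(0, index=projected.index, name="decile", dtype=int)
    # largest bins first so the top decile is never the oversized one
    chunks = np.array_split(np.asarray(order, dtype=object), 10)
    for k, chunk in enumerate(chunks, start=1):
        labels.loc[chunk] = k
    return labels


def rpm_fold_change(
    numerator: pd.DataFrame,
    denominator: pd.DataFrame,
    pseudocount_rpm: float = 0.0,
    genes=None,
) -> pd.DataFrame:
    """Per-gene RPM ratio numerator/denominator with optional pseudocount.

    With ``pseudocount_rpm == 0``, genes whose ratio is 0/ x, x/0 or 0/0 are
    excluded (their count is logged); the remaining fc are strictly
    positive so ``log2_fc`` is finite.
    """
    num = numerator.set_index("gene_id")["rpm"]
    den = denominator.set_index("gene_id")["rpm"]
    shared = num.index.intersection(den.index)
    if genes is not None:
        shared = shared.intersection(pd.Index(genes))
    fc = (num.loc[shared] + pseudocount_rpm) / (den.loc[shared] + pseudocount_rpm)
    bad = ~np.isfinite(fc) | (fc <= 0)
    if bad.any():
        logger.info("rpm_fold_change: excluded %d genes with zero/undefined RPM ratio", int(bad.sum()))
    fc = fc[~bad]
    return pd.DataFrame({"gene_id": fc.index, "fc": fc.to_numpy(), "log2_fc": np.log2(fc.to_numpy())}).reset_index(drop=True)


def _decile_split(fold_changes: pd.DataFrame, deciles: pd.Series) -> tuple[np.ndarray, np.ndarray, int]:
    fc = fold_changes.set_index("gene_id")["log2_fc"]
    known = fc.index.intersection(deciles.index)
    dropped = len(fc) - len(known)
    if dropped:
        logger.info("decile split: %d fold-change genes absent from the decile table", dropped)
    lab = deciles.loc[known]
    top = fc.loc[known[lab == 10]].to_numpy()
    rest = fc.loc[known[lab < 10]].to_numpy()
    return top, rest, dropped


def _ecdf_table(values: np.ndarray, label) -> pd.DataFrame:
    v = np.sort(values)
    return pd.DataFrame({"group": label, "log2_fc": v, "ecdf": np.arange(1, len(v) + 1) / len(v)})


def technique_bias_report(
    deciles: pd.Series, fold_changes: pd.DataFrame
) -> tuple[pd.DataFrame, KSResult]:
    """Per-decile ECDF table of technique log2 fold changes plus the
    headline decile-10 vs deciles-1-9 KS comparison."""
    fc = fold_changes.set_index("gene_id")["log2_fc"]
    known = fc.index.intersection(deciles.index)
    lab = deciles.loc[known]
    tables = [
        _ecdf_table(fc.loc[known[lab == k]].to_numpy(), k) for k in range(1, 11) if (lab == k).any()
    ]
    cdf = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(columns=["group", "log2_fc", "ecdf"])
    top, rest, _ = _decile_split(fold_changes, deciles)
    ks = ks_two_sample(top, rest, groups=("decile10", "deciles1-9"))
    return cdf, ks


def replicate_variability_report(
    rep_a: pd.DataFrame,
    rep_b: pd.DataFrame,
    deciles: pd.Series,
    pseudocount_rpm: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame, KSResult]:
    """Replicate-noise analysis: fold change rep_b/rep_a between two
    selected libraries of the same biological sample, KS of decile 10 vs
    deciles 1-9. Returns (fold_changes, cdf_table, ks)."""
    fc = rpm_fold_change(rep_b, rep_a, pseudocount_rpm=pseudocount_rpm)
    top, rest, _ = _decile_split(fc, deciles)
    ks = ks_two_sample(top, rest, groups=("decile10", "deciles1-9"))
    cdf = pd.concat(
        [_ecdf_table(top, "decile10"), _ecdf_table(rest, "deciles1-9")], ignore_index=True
    )
    return fc, cdf, ks


# ---------------------------------------------------------------------------
# Model / Results

class SelectionBiasModel:
    """Selection-bias analysis over a paired selected/unselected design.

    Parameters
    ----------
    summaries
        Mapping library_id -> per-gene summary frame (with ``rpm`` and
        ``passes_min_reads`` columns, as produced by
        :func:`polyadrift.summaries.summarize_experiment`).
    design
        Library design table with columns
        ``library_id, sample_id, technique, replicate``. The model needs at
        least two samples that each have a selected and an unselected
        library; extra selected replicates of a sample feed the
        replicate-variability analysis.
    pseudocount_rpm
        Added to both RPMs before ratios; 0 excludes zero-RPM genes.
    """

    def __init__(
        self,
        summaries: dict[str, pd.DataFrame],
        design: pd.DataFrame,
        pseudocount_rpm: float = 0.0,
    ):
        self.summaries = summaries
        self.design = design.reset_index(drop=True)
        self.pseudocount_rpm = float(pseudocount_rpm)
        dup = self.design.duplicated(["sample_id", "technique", "replicate"])
        if dup.any():
            raise ValueError("design rows must be unique in (sample, technique, replicate)")
        missing = set(self.design["library_id"]) - set(summaries)
        if missing:
            raise ValueError(f"design references unknown libraries: {sorted(missing)}")
        self._pairs = self._technique_pairs()
        if len(self._pairs) < 2:
            raise ValueError("need >= 2 samples with both a selected and an unselected library")

    @classmethod
    def from_frames(cls, summaries, design, **kw) -> "SelectionBiasModel":
        return cls(summaries, design, **kw)

    def _technique_pairs(self) -> list[tuple[str, str, str]]:
        """(sample_id, selected_lib, unselected_lib) per sample, taking the
        lowest-replicate library of each technique."""
        pairs = []
        for sample, grp in self.design.groupby("sample_id", sort=True):
            sel = grp[grp["technique"] == "selected"].sort_values("replicate")
            uns = grp[grp["technique"] == "unselected"].sort_values("replicate")
            if len(sel) and len(uns):
                pairs.append((sample, sel["library_id"].iloc[0], uns["library_id"].iloc[0]))
        return pairs

    def _replicate_pairs(self) -> list[tuple[str, str, str]]:
        pairs = []
        for sample, grp in self.design.groupby("sample_id", sort=True):
            sel = grp[grp["technique"] == "selected"].sort_values("replicate")
            if len(sel) >= 2:
                pairs.append((sample, sel["library_id"].iloc[0], sel["library_id"].iloc[1]))
        return pairs

    def fit(self) -> "SelectionBiasResults":
        (s1, sel1, uns1), (s2, sel2, uns2) = self._pairs[:2]
        d1 = tail_length_differences(self.summaries[sel1], self.summaries[uns1])
        d2 = tail_length_differences(self.summaries[sel2], self.summaries[uns2])
        projected = diagonal_projection(d1, d2)
        deciles = decile_bins(projected)
        tail_deltas = pd.DataFrame(
            {
                "gene_id": projected.index,
                "delta_rep1": d1.loc[projected.index].to_numpy(),
                "delta_rep2": d2.loc[projected.index].to_numpy(),
                "projected": projected.to_numpy(),
                "decile": deciles.loc[projected.index].to_numpy(),
            }
        ).reset_index(drop=True)

        technique_fc: dict[str, pd.DataFrame] = {}
        technique_cdf: dict[str, pd.DataFrame] = {}
        technique_ks: dict[str, KSResult] = {}
        for sample, sel, uns in self._pairs:
            fc = rpm_fold_change(
                self.summaries[sel],
                self.summaries[uns],
                pseudocount_rpm=self.pseudocount_rpm,
                genes=projected.index,
            )
            cdf, ks = technique_bias_report(deciles, fc)
            technique_fc[sample] = fc
            technique_cdf[sample] = cdf
            technique_ks[sample] = ks

        replicate_fc: dict[str, pd.DataFrame] = {}
        replicate_cdf: dict[str, pd.DataFrame] = {}
        replicate_ks: dict[str, KSResult] = {}
        for sample, rep_a, rep_b in self._replicate_pairs():
            fc, cdf, ks = replicate_variability_report(
                self.summaries[rep_a],
                self.summaries[rep_b],
                deciles,
                pseudocount_rpm=self.pseudocount_rpm,
            )
            replicate_fc[sample] = fc
            replicate_cdf[sample] = cdf
            replicate_ks[sample] = ks

        return SelectionBiasResults(
            model=self,
            tail_deltas=tail_deltas,
            technique_fold_changes=technique_fc,
            technique_cdf=technique_cdf,
            technique_ks=technique_ks,
            replicate_fold_changes=replicate_fc,
            replicate_cdf=replicate_cdf,
            replicate_ks=replicate_ks,
        )


@dataclass
class SelectionBiasResults:
    """Fitted selection-bias estimates.

    ``tail_deltas`` has one row per decile-eligible gene (delta per sample,
    projected average, decile label). Fold-change frames and KS results are
    keyed by sample_id. Fold-change orientation: selected/unselected for
    technique comparisons, replicate-2/replicate-1 for replicate
    comparisons.
    """

    model: SelectionBiasModel
    tail_deltas: pd.DataFrame
    technique_fold_changes: dict[str, pd.DataFrame]
    technique_cdf: dict[str, pd.DataFrame]
    technique_ks: dict[str, KSResult]
    replicate_fold_changes: dict[str, pd.DataFrame]
    replicate_cdf: dict[str, pd.DataFrame]
    replicate_ks: dict[str, KSResult]

    @property
    def median_projected_delta(self) -> float:
        return float(self.tail_deltas["projected"].median())

    @property
    def decile10_genes(self) -> pd.Index:
        td = self.tail_deltas
        return pd.Index(td.loc[td["decile"] == 10, "gene_id"])

    def decile10_median_log2_fc(self, sample: str) -> float:
        fc = self.technique_fold_changes[sample].set_index("gene_id")["log2_fc"]
        top = fc.index.intersection(self.decile10_genes)
        return float(fc.loc[top].median())

    def summary(self) -> str:
        lines = [
            "Poly(A) selection bias analysis",
            "=" * 47,
            f"decile-eligible genes          {len(self.tail_deltas):>10d}",
            f"median projected delta (nt)    {self.median_projected_delta:>10.3f}",
            f"decile 10 size                 {len(self.decile10_genes):>10d}",
            "",
            "Technique capture bias (KS, decile 10 vs 1-9; fc = selected/unselected RPM)",
        ]
        for sample, ks in self.technique_ks.items():
            lines.append(
                f"  sample {sample:<8s} D={ks.statistic:.4f}  p={ks.p_value:.3g}  "
                f"(n={ks.n1} vs {ks.n2}); decile-10 median log2 fc "
                f"{self.decile10_median_log2_fc(sample):+.3f}"
            )
        if self.replicate_ks:
            lines.append("Replicate variability (KS, decile 10 vs 1-9; fc = rep2/rep1 RPM)")
            for sample, ks in self.replicate_ks.items():
                lines.append(
                    f"  sample {sample:<8s} D={ks.statistic:.4f}  p={ks.p_value:.3g}  "
                    f"(n={ks.n1} vs {ks.n2})"
                )
        return "\n".join(lines)
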