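"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most transparent method available
(exhaustive enumeration, closed form, textbook formula) and stays
independent of the package code paths it checks.
"""

import numpy as np
from scipy.special import comb
from scipy.stats import t as t_dist


def ks_bruteforce_d(a, b) -> float:
    """Max ECDF gap by direct evaluation at every pooled point (O(n^2))."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    best = 0.0
    for x in np.concatenate([a, b]):
        gap = abs((a <= x).mean() - (b <= x).mean())
        best = max(best, gap)
    return best


def ks_p_series(d: float, n1: int, n2: int, terms: int = 200) -> float:
    """Asymptotic two-sided KS p via the alternating Kolmogorov series."""
    lam = np.sqrt(n1 * n2 / (n1 + n2)) * d
    if lam <= 0:
        return 1.0
    ks = np.arange(1, terms + 1)
    p = 2.0 * np.sum((-1.0) ** (ks - 1) * np.exp(-2.0 * ks**2 * lam**2))
    return float(min(1.0, max(0.0, p)))


def hypergeom_expected_unique(counts, m: int) -> float:
    """Closed-form expected number of detected genes in a size-m subsample
    without replacement: sum_g 1 - C(N - k_g, m) / C(N, m)."""
    counts = np.asarray(counts, dtype=int)
    n = int(counts.sum())
    total = 0.0
    for k in counts:
        total += 1.0 - comb(n - k, m, exact=True) / comb(n, m, exact=True) if m <= n - k else 1.0
    return total


def spearman_rank_pearson(x, y) -> float:
    """Spearman rho as Pearson correlation of hand-computed average ranks."""

    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        ranks = np.empty(len(v))
        for i, xi in enumerate(v):
            less = np.sum(v < xi)
            equal = np.sum(v == xi)
            ranks[i] = less + (equal + 1) / 2.0
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def paired_t_closed_form(diffs):
    """Paired t statistic and two-sided p from the textbook formula."""
    d = np.asarray(diffs, dtype=float)
    n = len(d)
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    p = 2.0 * t_dist.sf(abs(t), df=n - 1)
    return float(t), float(p)


def subset_signature_counts(sets: dict):
    """Per-gene membership-signature tally over all libraries."""
    libs = sorted(sets)
    out: dict[str, int] = {}
    for g in set().union(*sets.values()):
        sig = "".join("1" if g in sets[l] else "0" for l in libs)
        out[sig] = out.get(sig, 0) + 1
    return out
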