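"""Convenience matplotlib views of the report tables (not part of the
analysis contract)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_length_cdf(length_cdf, ax=None):
    """Read-length ECDF per library from the length_cdf table."""
    if ax is None:
        _, ax = plt.subplots()
    for lib, grp in length_cdf.groupby("library_id"):
        ax.step(grp["read_length"], grp["ecdf"], where="post", label=lib)
    ax.set_xlabel("read length (nt)")
    ax.set_ylabel("ECDF")
    ax.legend(fontsize=8)
    return ax


def plot_saturation(saturation, ax=None):
    """Mean unique genes vs subsample percent, one line per library."""
    if ax is None:
        _, ax = plt.subplots()
    for lib, grp in saturation.groupby("library_id"):
        ax.plot(grp["percent"], grp["mean_unique_genes"], label=lib)
        ax.fill_between(
            grp["percent"],
            grp["mean_unique_genes"] - grp["sd_unique_genes"],
            grp["mean_unique_genes"] + grp["sd_unique_genes"],
            alpha=0.2,
        )
    ax.set_xlabel("percent of reads subsampled")
    ax.set_ylabel("unique genes (mean over repeats)")
    ax.legend(fontsize=8)
    return ax


def plot_decile_cdfs(technique_cdf, ax=None, cmap="viridis"):
    """Fold-change CDFs per tail-delta decile (decile 10 = most variable)."""
    if ax is None:
        _, ax = plt.subplots()
    colors = plt.get_cmap(cmap)
    for k, grp in technique_cdf.groupby("group"):
        ax.step(
            grp["log2_fc"], grp["ecdf"], where="post",
            color=colors((int(k) - 1) / 9), label=f"decile {k}",
        )
    ax.set_xlabel("log2 RPM fold change (selected / unselected)")
    ax.set_ylabel("ECDF")
    ax.legend(fontsize=7, ncol=2)
    return ax
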