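"""Forward simulation of paired selected/unselected direct RNA-seq libraries.

The generator plants a known per-gene ground truth (abundance, poly(A) tail
mixture, variable-tail flag) and pushes molecules through a tail-length-
dependent capture model:

* both library types require a minimal 3'-adenosine run for splint ligation
  (hard threshold ``splint_min_a``);
* poly(A)-selected libraries additionally retain molecules with a logistic
  probability in tail length (oligo-dT bead binding), so short-tailed
  molecules are under-captured;
* unselected libraries capture every splint-ligatable molecule at the base
  rate.

Reads are anchored at the transcript 3' end and extend 5' until a
per-nucleotide stop event (pore stall / degraded template), giving the
long-tailed read-length distribution characteristic of dRNA-seq. Tail-length
calls carry multiplicative Gaussian noise, mimicking signal-based estimators
whose error grows with tail length.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "BIOTYPES",
    "TailDistribution",
    "CaptureConfig",
    "GroundTruth",
    "generate_annotation",
    "make_ground_truth",
    "capture_probability",
    "expected_capture",
    "simulate_library",
    "simulate_experiment",
    "default_design",
]

BIOTYPES = ("protein_coding", "rRNA", "snoRNA", "ncRNA", "other")

DEFAULT_BIOTYPE_FREQS = {
    "protein_coding": 0.85,
    "rRNA": 0.02,
    "snoRNA": 0.03,
    "ncRNA": 0.05,
    "other": 0.05,
}

#: Shortest read the simulator emits (nt); sub-50 nt fragments are not
#: realistically basecalled/mapped and would never pass gene assignment.
MIN_READ_LENGTH = 50


@dataclass(frozen=True)
class TailDistribution:
    """Gaussian-mixture model of one gene's poly(A) tail lengths (nt).

    Negative draws are clipped to zero; a gene with a genuinely bimodal
    mixture (distinct short/long modes) is the planted "variable tail
    length" case.
    """

    weights: tuple[float, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        m = np.asarray(self.means, dtype=float)
        s = np.asarray(self.sds, dtype=float)
        if not (len(w) == len(m) == len(s)) or len(w) < 1:
            raise ValueError("weights, means, sds must be equal-length and non-empty")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1 (got {w.sum()!r})")
        if (w < 0).any() or (s < 0).any() or (m < 0).any():
            raise ValueError("weights, means and sds must be non-negative")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def mean(self) -> float:
        return float(np.dot(self.weights, self.means))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(self.n_components, size=n, p=np.asarray(self.weights))
        vals = rng.normal(np.asarray(self.means)[comp], np.asarray(self.sds)[comp])
        return np.clip(vals, 0.0, None)


@dataclass(frozen=True)
class CaptureConfig:
    """Simulator parameters for library construction and signal calling.

    Parameters
    ----------
    splint_min_a
        Minimum true tail length (nt) for splint ligation; molecules below
        it are lost in *both* library types.
    selection_midpoint, selection_slope
        Logistic oligo-dT capture curve for selected libraries: capture is
        ``base_capture * expit(slope * (tail - midpoint))`` above the splint
        threshold. The midpoint is the tail length captured at half the base
        rate.
    base_capture
        Capture probability of a long-tailed molecule.
    depth
        Expected number of sequenced reads per library (library size is set
        by flow-cell time; capture efficiency changes composition, not
        yield).
    tail_call_sd_frac
        SD of tail-call noise as a fraction of the true tail length.
    tail_call_fail_rate
        Probability that the tail caller returns no estimate for a read.
    truncation_rate
        Per-nucleotide probability that the read stops while extending 5'
        from the 3' end (pore stall / degraded template).
    multimap_rate
        Probability that a read fails the unique-best-mapping filter.
    seed
        Root seed for the experiment-level simulation streams.
    """

    splint_min_a: float = 10.0
    selection_midpoint: float = 40.0
    selection_slope: float = 0.15
    base_capture: float = 0.5
    depth: float = 200_000.0
    tail_call_sd_frac: float = 0.15
    tail_call_fail_rate: float = 0.005
    truncation_rate: float = 5.5e-4
    multimap_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.base_capture <= 1.0):
            raise ValueError("base_capture must be in (0, 1]")
        if self.selection_slope < 0:
            raise ValueError("selection_slope must be >= 0")
        if self.splint_min_a < 0:
            raise ValueError("splint_min_a must be >= 0")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not (0.0 <= self.truncation_rate < 1.0):
            raise ValueError("truncation_rate must be in [0, 1)")

    def replace(self, **kw) -> "CaptureConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """Planted per-gene truth for one simulated experiment.

    Arrays are aligned with the rows of ``genes``. ``three_prime_offset``
    models annotation-incomplete 3' UTR ends: reads of such genes extend
    past the annotated transcript end, which is what makes the 5'-end
    fallback assignment path do real work.
    """

    genes: pd.DataFrame
    abundance: np.ndarray
    tails: list[TailDistribution]
    variable_tail: np.ndarray
    three_prime_offset: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.genes)
        if not (len(self.abundance) == len(self.tails) == len(self.variable_tail) == n):
            raise ValueError("ground-truth arrays must align with the gene table")
        if n == 0:
            raise ValueError("ground truth is empty")
        for flag, dist in zip(self.variable_tail, self.tails):
            if flag and dist.n_components < 2:
                raise ValueError("variable_tail gene must have a multi-component mixture")


def generate_annotation(
    n_genes: int,
    seed: int,
    *,
    chrom: str = "chrI",
    chrom_length: int | None = None,
    mean_tx_len: float = 1400.0,
    sigma_tx_len: float = 0.5,
    min_tx_len: int = 200,
    intergenic_mean: float = 400.0,
    single_transcript_frac: float = 0.7,
    biotype_freqs: dict[str, float] | None = None,
    overlap_frac: float = 0.0,
    utr5_mean: float = 120.0,
    utr3_mean: float = 220.0,
) -> pd.DataFrame:
    """Lay out ``n_genes`` gene models on one chromosome.

    Genes are placed left to right with exponential intergenic gaps and are
    pairwise disjoint unless ``overlap_frac > 0``, in which case that
    fraction of genes is shifted back to overlap its left neighbour.
    Coordinates are 0-based half-open. Raises ``ValueError`` if an explicit
    ``chrom_length`` cannot hold the layout.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    freqs = dict(DEFAULT_BIOTYPE_FREQS if biotype_freqs is None else biotype_freqs)
    bt_names = list(freqs)
    bt_p = np.asarray([freqs[b] for b in bt_names], dtype=float)
    bt_p = bt_p / bt_p.sum()

    lengths = np.maximum(
        min_tx_len,
        rng.lognormal(np.log(mean_tx_len), sigma_tx_len, size=n_genes),
    ).astype(np.int64)
    gaps = np.maximum(1, rng.exponential(intergenic_mean, size=n_genes)).astype(np.int64)
    # leading margin so 3'-offset reads of the first genes stay on-chromosome
    gaps[0] += 2000

    tx_start = np.empty(n_genes, dtype=np.int64)
    pos = np.int64(0)
    overlap_flags = rng.random(n_genes) < overlap_frac
    overlap_flags[0] = False
    prev_len = np.int64(0)
    for i in range(n_genes):
        pos += gaps[i]
        if overlap_flags[i]:
            # slide back into the previous gene by up to half its length
            back = int(rng.integers(1, max(2, prev_len // 2)))
            pos = max(tx_start[i - 1] + 1, pos - gaps[i] - back)
        tx_start[i] = pos
        pos += lengths[i]
        prev_len = lengths[i]
    tx_end = tx_start + lengths
    if chrom_length is not None and int(tx_end.max()) > int(chrom_length):
        raise ValueError(
            f"layout needs {int(tx_end.max())} nt but chrom_length={chrom_length}"
        )

    biotype = np.asarray(bt_names, dtype=object)[rng.choice(len(bt_names), n_genes, p=bt_p)]
    strand = np.where(rng.random(n_genes) < 0.5, "+", "-")
    n_tx = np.where(
        rng.random(n_genes) < single_transcript_frac,
        1,
        rng.integers(2, 5, size=n_genes),
    )

    utr5 = np.minimum(rng.exponential(utr5_mean, n_genes).astype(np.int64), lengths // 3)
    utr3 = np.minimum(rng.exponential(utr3_mean, n_genes).astype(np.int64), lengths // 3)
    coding = biotype == "protein_coding"
    # on the minus strand the 5' UTR sits at the high-coordinate end
    left = np.where(strand == "+", utr5, utr3)
    right = np.where(strand == "+", utr3, utr5)
    cds_start = np.where(coding, tx_start + left, tx_start)
    cds_end = np.where(coding, tx_end - right, tx_start)
    cds_end = np.where(coding & (cds_end <= cds_start), tx_end - right.clip(max=0), cds_end)

    width = max(4, len(str(n_genes)))
    gene_id = np.asarray([f"gene-{i:0{width}d}" for i in range(n_genes)], dtype=object)
    return pd.DataFrame(
        {
            "gene_id": gene_id,
            "chrom": chrom,
            "strand": strand,
            "tx_start": tx_start,
            "tx_end": tx_end,
            "cds_start": cds_start.astype(np.int64),
            "cds_end": cds_end.astype(np.int64),
            "biotype": biotype,
            "n_transcripts": n_tx.astype(np.int64),
        }
    )


def make_ground_truth(
    genes: pd.DataFrame,
    seed: int,
    *,
    bimodal_fraction: float = 0.10,
    abundance_sigma: float = 0.05,
    unimodal_mean_loc: float = 70.0,
    unimodal_mean_scale: float = 10.0,
    unimodal_mean_range: tuple[float, float] = (50.0, 110.0),
    unimodal_sd_range: tuple[float, float] = (8.0, 14.0),
    bimodal_short_weight: float = 0.12,
    bimodal_modes: tuple[float, float] = (20.0, 120.0),
    bimodal_sds: tuple[float, float] = (8.0, 15.0),
    offset_fraction: float = 0.10,
    offset_mean: float = 250.0,
) -> GroundTruth:
    """Plant abundances, tail mixtures and annotation 3'-offsets.

    Defaults emulate the well-expressed regime the per-gene tail analyses
    operate in (the 80-read filter conditions every downstream statistic on
    well-covered genes), so gene abundances are nearly uniform
    (``abundance_sigma`` on a log scale). A ``bimodal_fraction`` of genes
    gets a short/long tail mixture (the planted variable-tail class); the
    rest get a single Gaussian tail population.
    """
    genes = genes.reset_index(drop=True)
    n = len(genes)
    if n == 0:
        raise ValueError("empty annotation")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 23]))
    raw = rng.lognormal(0.0, abundance_sigma, size=n)
    abundance = raw / raw.sum()

    variable = np.zeros(n, dtype=bool)
    n_var = int(round(bimodal_fraction * n))
    if n_var:
        variable[rng.choice(n, size=n_var, replace=False)] = True

    mu = np.clip(
        rng.normal(unimodal_mean_loc, unimodal_mean_scale, size=n),
        *unimodal_mean_range,
    )
    sd = rng.uniform(*unimodal_sd_range, size=n)
    tails: list[TailDistribution] = []
    for i in range(n):
        if variable[i]:
            tails.append(
                TailDistribution(
                    weights=(bimodal_short_weight, 1.0 - bimodal_short_weight),
                    means=bimodal_modes,
                    sds=bimodal_sds,
                )
            )
        else:
            tails.append(TailDistribution((1.0,), (float(mu[i]),), (float(sd[i]),)))

    offset = np.zeros(n, dtype=np.int64)
    off_mask = rng.random(n) < offset_fraction
    offset[off_mask] = np.maximum(1, rng.exponential(offset_mean, off_mask.sum())).astype(np.int64)
    # a real unannotated 3' extension still ends before the neighbouring
    # gene: cap each offset at the intergenic gap on the 3' side
    cap = np.full(n, np.iinfo(np.int64).max)
    for _, grp in genes.groupby("chrom"):
        order = grp["tx_start"].sort_values().index.to_numpy()
        starts = genes.loc[order, "tx_start"].to_numpy()
        ends = genes.loc[order, "tx_end"].to_numpy()
        strands = genes.loc[order, "strand"].to_numpy()
        pos = genes.index.get_indexer(order)
        gap_right = np.append(starts[1:] - ends[:-1], np.iinfo(np.int64).max)
        gap_left = np.append(np.iinfo(np.int64).max, starts[1:] - ends[:-1])
        cap[pos] = np.where(strands == "+", gap_right, gap_left) - 20
    offset = np.clip(offset, 0, np.maximum(cap, 0))

    return GroundTruth(
        genes=genes.reset_index(drop=True),
        abundance=abundance,
        tails=tails,
        variable_tail=variable,
        three_prime_offset=offset,
    )


def capture_probability(tail_length, selected: bool, config: CaptureConfig):
    """Probability that a molecule with the given true tail is captured.

    Unselected: 0 below the splint threshold, else ``base_capture``.
    Selected: additionally scaled by the logistic oligo-dT binding curve.
    Monotone non-decreasing in tail length in both modes.
    """
    t = np.asarray(tail_length, dtype=float)
    if (t < 0).any():
        raise ValueError("tail_length must be >= 0")
    p = np.full(t.shape, config.base_capture)
    if selected:
        p = p * expit(config.selection_slope * (t - config.selection_midpoint))
    p = np.where(t < config.splint_min_a, 0.0, p)
    if np.isscalar(tail_length):
        return float(p)
    return p


def expected_capture(dist: TailDistribution, selected: bool, config: CaptureConfig) -> float:
    """E[capture] for one gene's tail mixture, by per-component quadrature.

    Draws are clipped at zero, so the sub-zero Gaussian mass sits as an atom
    at tail = 0.
    """
    total = 0.0
    for w, m, s in zip(dist.weights, dist.means, dist.sds):
        if s == 0:
            total += w * capture_probability(max(m, 0.0), selected, config)
            continue
        hi = m + 10.0 * s
        grid = np.linspace(0.0, hi, 4001)
        pdf = norm.pdf(grid, loc=m, scale=s)
        cap = capture_probability(grid, selected, config)
        integral = np.trapezoid(pdf * cap, grid)
        atom = norm.cdf(0.0, loc=m, scale=s) * capture_probability(0.0, selected, config)
        total += w * (integral + atom)
    return float(total)


def _per_gene_expected_capture(truth: GroundTruth, selected: bool, config: CaptureConfig) -> np.ndarray:
    cache: dict[TailDistribution, float] = {}
    out = np.empty(len(truth.tails))
    for i, dist in enumerate(truth.tails):
        if dist not in cache:
            cache[dist] = expected_capture(dist, selected, config)
        out[i] = cache[dist]
    return out


READS_COLUMNS = [
    "read_id",
    "library_id",
    "gene_id_true",
    "chrom",
    "strand",
    "start",
    "end",
    "read_length",
    "tail_true",
    "tail_called",
    "unique_best",
]


def simulate_library(
    genes: pd.DataFrame,
    truth: GroundTruth,
    selected: bool,
    config: CaptureConfig,
    library_id: str,
    rng: np.random.Generator | None = None,
    depth: float | None = None,
) -> pd.DataFrame:
    """Simulate one library as a per-read table (see ``READS_COLUMNS``).

    Molecules are drawn per gene proportional to abundance, tails from the
    gene's mixture, retention by :func:`capture_probability`; the number of
    molecules is calibrated so the expected retained read count is
    ``depth``.
    """
    if truth is None or len(truth.genes) == 0:
        raise ValueError("empty ground truth")
    if not truth.genes["gene_id"].equals(genes.reset_index(drop=True)["gene_id"]):
        raise ValueError("ground truth does not cover the supplied annotation")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 101]))
    depth = float(config.depth if depth is None else depth)

    ecap = _per_gene_expected_capture(truth, selected, config)
    mean_cap = float(np.dot(truth.abundance, ecap))
    if mean_cap <= 0:
        raise ValueError("capture model retains no molecules under this configuration")
    n_mol = int(rng.poisson(depth / mean_cap))
    counts = rng.multinomial(n_mol, truth.abundance)

    g = truth.genes
    tx_start = g["tx_start"].to_numpy()
    tx_end = g["tx_end"].to_numpy()
    strand = g["strand"].to_numpy()
    gene_ids = g["gene_id"].to_numpy()
    chroms = g["chrom"].to_numpy()
    offs = truth.three_prime_offset

    rows_gene: list[np.ndarray] = []
    rows_tail: list[np.ndarray] = []
    for gi in np.nonzero(counts)[0]:
        k = counts[gi]
        tails = truth.tails[gi].sample(k, rng)
        keep = rng.random(k) < capture_probability(tails, selected, config)
        if keep.any():
            rows_gene.append(np.full(int(keep.sum()), gi, dtype=np.int64))
            rows_tail.append(tails[keep])
    if rows_gene:
        gidx = np.concatenate(rows_gene)
        tail_true = np.concatenate(rows_tail)
    else:
        gidx = np.empty(0, dtype=np.int64)
        tail_true = np.empty(0)
    n_reads = len(gidx)

    # 3'-anchored read extension with per-nt stop rate
    eff_span = (tx_end[gidx] - tx_start[gidx]) + offs[gidx]
    if config.truncation_rate > 0:
        raw_len = rng.geometric(config.truncation_rate, size=n_reads)
    else:
        raw_len = eff_span.copy()
    read_len = np.minimum(eff_span, np.maximum(raw_len, MIN_READ_LENGTH))

    plus = strand[gidx] == "+"
    end3 = np.where(plus, tx_end[gidx] + offs[gidx], tx_start[gidx] - offs[gidx])
    start = np.where(plus, end3 - read_len, end3)
    end = np.where(plus, end3, end3 + read_len)
    start = np.maximum(start, 0)

    noise_sd = config.tail_call_sd_frac * tail_true
    tail_called = np.clip(tail_true + rng.normal(0.0, 1.0, n_reads) * noise_sd, 0.0, None)
    tail_called = np.where(
        rng.random(n_reads) < config.tail_call_fail_rate, np.nan, tail_called
    )
    unique_best = rng.random(n_reads) >= config.multimap_rate

    order = rng.permutation(n_reads)
    df = pd.DataFrame(
        {
            "read_id": [f"{library_id}.r{i:07d}" for i in range(n_reads)],
            "library_id": library_id,
            "gene_id_true": gene_ids[gidx][order],
            "chrom": chroms[gidx][order],
            "strand": strand[gidx][order],
            "start": start[order].astype(np.int64),
            "end": end[order].astype(np.int64),
            "read_length": read_len[order].astype(np.int64),
            "tail_true": tail_true[order],
            "tail_called": tail_called[order],
            "unique_best": unique_best[order],
        }
    )
    return df


def default_design() -> pd.DataFrame:
    """Five-library paired design: two biological samples, each with a
    selected and an unselected library, plus a second selected technical
    replicate on sample B."""
    return pd.DataFrame(
        {
            "library_id": ["Selected-1", "Unselected-1", "Selected-2", "Unselected-2", "Selected-3"],
            "sample_id": ["A", "A", "B", "B", "B"],
            "technique": ["selected", "unselected", "selected", "unselected", "selected"],
            "replicate": [1, 1, 1, 1, 2],
        }
    )


def simulate_experiment(
    genes: pd.DataFrame,
    truth: GroundTruth,
    config: CaptureConfig,
    design: pd.DataFrame | None = None,
    seed: int | None = None,
    depths: dict[str, float] | None = None,
) -> dict[str, pd.DataFrame]:
    """Simulate every library in a design table; returns library_id -> reads.

    Each library gets an independent child stream of the root seed, so the
    experiment is reproducible as a whole and libraries are independent.
    """
    if design is None:
        design = default_design()
    root = int(config.seed if seed is None else seed)
    out: dict[str, pd.DataFrame] = {}
    for i, row in enumerate(design.itertuples(index=False)):
        rng = np.random.default_rng(np.random.SeedSequence([root, 101, i]))
        depth = None if depths is None else depths.get(row.library_id)
        out[row.library_id] = simulate_library(
            genes,
            truth,
            selected=(row.technique == "selected"),
            config=config,
            library_id=row.library_id,
            rng=rng,
            depth=depth,
        )
    return out
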