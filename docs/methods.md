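# Methods

This note documents the models, defaults and numerical conventions behind
`polyadrift`, and what the synthetic experiments do and do not establish
about real data.

## Capture model

A sequenced molecule with true poly(A) tail length `t` (nt) is retained
with probability

```
unselected:  c(t) = 0                          if t <  s
             c(t) = b                          if t >= s
selected:    c(t) = b * logistic(k * (t - m))  if t >= s, else 0
```

where `s = splint_min_a` (default 10 nt) is the hard minimum adenosine run
needed for splint ligation in *both* library types, `b = base_capture`
(default 0.5) is the capture ceiling, and the logistic factor models
oligo(dT) bead binding with midpoint `m = selection_midpoint` (default
40 nt, the tail length captured at `b/2`) and slope `k = selection_slope`
(default 0.15 /nt). Both curves are monotone non-decreasing in tail
length. The logistic-with-threshold form is the minimal monotone model
consistent with the known biochemistry (short tails bind oligo(dT)
inefficiently; splint ligation needs a minimum adenosine run); none of the
numeric defaults are asserted as measured biology, and all are
configurable.

Library size is treated as set by flow-cell time rather than by capture
efficiency: molecules are drawn with expectation `depth / E[c]`, so the
expected number of *retained* reads equals `depth` and capture changes
library composition, not yield. `E[c]` is computed per gene by quadrature
over the gene's tail mixture (4001-point trapezoid per component over
[0, mean + 10 SD], plus the clipped-mass atom at 0).

## Planted ground truth

Each gene gets:

- an abundance share, log-normal with `abundance_sigma` (default 0.05 —
  see "Regime" below);
- a tail-length mixture. By default 10% of genes ("variable-tail" genes)
  are bimodal with modes 20 nt (SD 8) and 120 nt (SD 15) and short-mode
  weight 0.12; the rest are unimodal with per-gene mean ~ N(70, 10) clipped
  to [50, 110] and within-gene SD uniform on [8, 14]. Draws are clipped at
  0 nt;
- with probability 0.10, an unannotated 3′-UTR extension (exponential,
  mean 250 nt, capped at the intergenic gap): reads of such genes extend
  past the annotated transcript end. This emulates incomplete 3′
  annotation and is what gives the 5′-end fallback assignment real work to
  do; without it, every simulated read lies inside its gene's span and the
  overlap method never fails.

Reads are anchored at the (possibly extended) transcript 3′ end and extend
5′ with a per-nucleotide stop probability `truncation_rate` (default
5.5e-4): the read length is `min(span, max(G, 50))` with `G ~ Geometric`.
This "stop-rate" model was chosen over drawing a geometric *amount of 5′
loss* because it produces the two behaviours the analyses rely on: a
long-tailed read-length CDF, and a spanning-CDS probability
`(1 - r)^(CDS + 3'UTR)` that genuinely declines with CDS length. (Under a
5′-loss-amount model, spanning depends only on the 5′ UTR length and is
flat across CDS-length bins.) With the default transcript-length
distribution (log-normal, median 1.4 kb) the pooled mean read length is
~985 nt, matching the regime dRNA-seq libraries of this type report.

Tail calls are `t + N(0, (0.15 t)^2)` floored at 0 (signal-based tail
callers have errors that grow with tail length); calls fail outright with
probability 0.005, and reads fail the unique-best-mapping filter with
probability 0.005.

## Regime the defaults emulate

The per-gene tail analyses condition on ≥ 80 reads per gene in all four
paired libraries, so they only ever see well-covered genes. The generator's
default library therefore represents that well-expressed slice of a
transcriptome: at the default scale (2000 genes × 200k reads/library) the
mean coverage is ~100 reads/gene and abundances are nearly uniform
(`abundance_sigma = 0.05`). These defaults, including the bimodal
short-mode weight, were fixed once by a design analysis of the planted
phenomenon's detectability (variable-tail genes must be depleted enough by
selection to measure, yet still clear the 80-read filter in the selected
libraries) before the test suite was written, and not revisited.

What passing tests on these synthetics do **not** show about real data:
real abundance distributions span orders of magnitude, so real decile
tables cover a biased (well-expressed) subset of genes; real tail-call
error is not exactly multiplicative Gaussian; alignment artifacts,
chimeras, rRNA contamination and isoform structure are absent; and the
logistic capture curve is a stand-in for unknown bead-binding kinetics.
The complexity analyses use separate configurations with wide abundance
spreads (`abundance_sigma` ≈ 1), since saturation and gene-loss behaviour
is only informative when genes sit near the detection limit.

## Analysis conventions

- **Assignment.** Overlap is computed against transcript spans (not exon
  chains), strand-aware, with `min_overlap_frac = 0.5` of the read length;
  ties yield no call rather than an arbitrary winner. The 5′-end fallback
  requires the 5′-most nucleotide (`start` on +, `end-1` on −) to lie in
  exactly one same-strand gene. Overlap takes precedence when both methods
  answer, since the 5′ method exists to rescue reads the overlap method
  cannot handle. Discard reasons are tallied per library
  (`not_unique_best`, `no_gene`, `no_tail_call`); a read with a gene but
  no tail call counts as `no_tail_call`.
- **Summaries.** Means are arithmetic; SDs are sample SDs (n−1), absent
  for single-read genes. RPM uses assigned-read library depth as the
  denominator, which keeps selected/unselected libraries comparable
  despite differing non-mRNA content. The ≥ 80-read filter is boundary
  inclusive.
- **Deciles.** Genes eligible for the decile table must pass the 80-read
  filter in all four paired libraries (both techniques × both samples),
  because the projected delta needs all four mean tails. Genes are sorted
  by projected delta with lexicographic gene-id tie-breaks (deterministic
  across runs) and split into 10 contiguous bins with sizes differing by
  at most one; when the count is not divisible by 10, the *lower* deciles
  take the extra genes, so decile 10 is never the oversized bin.
- **Fold changes.** Orientation is selected/unselected (technique) and
  replicate-2/replicate-1 (noise). Default `pseudocount_rpm = 0`: genes
  with a zero RPM on either side are excluded and their count logged; a
  pseudocount option is available. Both `fc` and `log2_fc` are emitted.
- **KS test.** Two-sided; `D` is the sup-norm ECDF gap computed on the
  pooled sample. The default p-value is the Kolmogorov limiting
  distribution evaluated at `sqrt(n1 n2/(n1+n2)) * D`; an exact p
  (lattice-path count over the C(n1+n2, n1) orderings) is available for
  `n1*n2 <= 10,000` on tie-free data. The asymptotic p is mildly
  conservative at decile-sized samples (~4–5% rejection at the nominal
  5%), which the null-calibration test accounts for by using a binomial
  acceptance band.
- **Paired read-length test.** Two-sided paired t on per-library mean
  read lengths. Degenerate conventions: all differences zero → (t=0, p=1);
  equal nonzero differences → (t=±inf, p=0).
- **Saturation.** Subsampling is without replacement; subsample size is
  round-half-away-from-zero of `p/100 × N`; each (library, percent) pair
  gets its own child seed stream so curves are reproducible and repeats
  independent; the 100% point is the full read set with SD exactly 0.
- **Spanning-CDS.** Only single-transcript protein-coding genes; a read
  spans when `start <= cds_start + slack` and `end >= cds_end - slack`
  with `slack = 0` by default; bins default to quintiles of observed CDS
  lengths (no canonical bin edges exist for this analysis).
- **Coordinates.** 0-based half-open throughout; BED12 is written
  natively, GFF3 converted to 1-based closed on write and back on read.
- **Seeding.** All randomness descends from one root seed through named
  `SeedSequence` child streams (per stage, per library, per saturation
  point); identical configuration + seed reproduces every output byte for
  byte.

## Problem sizes used in the test suite

Chosen as the smallest sizes at which each property is statistically
clean: the planted-recovery checks run one full default study (2000 genes,
5 × 200k reads); null calibration runs 100 seeds at 300 genes × 30k
reads/library with the selection curve flattened; accuracy and limit-case
checks use 200–800 genes. The saturation oracle uses a 376-read toy
library where the hypergeometric expectation is exactly computable.

## Known limitations

- Gene assignment is gene-level only; no splice-aware matching, isoform
  quantification, or multi-mapping rescue.
- The simulator emits transcript-span reads on a single chromosome without
  introns; exon-level overlap is unnecessary for it and untested against
  spliced annotations.
- The exact KS p-value uses floating-point path counts (relative error
  ~1e-12 at the permitted sizes) and declines data with cross-sample ties.
- `unidentified_fraction_curve` and the overlap table treat "identified"
  as ≥ 1 assigned read; they inherit any assignment bias.
- With `pseudocount_rpm = 0`, fold-change CDFs silently condition on genes
  detected in both libraries (the exclusion count is logged, not modeled).
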