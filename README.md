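# polyadrift

Poly(A)-selection bias analysis for Oxford Nanopore direct RNA sequencing
(dRNA-seq), with a ground-truthed forward simulator of tail-length-dependent
oligo-dT capture.

## The problem

dRNA-seq sequences native mRNA molecules 3′→5′ through a pore, attaching the
sequencing adapter via an oligo(dT) *splint* annealed to the poly(A) tail.
Before library preparation, most protocols additionally enrich mRNA on
oligo(dT) beads ("poly(A) selection"). Because bead binding efficiency grows
with tail length, selection preferentially captures long-tailed molecules.
For genes whose mRNAs carry *variable* tails — e.g. a subpopulation of
short-tailed molecules — selection does two things at once:

1. it inflates the gene's apparent mean tail length (the short subpopulation
   is censored), and
2. it depresses the gene's apparent expression (part of its molecules are
   simply lost), inconsistently across replicates.

`polyadrift` quantifies both effects from per-read tables of paired
selected/unselected libraries, and ships a simulator that plants the
phenomenon so every stage of the analysis can be validated against known
truth. It is aimed at people building or evaluating long-read RNA-seq
pipelines who need to know how much of a "differential expression" or
"tail-length shift" signal can be manufactured by the capture protocol
alone.

## The analysis

For a paired design (two biological samples, each with a selected and an
unselected library):

- reads are assigned to genes by maximal same-strand transcript-span overlap
  (requiring ≥ 50% of the read length), with a 5′-end-position fallback that
  rescues truncated/abortive reads; reads also need a unique best mapping
  and a successful tail-length call;
- per gene *g* and library, the mean called tail length and RPM
  (reads per gene per million assigned reads) are computed over genes with
  ≥ 80 reads;
- the per-sample tail shift Δᵢ(g) = mean tail(selected) − mean tail(unselected)
  is averaged across the two samples — the projection of (Δ₁, Δ₂) onto the
  replicate diagonal, up to a √2 factor — and genes are cut into
  equal-frequency deciles of this projected shift. Decile 10 holds the most
  tail-variable genes;
- differential capture is tested with a two-sample Kolmogorov–Smirnov test
  comparing log₂ RPM fold changes (selected/unselected) of decile 10 against
  deciles 1–9, and replicate noise with the same test on fold changes
  between two selected replicates of one sample.

The simulator draws each gene's tails from a Gaussian mixture (a planted
fraction of genes is bimodal, short mode ≈ 20 nt, long mode ≈ 120 nt),
captures molecules with probability
`base_capture · σ(slope · (tail − midpoint))` above a hard splint threshold
(unselected libraries: flat `base_capture` above the threshold), extends
reads 5′ from the transcript 3′ end with a per-nucleotide stop rate, and
adds multiplicative Gaussian noise to tail calls. See `docs/methods.md` for
the model details and defaults.

## Worked example

```python
import polyadrift as pa

genes  = pa.generate_annotation(400, seed=7)
truth  = pa.make_ground_truth(genes, seed=7)           # plants 10% bimodal-tail genes
config = pa.CaptureConfig(depth=50_000, seed=7)        # logistic capture, midpoint 40 nt
design = pa.default_design()                           # 2 samples x {selected, unselected} + 1 technical replicate
reads  = pa.simulate_experiment(genes, truth, config, design, seed=7)

assigned  = {lib: pa.assign_reads(df, genes).assigned for lib, df in reads.items()}
summaries = pa.summarize_experiment(assigned, min_reads=80)
results   = pa.SelectionBiasModel(summaries, design).fit()
print(results.summary())
```

prints

```
Poly(A) selection bias analysis
===============================================
decile-eligible genes                 395
median projected delta (nt)         0.999
decile 10 size                         39

Technique capture bias (KS, decile 10 vs 1-9; fc = selected/unselected RPM)
  sample A        D=0.1913  p=0.153  (n=39 vs 356); decile-10 median log2 fc -0.051
  sample B        D=0.3500  p=0.000364  (n=39 vs 356); decile-10 median log2 fc -0.079
Replicate variability (KS, decile 10 vs 1-9; fc = rep2/rep1 RPM)
  sample B        D=0.0896  p=0.94  (n=39 vs 356)
```

Reading this: 395 genes had ≥ 80 reads in all four paired libraries; the
median gene's mean tail is ~1 nt longer after selection (the global skew),
and the 39 most tail-variable genes (decile 10) are under-captured after
selection (negative median log₂ fold change), significantly so in sample B
at this small simulated depth. At the default study scale (2000 genes,
200k reads/library) both samples reject strongly and decile 10 is ~90%
planted bimodal genes. `results.tail_deltas` holds the per-gene table:

```
  gene_id  delta_rep1  delta_rep2  projected  decile
gene-0015   23.641159   12.829624  18.235391      10
gene-0123   10.066764   18.494885  14.280824      10
gene-0136   12.651234   15.503506  14.077370      10
```

The same workflow is available from the shell:

```bash
polyadrift run --out-dir reports --seed 0          # simulate + full report set
polyadrift assign --reads reads.tsv --annotation ann.bed --out assigned.tsv
polyadrift summarize --assigned assigned.tsv --min-reads 80 --out summary.tsv
```

`run` writes `tail_deltas.tsv`, `fold_changes.tsv`, `ks_results.tsv`,
saturation/overlap/biotype complexity tables, read-length ECDFs,
spanning-CDS tables and a provenance `manifest.json`.

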