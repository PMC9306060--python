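import numpy as np
import pandas as pd
import pytest

import polyadrift as pa


def make_reads(rows, library_id="lib1"):
    """Build a reads frame from (chrom, strand, start, end, tail_called,
    unique_best[, gene_id_true]) tuples."""
    recs = []
    for i, row in enumerate(rows):
        chrom, strand, start, end, tail, ub = row[:6]
        recs.append(
            {
                "read_id": f"r{i}",
                "library_id": library_id,
                "gene_id_true": row[6] if len(row) > 6 else np.nan,
                "chrom": chrom,
                "strand": strand,
                "start": start,
                "end": end,
                "read_length": end - start,
                "tail_true": tail if tail == tail else np.nan,
                "tail_called": tail,
                "unique_best": ub,
            }
        )
    return pd.DataFrame(recs)


@pytest.fixture(scope="session")
def toy_genes():
    """Hand-laid annotation: disjoint genes on both strands plus an
    overlapping same-strand pair for ambiguity cases."""
    return pd.DataFrame(
        {
            "gene_id": ["gA", "gB", "gC", "gD", "gE"],
            "chrom": ["chr1", "chr1", "chr1", "chr1", "chr1"],
            "strand": ["+", "+", "-", "+", "+"],
            "tx_start": [0, 1000, 3000, 5000, 5500],
            "tx_end": [1000, 1200, 4000, 6000, 6500],
            "cds_start": [100, 1020, 3100, 5100, 5600],
            "cds_end": [900, 1180, 3900, 5900, 6400],
            "biotype": ["protein_coding"] * 5,
            "n_transcripts": [1, 1, 1, 1, 1],
        }
    )


@pytest.fixture(scope="session")
def study_run():
    """One full simulated study at the default conditions (2000 genes, 10%
    bimodal tails, 200k reads/library, five-library paired design), pushed
    through assignment, summarization and the bias model."""
    seed = 1
    genes = pa.generate_annotation(2000, seed=seed)
    truth = pa.make_ground_truth(genes, seed=seed)
    config = pa.CaptureConfig(depth=200_000, seed=seed)
    design = pa.default_design()
    reads = pa.simulate_experiment(genes, truth, config, design, seed=seed)
    assignments = {lib: pa.assign_reads(df, genes) for lib, df in reads.items()}
    assigned = {lib: res.assigned for lib, res in assignments.items()}
    summaries = pa.summarize_experiment(assigned)
    results = pa.SelectionBiasModel(summaries, design).fit()
    return {
        "seed": seed,
        "genes": genes,
        "truth": truth,
        "config": config,
        "design": design,
        "reads": reads,
        "assignments": assignments,
        "assigned": assigned,
        "summaries": summaries,
        "results": results,
    }
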