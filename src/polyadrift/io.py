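"""Readers and writers for the pipeline's interchange formats.

Per-read tables are TSV with the schema in ``READS_COLUMNS`` (missing tail
calls serialized as ``NA``); annotations are BED12 (0-based half-open,
native) or GFF3 (converted to 1-based closed on write). Reads can also
round-trip through BAM, with tail lengths and assignment carried as
per-read tags.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam

from .simulate import READS_COLUMNS

__all__ = [
    "read_reads_table",
    "write_reads_tsv",
    "read_reads_tsv",
    "write_reads_bam",
    "read_reads_bam",
    "write_annotation",
    "read_annotation",
    "read_design",
    "write_summary_tsv",
    "read_summary_tsv",
]

_OPTIONAL_COLUMNS = ["gene_id_true", "tail_true", "gene_id", "assignment_method", "mapq"]

# BAM tag layout for the extended per-read information
_TAG_TAIL_CALLED = "tc"
_TAG_TAIL_TRUE = "tt"
_TAG_GENE_TRUE = "tg"
_TAG_GENE = "ga"
_TAG_METHOD = "am"
_TAG_UNIQUE_BEST = "ub"


def write_reads_tsv(reads: pd.DataFrame, path) -> None:
    cols = [c for c in READS_COLUMNS if c in reads.columns] + [
        c for c in _OPTIONAL_COLUMNS if c in reads.columns and c not in READS_COLUMNS
    ]
    out = reads[cols].copy()
    out["unique_best"] = out["unique_best"].astype(bool).map({True: "1", False: "0"})
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.3f")


def read_reads_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)
    required = [c for c in READS_COLUMNS if c not in ("gene_id_true", "tail_true")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for row, strand in enumerate(df["strand"], start=2):
        if strand not in ("+", "-"):
            raise ValueError(f"{path}: line {row}, column 'strand': bad symbol {strand!r}")
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise ValueError(
            f"{path}: line {int(bad[0]) + 2}, column 'start': start >= end"
        )
    if (df["read_length"] <= 0).any():
        row = int(df.index[df["read_length"] <= 0][0]) + 2
        raise ValueError(f"{path}: line {row}, column 'read_length': must be > 0")
    if (df["tail_called"].dropna() < 0).any():
        raise ValueError(f"{path}: column 'tail_called': negative tail call")
    df["unique_best"] = df["unique_best"].astype(int).astype(bool)
    return df


def read_reads_table(path, dialect: str | None = None) -> pd.DataFrame:
    """Dispatch on dialect ('tsv' or 'bam'; inferred from the suffix)."""
    if dialect is None:
        dialect = "bam" if str(path).endswith(".bam") else "tsv"
    if dialect == "tsv":
        return read_reads_tsv(path)
    if dialect == "bam":
        return read_reads_bam(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_reads_bam(reads: pd.DataFrame, path, chrom_lengths: dict[str, int]) -> None:
    """Write reads as an unaligned-sequence BAM with extended tags."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in chrom_lengths.items()],
        "RG": [{"ID": lib} for lib in pd.unique(reads["library_id"])],
    }
    refs = {c: i for i, c in enumerate(chrom_lengths)}
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for row in reads.itertuples(index=False):
            a = pysam.AlignedSegment(bam.header)
            a.query_name = row.read_id
            a.reference_id = refs[row.chrom]
            a.reference_start = int(row.start)
            a.flag = 16 if row.strand == "-" else 0
            a.mapping_quality = int(getattr(row, "mapq", 60))
            a.cigartuples = [(0, int(row.end - row.start))]
            tags = [
                ("RG", row.library_id),
                (_TAG_UNIQUE_BEST, int(bool(row.unique_best))),
            ]
            if not pd.isna(row.tail_called):
                tags.append((_TAG_TAIL_CALLED, float(row.tail_called)))
            if hasattr(row, "tail_true") and not pd.isna(row.tail_true):
                tags.append((_TAG_TAIL_TRUE, float(row.tail_true)))
            if hasattr(row, "gene_id_true") and not pd.isna(row.gene_id_true):
                tags.append((_TAG_GENE_TRUE, str(row.gene_id_true)))
            if hasattr(row, "gene_id") and not pd.isna(row.gene_id):
                tags.append((_TAG_GENE, str(row.gene_id)))
            if hasattr(row, "assignment_method") and not pd.isna(row.assignment_method):
                tags.append((_TAG_METHOD, str(row.assignment_method)))
            a.set_tags(tags)
            bam.write(a)


def read_reads_bam(path) -> pd.DataFrame:
    rows = []
    with pysam.AlignmentFile(str(path), "rb", check_sq=False) as bam:
        for a in bam:
            end = a.reference_end if a.reference_end is not None else a.reference_start
            rows.append(
                {
                    "read_id": a.query_name,
                    "library_id": a.get_tag("RG"),
                    "gene_id_true": a.get_tag(_TAG_GENE_TRUE) if a.has_tag(_TAG_GENE_TRUE) else np.nan,
                    "chrom": a.reference_name,
                    "strand": "-" if a.is_reverse else "+",
                    "start": a.reference_start,
                    "end": end,
                    "read_length": end - a.reference_start,
                    "tail_true": a.get_tag(_TAG_TAIL_TRUE) if a.has_tag(_TAG_TAIL_TRUE) else np.nan,
                    "tail_called": a.get_tag(_TAG_TAIL_CALLED) if a.has_tag(_TAG_TAIL_CALLED) else np.nan,
                    "unique_best": bool(a.get_tag(_TAG_UNIQUE_BEST)) if a.has_tag(_TAG_UNIQUE_BEST) else True,
                    "mapq": a.mapping_quality,
                }
            )
    df = pd.DataFrame(rows)
    if "gene_id" not in df.columns:
        for a_col in ("gene_id", "assignment_method"):
            df[a_col] = np.nan
    return df


# ---------------------------------------------------------------------------
# Annotation

_ANN_COLUMNS = [
    "gene_id", "chrom", "strand", "tx_start", "tx_end",
    "cds_start", "cds_end", "biotype", "n_transcripts",
]


def write_annotation(genes: pd.DataFrame, path) -> None:
    path = str(path)
    if path.endswith(".bed"):
        _write_bed12(genes, path)
    elif path.endswith((".gff3", ".gff")):
        _write_gff3(genes, path)
    else:
        raise ValueError(f"unknown annotation format for {path}")


def read_annotation(path) -> pd.DataFrame:
    path = str(path)
    if path.endswith(".bed"):
        return _read_bed12(path)
    if path.endswith((".gff3", ".gff")):
        return _read_gff3(path)
    raise ValueError(f"unknown annotation format for {path}")


def _write_bed12(genes: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        for g in genes.itertuples(index=False):
            span = int(g.tx_end - g.tx_start)
            fields = [
                g.chrom, int(g.tx_start), int(g.tx_end),
                f"{g.gene_id}|{g.biotype}|{int(g.n_transcripts)}",
                0, g.strand, int(g.cds_start), int(g.cds_end),
                "0,0,0", 1, f"{span},", "0,",
            ]
            fh.write("\t".join(str(f) for f in fields) + "\n")


def _read_bed12(path: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            name = f[3].split("|")
            rows.append(
                {
                    "gene_id": name[0],
                    "chrom": f[0],
                    "strand": f[5],
                    "tx_start": int(f[1]),
                    "tx_end": int(f[2]),
                    "cds_start": int(f[6]),
                    "cds_end": int(f[7]),
                    "biotype": name[1] if len(name) > 1 else "other",
                    "n_transcripts": int(name[2]) if len(name) > 2 else 1,
                }
            )
    return pd.DataFrame(rows, columns=_ANN_COLUMNS)


def _write_gff3(genes: pd.DataFrame, path: str) -> None:
    # GFF3 is 1-based closed: start+1, end unchanged
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.itertuples(index=False):
            attrs = f"ID={g.gene_id};gene_biotype={g.biotype};n_transcripts={int(g.n_transcripts)}"
            fh.write(
                f"{g.chrom}\tpolyadrift\tgene\t{int(g.tx_start) + 1}\t{int(g.tx_end)}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.chrom}\tpolyadrift\tmRNA\t{int(g.tx_start) + 1}\t{int(g.tx_end)}\t.\t{g.strand}\t.\tID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            if g.cds_end > g.cds_start:
                fh.write(
                    f"{g.chrom}\tpolyadrift\tCDS\t{int(g.cds_start) + 1}\t{int(g.cds_end)}\t.\t{g.strand}\t.\tID={g.gene_id}.cds;Parent={g.gene_id}.t1\n"
                )


def _parse_gff_attrs(s: str) -> dict[str, str]:
    out = {}
    for part in s.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def _read_gff3(path: str) -> pd.DataFrame:
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}: malformed GFF3 line: {line!r}")
            ftype = f[2]
            attrs = _parse_gff_attrs(f[8])
            start, end = int(f[3]) - 1, int(f[4])
            if ftype == "gene":
                gid = attrs["ID"]
                genes[gid] = {
                    "gene_id": gid,
                    "chrom": f[0],
                    "strand": f[6],
                    "tx_start": start,
                    "tx_end": end,
                    "cds_start": start,
                    "cds_end": start,
                    "biotype": attrs.get("gene_biotype", "other"),
                    "n_transcripts": int(attrs.get("n_transcripts", 1)),
                }
            elif ftype == "CDS":
                gid = attrs.get("Parent", "").rsplit(".t1", 1)[0]
                if gid in genes:
                    genes[gid]["cds_start"] = start
                    genes[gid]["cds_end"] = end
    return pd.DataFrame(list(genes.values()), columns=_ANN_COLUMNS)


# ---------------------------------------------------------------------------
# Design & summaries

def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"library_id", "sample_id", "technique", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: design table missing columns {sorted(missing)}")
    bad = set(df["technique"]) - {"selected", "unselected"}
    if bad:
        raise ValueError(f"{path}: unknown technique values {sorted(bad)}")
    if df.duplicated(["sample_id", "technique", "replicate"]).any():
        raise ValueError(f"{path}: duplicate (sample, technique, replicate) rows")
    return df


def write_summary_tsv(summaries: pd.DataFrame, path) -> None:
    summaries.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_summary_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if "passes_min_reads" in df.columns:
        df["passes_min_reads"] = df["passes_min_reads"].astype(bool)
    return df
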