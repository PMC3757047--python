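"""Flat-file I/O: FASTA/FASTQ via Biopython, GFF3 and bedGraph as tabular text.

All sequence containers are plain ``dict[str, str]`` keyed by sequence name;
annotations are pandas DataFrames with 1-based inclusive coordinates
(converted from/to the native convention of each format at the boundary).
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GFF3_COLUMNS = [
    "seqid", "source", "type", "start", "end",
    "score", "strand", "phase", "attributes",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, seqs: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str]]) -> None:
    """Write (id, sequence) pairs as FASTQ with uniform placeholder qualities."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read GFF3 into a DataFrame (1-based inclusive, as GFF3 itself)."""
    df = pd.read_csv(
        str(path), sep="\t", comment="#", header=None, names=GFF3_COLUMNS,
        dtype={"seqid": str}, na_filter=False,
    )
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_gff3(path: str | Path, df: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        df.to_csv(fh, sep="\t", header=False, index=False, columns=GFF3_COLUMNS)


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read bedGraph (0-based half-open) into columns chrom/start/end/value."""
    df = pd.read_csv(
        str(path), sep="\t", header=None,
        names=["chrom", "start", "end", "value"],
        comment="#", dtype={"chrom": str},
    )
    return df


def write_bedgraph(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(str(path), sep="\t", header=False, index=False,
              columns=["chrom", "start", "end", "value"])


def write_bed(path: str | Path, rows: Iterable[tuple], *, one_based: bool = True) -> None:
    """Write (chrom, start, end, name) rows as BED.

    With ``one_based=True`` the input coordinates are 1-based inclusive and are
    converted to BED's 0-based half-open convention.
    """
    with open(path, "w") as fh:
        for row in rows:
            chrom, start, end, *rest = row
            if one_based:
                start, end = start - 1, end
            fields = [str(chrom), str(start), str(end)] + [str(x) for x in rest]
            fh.write("\t".join(fields) + "\n")
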