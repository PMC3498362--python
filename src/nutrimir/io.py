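"""Readers and writers for the flat formats the pipeline exchanges.

FASTA/FASTQ parsing goes through Biopython; GFF3 and the tabular formats are
plain TSV handled with pandas. Genomic coordinates are 0-based half-open
internally; GFF3 I/O converts to/from 1-based inclusive at this boundary only.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import pandas as pd
from Bio import SeqIO

from ._util import normalize_seq

PathLike = Union[str, Path]


@dataclass(frozen=True, order=True)
class GenomeLocus:
    """Stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int  # inclusive
    end: int  # exclusive
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AnnotationRecord:
    """Genomic feature carrying an RNA-class label."""

    locus: GenomeLocus
    rna_class: str  # rRNA / tRNA / snRNA / snoRNA / mRNA / other-feature
    feature_id: str


RNA_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA", "mRNA", "other-feature")


def read_fasta(path_or_text: PathLike, *, is_text: bool = False) -> dict[str, str]:
    """Read FASTA into an ordered {name: sequence} dict (DNA-normalized)."""
    handle = _stdio.StringIO(path_or_text) if is_text else open(path_or_text)
    try:
        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate sequence name {rec.id!r}")
            seqs[rec.id] = normalize_seq(str(rec.seq))
        return seqs
    finally:
        handle.close()


def write_fasta(seqs: dict[str, str], path: PathLike | None = None, width: int = 70) -> str:
    lines = []
    for name, seq in seqs.items():
        lines.append(f">{name}")
        for i in range(0, len(seq), width):
            lines.append(seq[i : i + width])
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def read_reads(path: PathLike) -> list[str]:
    """Read a small-RNA library (FASTQ, or FASTA with optional ``name-count`` headers).

    Returns the expanded list of raw read sequences: a FASTA header whose last
    ``-``-separated field is an integer replicates the sequence that many times.
    """
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    reads: list[str] = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            seq = normalize_seq(str(rec.seq))
            n = 1
            if fmt == "fasta" and "-" in rec.id:
                tail = rec.id.rsplit("-", 1)[1]
                if tail.isdigit():
                    n = int(tail)
            reads.extend([seq] * n)
    return reads


def write_fastq(reads: Iterable[str], path: PathLike) -> None:
    """Write reads as FASTQ with constant quality 'I' (quality is never used)."""
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@read{i}\n{seq}\n+\n{'I' * len(seq)}\n")


# --- GFF3 ---------------------------------------------------------------

_GFF_COLS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def read_gff3(path: PathLike) -> list[AnnotationRecord]:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=_GFF_COLS,
        dtype={"seqid": str, "type": str, "strand": str, "attributes": str},
    )
    records = []
    for row in df.itertuples(index=False):
        attrs = dict(
            kv.split("=", 1) for kv in str(row.attributes).split(";") if "=" in kv
        )
        fid = attrs.get("ID", f"{row.type}:{row.seqid}:{row.start}")
        records.append(
            AnnotationRecord(
                locus=GenomeLocus(str(row.seqid), int(row.start) - 1, int(row.end), row.strand),
                rna_class=str(row.type),
                feature_id=fid,
            )
        )
    return records


def write_gff3(records: Iterable[AnnotationRecord], path: PathLike | None = None) -> str:
    lines = ["##gff-version 3"]
    for rec in records:
        loc = rec.locus
        lines.append(
            "\t".join(
                [
                    loc.chrom, "nutrimir", rec.rna_class,
                    str(loc.start + 1), str(loc.end), ".", loc.strand, ".",
                    f"ID={rec.feature_id}",
                ]
            )
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# --- Degradome tags ------------------------------------------------------


def read_degradome(path: PathLike) -> pd.DataFrame:
    """3-column TSV: transcript, pos_1based, count."""
    df = pd.read_csv(path, sep="\t")
    expected = {"transcript", "pos_1based", "count"}
    if not expected.issubset(df.columns):
        raise ValueError(f"degradome table must have columns {sorted(expected)}")
    return df


def write_tsv(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)
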