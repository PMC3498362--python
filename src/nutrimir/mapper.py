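"""Perfect-match placement of tags on both genome strands.

The index is a k-mer seed table (seed length = the shortest query supported)
with verification by direct string comparison, so every reported locus is an
exact match by construction. Tags map on the forward strand as-is and on the
reverse strand via reverse complement; positions containing N never match.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._util import normalize_seq, revcomp
from .io import GenomeLocus
from .preprocess import ReadTagTable

MIN_QUERY = 15
MAX_QUERY = 35


@dataclass
class GenomeIndex:
    chroms: dict[str, str]
    seed_len: int = MIN_QUERY
    _seeds: dict[str, list[tuple[str, int]]] = field(repr=False, default_factory=dict)

    def lookup(self, query: str) -> list[tuple[str, int]]:
        """All (chrom, start) forward-strand occurrences of ``query``."""
        query = normalize_seq(query)
        if not query or len(query) > MAX_QUERY:
            raise ValueError(f"query length {len(query)} outside [1, {MAX_QUERY}]")
        if "N" in query:
            return []
        if len(query) < self.seed_len:
            # sub-seed queries fall back to a direct scan (rare; tiny genomes)
            hits = []
            for chrom, seq in self.chroms.items():
                start = seq.find(query)
                while start >= 0:
                    if "N" not in seq[start : start + len(query)]:
                        hits.append((chrom, start))
                    start = seq.find(query, start + 1)
            return sorted(hits)
        hits = []
        for chrom, pos in self._seeds.get(query[: self.seed_len], ()):
            if self.chroms[chrom].startswith(query, pos):
                hits.append((chrom, pos))
        return hits


@dataclass
class MappedTag:
    sequence: str
    loci: list[GenomeLocus]

    @property
    def n_loci(self) -> int:
        return len(self.loci)


def build_index(chroms: dict[str, str], seed_len: int = MIN_QUERY) -> GenomeIndex:
    """Index every seed_len-mer of the genome. Seeds containing N are skipped."""
    if len(set(chroms)) != len(chroms):
        raise ValueError("duplicate chromosome names")
    norm = {name: normalize_seq(seq) for name, seq in chroms.items()}
    seeds: dict[str, list[tuple[str, int]]] = {}
    for name, seq in norm.items():
        for i in range(len(seq) - seed_len + 1):
            kmer = seq[i : i + seed_len]
            if "N" in kmer:
                continue
            seeds.setdefault(kmer, []).append((name, i))
    return GenomeIndex(chroms=norm, seed_len=seed_len, _seeds=seeds)


def locate_tag(sequence: str, index: GenomeIndex) -> MappedTag:
    """All perfect-match loci of one tag on both strands."""
    sequence = normalize_seq(sequence)
    loci = [
        GenomeLocus(chrom, pos, pos + len(sequence), "+")
        for chrom, pos in index.lookup(sequence)
    ]
    rc = revcomp(sequence)
    loci += [
        GenomeLocus(chrom, pos, pos + len(sequence), "-")
        for chrom, pos in index.lookup(rc)
    ]
    loci.sort(key=lambda l: (l.chrom, l.start, l.strand))
    return MappedTag(sequence, loci)


def locate(
    table: ReadTagTable, index: GenomeIndex
) -> tuple[list[MappedTag], list[str], pd.DataFrame]:
    """Map every tag in the table.

    Returns (mapped tags, unmapped tag sequences, per-library mapping summary).
    Tags with zero loci are excluded from all downstream analysis; multi-mapping
    tags are counted once per tag, with n_loci carried for reporting.
    """
    mapped: list[MappedTag] = []
    unmapped: list[str] = []
    stats = {
        "A": {"total": 0, "mapped": 0},
        "B": {"total": 0, "mapped": 0},
    }
    for row in table.df.itertuples(index=False):
        tag = locate_tag(row.sequence, index)
        stats["A"]["total"] += row.count_A
        stats["B"]["total"] += row.count_B
        if tag.loci:
            mapped.append(tag)
            stats["A"]["mapped"] += row.count_A
            stats["B"]["mapped"] += row.count_B
        else:
            unmapped.append(row.sequence)
    summary = pd.DataFrame(
        [
            {
                "library": lib,
                "clean_reads": s["total"],
                "mapped_reads": s["mapped"],
                "mapped_fraction": (s["mapped"] / s["total"]) if s["total"] else 0.0,
            }
            for lib, s in stats.items()
        ]
    )
    return mapped, unmapped, summary


def mapped_table(table: ReadTagTable, mapped: list[MappedTag]) -> ReadTagTable:
    """Restrict a tag table to mapped sequences (downstream contract)."""
    keep = {t.sequence for t in mapped}
    df = table.df[table.df["sequence"].isin(keep)].reset_index(drop=True)
    return ReadTagTable(df, raw_reads=dict(table.raw_reads))


def mapping_frame(mapped: list[MappedTag]) -> pd.DataFrame:
    """Flat per-locus TSV view (sequence, chrom, start0, end, strand, n_loci)."""
    rows = []
    for tag in mapped:
        for loc in tag.loci:
            rows.append(
                {
                    "sequence": tag.sequence,
                    "chrom": loc.chrom,
                    "start0": loc.start,
                    "end": loc.end,
                    "strand": loc.strand,
                    "n_loci": tag.n_loci,
                }
            )
    return pd.DataFrame(
        rows, columns=["sequence", "chrom", "start0", "end", "strand", "n_loci"]
    )
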