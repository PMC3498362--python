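"""RNA-class annotation of mapped tags and library-level composition summaries.

A tag inherits the class of any annotated structural-RNA feature one of its
loci overlaps (>= 1 bp, strand-aware by default). When loci touch several
classes the fixed precedence rRNA > tRNA > snRNA > snoRNA decides; everything
else is "other". The class summary mirrors the standard per-library
composition table (unique and total counts with percentages), and the overlap
summary compares which tags the two libraries share.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from ._util import percent_mixed_precision
from .io import AnnotationRecord
from .mapper import MappedTag
from .preprocess import ReadTagTable

STRUCTURAL_PRECEDENCE = ("rRNA", "tRNA", "snRNA", "snoRNA")
OTHER = "other"


def classify_tag(
    tag: MappedTag,
    annotations: Iterable[AnnotationRecord],
    stranded: bool = True,
) -> str:
    """RNA class of one mapped tag under the fixed precedence order."""
    if not tag.loci:
        raise ValueError("tag has no loci")
    hit_classes = set()
    for rec in annotations:
        if rec.rna_class not in STRUCTURAL_PRECEDENCE:
            continue
        a = rec.locus
        for loc in tag.loci:
            if loc.chrom != a.chrom:
                continue
            if stranded and loc.strand != a.strand:
                continue
            if loc.start < a.end and a.start < loc.end:  # >= 1 bp overlap
                hit_classes.add(rec.rna_class)
    for cls in STRUCTURAL_PRECEDENCE:
        if cls in hit_classes:
            return cls
    return OTHER


def classify_tags(
    tags: Iterable[MappedTag],
    annotations: Iterable[AnnotationRecord],
    stranded: bool = True,
) -> dict[str, str]:
    """sequence -> class for every mapped tag."""
    annotations = list(annotations)
    return {t.sequence: classify_tag(t, annotations, stranded) for t in tags}


def class_summary(table: ReadTagTable, classes: Mapping[str, str]) -> pd.DataFrame:
    """Per-class unique/total counts and percentages per library, plus a totals row.

    Percentages use the mixed-precision dialect (2 decimals below 10%, 1 at or
    above); the totals row equals the column sums exactly.
    """
    df = table.df
    if df.empty or (df["count_A"].sum() == 0 and df["count_B"].sum() == 0):
        raise ValueError("empty_library")
    cls = df["sequence"].map(lambda s: classes.get(s, OTHER))
    order = list(STRUCTURAL_PRECEDENCE) + [OTHER]
    rows = []
    tot = {
        "unique_A": int((df["count_A"] > 0).sum()),
        "unique_B": int((df["count_B"] > 0).sum()),
        "total_A": int(df["count_A"].sum()),
        "total_B": int(df["count_B"].sum()),
    }
    for c in order:
        sub = df[cls == c]
        row = {
            "class": c,
            "unique_A": int((sub["count_A"] > 0).sum()),
            "unique_B": int((sub["count_B"] > 0).sum()),
            "total_A": int(sub["count_A"].sum()),
            "total_B": int(sub["count_B"].sum()),
        }
        for k in ("unique_A", "unique_B", "total_A", "total_B"):
            denom = tot[k]
            row[f"{k}_pct"] = (
                percent_mixed_precision(100.0 * row[k] / denom) if denom else 0.0
            )
        rows.append(row)
    total_row = {"class": "total", **tot}
    for k in ("unique_A", "unique_B", "total_A", "total_B"):
        total_row[f"{k}_pct"] = 100.0
    rows.append(total_row)
    return pd.DataFrame(rows)


def summary_from_counts(
    unique: Mapping[str, tuple[int, int]] | None = None,
    total: Mapping[str, tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Class summary computed directly from per-class (A, B) count pairs.

    Accepts externally tabulated composition counts (e.g. a published summary
    table) and applies the same totals/percentage arithmetic as class_summary.
    """
    order = list(STRUCTURAL_PRECEDENCE) + [OTHER]
    unique = dict(unique or {})
    total = dict(total or {})
    counts = {
        "unique_A": {c: unique.get(c, (0, 0))[0] for c in order},
        "unique_B": {c: unique.get(c, (0, 0))[1] for c in order},
        "total_A": {c: total.get(c, (0, 0))[0] for c in order},
        "total_B": {c: total.get(c, (0, 0))[1] for c in order},
    }
    sums = {k: sum(v.values()) for k, v in counts.items()}
    rows = []
    for c in order:
        row = {"class": c}
        for k in counts:
            row[k] = counts[k][c]
            row[f"{k}_pct"] = (
                percent_mixed_precision(100.0 * counts[k][c] / sums[k])
                if sums[k]
                else 0.0
            )
        rows.append(row)
    rows.append({"class": "total", **sums, **{f"{k}_pct": 100.0 for k in counts}})
    return pd.DataFrame(rows)


def library_overlap(table: ReadTagTable) -> pd.DataFrame:
    """A-specific / B-specific / common tag shares, as unique-% and total-read-%.

    A sequence is common iff it has nonzero counts in both libraries. Total
    percentages use the combined read total as denominator; common sequences
    contribute their counts from both libraries.
    """
    df = table.df
    in_a = df["count_A"] > 0
    in_b = df["count_B"] > 0
    n_seqs = int((in_a | in_b).sum())
    total_reads = int(df["count_A"].sum() + df["count_B"].sum())
    parts = {
        "A_specific": in_a & ~in_b,
        "B_specific": in_b & ~in_a,
        "common": in_a & in_b,
    }
    rows = []
    for name, mask in parts.items():
        sub = df[mask]
        uniq = int(mask.sum())
        reads = int(sub["count_A"].sum() + sub["count_B"].sum())
        rows.append(
            {
                "subset": name,
                "unique_sequences": uniq,
                "unique_pct": round(100.0 * uniq / n_seqs, 2) if n_seqs else 0.0,
                "total_reads": reads,
                "total_pct": round(100.0 * reads / total_reads, 2) if total_reads else 0.0,
            }
        )
    return pd.DataFrame(rows)
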