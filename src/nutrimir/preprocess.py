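"""Adapter trimming, read collapsing and length profiling.

Raw small-RNA reads carry the 3' sequencing adapter; the insert is the read
prefix preceding the leftmost adapter occurrence (a full match anywhere in the
read, or a >= min_overlap prefix of the adapter flush with the read's 3' end).
Trimmed, length-filtered inserts from both condition libraries are collapsed
into a table of unique tags with per-library counts — the unit every
downstream stage quantifies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from ._util import normalize_seq

DEFAULT_MIN_LEN = 18
DEFAULT_MAX_LEN = 30
DEFAULT_MIN_OVERLAP = 8


@dataclass
class TrimResult:
    insert: str | None
    reason: str | None = None  # None on success

    @property
    def ok(self) -> bool:
        return self.insert is not None


@dataclass
class ReadTagTable:
    """Collapsed unique tags with per-library counts.

    ``df`` columns: sequence, count_A, count_B — sorted by descending combined
    count then lexicographically, so collapsing is deterministic.
    """

    df: pd.DataFrame
    raw_reads: dict[str, int] = field(default_factory=dict)

    @property
    def total_A(self) -> int:
        return int(self.df["count_A"].sum())

    @property
    def total_B(self) -> int:
        return int(self.df["count_B"].sum())

    def counts(self, sequence: str) -> tuple[int, int]:
        row = self.df[self.df["sequence"] == sequence]
        if row.empty:
            return (0, 0)
        return int(row["count_A"].iloc[0]), int(row["count_B"].iloc[0])


def trim_adapter(
    read: str,
    adapter3: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    adapter5: str | None = None,
) -> TrimResult:
    """Trim the 3' adapter off one read; reject with a reason when impossible.

    Rejection reasons: ``empty``, ``adapter5``, ``no_adapter``, ``too_short``,
    ``too_long``.
    """
    if min_overlap < 1 or len(adapter3) < min_overlap:
        raise ValueError("adapter3 length must be >= min_overlap >= 1")
    read = normalize_seq(read)
    if not read:
        return TrimResult(None, "empty")
    adapter3 = normalize_seq(adapter3)
    if adapter5 and normalize_seq(adapter5) in read:
        # two-adapter ligation artifact: insert-free read carrying the 5' adapter
        return TrimResult(None, "adapter5")

    cut = read.find(adapter3)
    if cut < 0:
        # partial adapter at the 3' end: longest adapter prefix that is a read suffix
        for k in range(min(len(adapter3) - 1, len(read)), min_overlap - 1, -1):
            if read.endswith(adapter3[:k]):
                cut = len(read) - k
                break
    if cut < 0:
        return TrimResult(None, "no_adapter")
    insert = read[:cut]
    if len(insert) < min_len:
        return TrimResult(None, "too_short")
    if len(insert) > max_len:
        return TrimResult(None, "too_long")
    return TrimResult(insert)


def trim_library(
    reads: Iterable[str],
    adapter3: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    adapter5: str | None = None,
) -> tuple[list[str], Counter]:
    """Trim every read; return (clean inserts, rejection-reason tally)."""
    inserts: list[str] = []
    rejected: Counter = Counter()
    for read in reads:
        res = trim_adapter(read, adapter3, min_overlap, min_len, max_len, adapter5)
        if res.ok:
            inserts.append(res.insert)
        else:
            rejected[res.reason] += 1
    return inserts, rejected


def collapse_reads(inserts_a: Sequence[str], inserts_b: Sequence[str]) -> ReadTagTable:
    """Collapse trimmed inserts from both libraries into one unique-tag table."""
    ca = Counter(normalize_seq(s) for s in inserts_a)
    cb = Counter(normalize_seq(s) for s in inserts_b)
    seqs = sorted(set(ca) | set(cb), key=lambda s: (-(ca[s] + cb[s]), s))
    df = pd.DataFrame(
        {
            "sequence": seqs,
            "count_A": [ca[s] for s in seqs],
            "count_B": [cb[s] for s in seqs],
        }
    )
    return ReadTagTable(df, raw_reads={"A": len(inserts_a), "B": len(inserts_b)})


def length_profile(
    table: ReadTagTable,
    window: tuple[int, int] = (19, 24),
    lengths: tuple[int, int] = (15, 35),
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-length unique/total counts per library, plus the in-window read fraction.

    The window fraction mirrors the headline statistic that 19–24-nt tags
    dominate a genuine small-RNA library.
    """
    if table.df.empty:
        raise ValueError("empty_library")
    df = table.df.assign(length=table.df["sequence"].str.len())
    lo, hi = lengths
    rows = []
    for length in range(lo, hi + 1):
        sub = df[df["length"] == length]
        rows.append(
            {
                "length": length,
                "unique_A": int((sub["count_A"] > 0).sum()),
                "unique_B": int((sub["count_B"] > 0).sum()),
                "total_A": int(sub["count_A"].sum()),
                "total_B": int(sub["count_B"].sum()),
            }
        )
    profile = pd.DataFrame(rows)
    wlo, whi = window
    in_win = df[(df["length"] >= wlo) & (df["length"] <= whi)]
    fractions = {}
    for lib, col in (("A", "count_A"), ("B", "count_B"), ("combined", None)):
        if col is None:
            tot = df["count_A"].sum() + df["count_B"].sum()
            win = in_win["count_A"].sum() + in_win["count_B"].sum()
        else:
            tot = df[col].sum()
            win = in_win[col].sum()
        fractions[lib] = float(win / tot) if tot else 0.0
    return profile, fractions
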