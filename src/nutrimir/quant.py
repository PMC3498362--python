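"""Member-resolved miRNA quantification, normalization and response classification.

Tags are assigned to mature miRNAs by full-length perfect identity, so members
of one family differing by a single nucleotide are quantified separately, and
members sharing an identical mature sequence are merged into one group (named
miR169d-g style). Abundances normalize to reads per million (RPM); differential
response between the two conditions is a log2 fold change of B over A with a
+1 pseudocount applied to both raw counts when either is zero, classified into
suppressed (NSS) / induced (NSI) / unchanged by a strict fold-ratio threshold.
"""

from __future__ import annotations

import math
import re
from typing import Mapping, Sequence

import pandas as pd

from ._util import normalize_seq, round_half_away
from .preprocess import ReadTagTable

NSS = "NSS"  # suppressed in condition B relative to A
NSI = "NSI"  # induced in condition B relative to A
UNCHANGED = "unchanged"

DEFAULT_KNOWN_RATIO = 3.0  # "greater than 3-fold" rule for known miRNAs
DEFAULT_NOVEL_RATIO = 2.0  # ratio > 2 rule for novel candidates
DEFAULT_MIN_EVIDENCE = 5  # combined-count floor below which no call is made


def group_members(mature: Mapping[str, str]) -> dict[str, str]:
    """Merge members with identical mature sequences into named groups.

    Returns {group name: sequence}. Same-family members whose suffix letters
    are consecutive compress to a range (miR169d,e,f,g -> miR169d-g); otherwise
    names join with '/'.
    """
    if len(set(mature)) != len(mature):
        raise ValueError("duplicate member names")
    by_seq: dict[str, list[str]] = {}
    for name, seq in mature.items():
        by_seq.setdefault(normalize_seq(seq), []).append(name)
    groups = {}
    for seq, names in by_seq.items():
        groups[_group_name(sorted(names))] = seq
    return groups


def _group_name(names: list[str]) -> str:
    if len(names) == 1:
        return names[0]
    m = [re.fullmatch(r"(.*?)([a-z])", n) for n in names]
    if all(m) and len({x.group(1) for x in m}) == 1:
        letters = sorted(x.group(2) for x in m)
        if all(ord(b) - ord(a) == 1 for a, b in zip(letters, letters[1:])):
            return f"{m[0].group(1)}{letters[0]}-{letters[-1]}"
    return "/".join(names)


def match_known(table: ReadTagTable, mature: Mapping[str, str]) -> pd.DataFrame:
    """Per-member-group counts: a tag counts iff it equals the mature sequence.

    Unmatched member groups get zero rows, so low/absent miRNAs stay visible.
    """
    groups = group_members(mature)
    counts = {
        normalize_seq(r.sequence): (int(r.count_A), int(r.count_B))
        for r in table.df.itertuples(index=False)
    }
    rows = []
    for gname in sorted(groups):
        seq = groups[gname]
        a, b = counts.get(seq, (0, 0))
        rows.append({"id": gname, "sequence": seq, "count_A": a, "count_B": b})
    return pd.DataFrame(rows, columns=["id", "sequence", "count_A", "count_B"])


def rpm(count: int, library_total: int) -> float:
    if library_total <= 0:
        raise ValueError("library total must be > 0")
    return round_half_away(count / library_total * 1e6, 2)


def rpm_normalize(records: pd.DataFrame, total_a: int, total_b: int) -> pd.DataFrame:
    out = records.copy()
    out["rpm_A"] = [rpm(c, total_a) for c in out["count_A"]]
    out["rpm_B"] = [rpm(c, total_b) for c in out["count_B"]]
    return out


def log2_fold_change(
    count_a: float,
    count_b: float,
    mode: str = "raw",
    rpm_totals: tuple[int, int] | None = None,
    rounded: bool = True,
) -> float:
    """log2(B/A), with +1 added to BOTH raw counts when either is zero.

    ``raw`` mode ratios the counts directly; ``rpm`` mode ratios per-million
    normalized abundances. Rounding is half-away-from-zero to 1 decimal.
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be >= 0")
    if count_a == 0 and count_b == 0:
        raise ValueError("no_signal")
    a, b = count_a, count_b
    if a == 0 or b == 0:
        a, b = a + 1, b + 1
    if mode == "rpm":
        if rpm_totals is None:
            raise ValueError("rpm mode needs rpm_totals=(total_A, total_B)")
        ta, tb = rpm_totals
        a, b = a / ta * 1e6, b / tb * 1e6
    elif mode != "raw":
        raise ValueError(f"unknown mode {mode!r}")
    lfc = math.log2(b / a)
    return round_half_away(lfc, 1) if rounded else lfc


def classify_response(log2fc: float, ratio_threshold: float) -> str:
    """NSI / NSS / unchanged under strict |fold| > threshold inequalities."""
    if ratio_threshold <= 1:
        raise ValueError("ratio_threshold must be > 1")
    cut = math.log2(ratio_threshold)
    if log2fc > cut:
        return NSI
    if log2fc < -cut:
        return NSS
    return UNCHANGED


def expression_table(
    records: pd.DataFrame,
    total_a: int,
    total_b: int,
    ratio_threshold: float = DEFAULT_KNOWN_RATIO,
    min_evidence: int = DEFAULT_MIN_EVIDENCE,
    fold_mode: str = "raw",
) -> pd.DataFrame:
    """Full expression records: counts -> RPM -> log2fc -> response class.

    Rows with combined count below ``min_evidence`` are flagged low_count and
    receive no response call. Zero-signal rows get NA fold and no call.
    """
    out = rpm_normalize(records, total_a, total_b)
    folds, resp, low = [], [], []
    for r in out.itertuples(index=False):
        lowc = (r.count_A + r.count_B) < min_evidence
        low.append(lowc)
        if r.count_A == 0 and r.count_B == 0:
            folds.append(float("nan"))
            resp.append(pd.NA)
            continue
        exact = log2_fold_change(
            r.count_A, r.count_B, mode=fold_mode,
            rpm_totals=(total_a, total_b), rounded=False,
        )
        folds.append(round_half_away(exact, 1))
        resp.append(pd.NA if lowc else classify_response(exact, ratio_threshold))
    out["log2fc"] = folds
    out["response"] = resp
    out["low_count"] = low
    return out


def family_aggregate(
    records: pd.DataFrame, family_map: Mapping[str, str]
) -> pd.DataFrame:
    """Sum member counts per family. Every member id must map to a family."""
    missing = [i for i in records["id"] if i not in family_map]
    if missing:
        raise ValueError(f"members without family mapping: {missing}")
    fam = records.assign(family=records["id"].map(family_map))
    agg = (
        fam.groupby("family", as_index=False)[["count_A", "count_B"]]
        .sum()
        .sort_values("family")
        .reset_index(drop=True)
    )
    return agg


def count_responsive(
    count_pairs: Sequence[tuple[float, float]], ratio_threshold: float = DEFAULT_NOVEL_RATIO
) -> int:
    """How many (A, B) count pairs exceed the fold-ratio threshold in either direction."""
    n = 0
    for a, b in count_pairs:
        lfc = log2_fold_change(a, b, rounded=False)
        if classify_response(lfc, ratio_threshold) != UNCHANGED:
            n += 1
    return n
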