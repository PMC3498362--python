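"""Complementarity-based target prediction and degradome validation.

A miRNA is aligned antiparallel and ungapped against every window of its own
length on each transcript: Watson-Crick pairs cost 0, G:U wobbles 0.5,
anything else 1, and windows with total penalty at or below the threshold
(default 3.0, the "three mismatches or less" rule) are reported. Slicer
cleavage is expected opposite miRNA position 10, so each site maps to one
transcript coordinate; degradome 5'-end tags piling up there (within a +-1
window) support the site, graded by a 5-level category scheme relative to the
tag profile of the whole transcript.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import normalize_seq

DEFAULT_PENALTY_THRESHOLD = 3.0
DEFAULT_CLEAVAGE_WINDOW = 1
CATEGORY_NONE = "none"

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}  # G:U in RNA space


@dataclass(frozen=True)
class TargetSite:
    mirna_id: str
    transcript_id: str
    start1: int  # 1-based inclusive
    end1: int  # 1-based inclusive
    penalty: float
    status: str  # per-position '|' match, 'o' wobble, 'x' mismatch (miRNA 5'->3')


@dataclass(frozen=True)
class DegradomeEvidence:
    site: TargetSite
    cleavage_pos: int  # 1-based transcript coordinate
    evidence_count: int
    max_count: int
    category: int | str  # 0..4 or "none"


def duplex_penalty(mirna: str, site: str, gu_penalty: float = 0.5) -> tuple[float, str]:
    """Ungapped antiparallel duplex penalty of miRNA vs a transcript window.

    The site is given 5'->3' in mRNA sense; miRNA position i (from its 5' end)
    faces site position L-1-i. ``gu_penalty=1.0`` gives the strict Hamming mode.
    """
    m = normalize_seq(mirna)
    s = normalize_seq(site)
    if len(m) != len(s):
        raise ValueError("miRNA and site must have equal lengths")
    penalty = 0.0
    status = []
    L = len(m)
    for i, base in enumerate(m):
        t = s[L - 1 - i]
        if (base, t) in _WC:
            status.append("|")
        elif (base, t) in _WOBBLE:
            status.append("o")
            penalty += gu_penalty
        else:
            status.append("x")
            penalty += 1.0
    return penalty, "".join(status)


def scan_targets(
    mirna_id: str,
    mirna_seq: str,
    transcripts: dict[str, str],
    threshold: float = DEFAULT_PENALTY_THRESHOLD,
    gu_penalty: float = 0.5,
) -> list[TargetSite]:
    """All windows on all transcripts with duplex penalty <= threshold.

    Transcripts shorter than the miRNA are skipped. Results sort by penalty,
    then transcript id and coordinate.
    """
    m = normalize_seq(mirna_seq)
    L = len(m)
    sites: list[TargetSite] = []
    for tid, seq in transcripts.items():
        s = normalize_seq(seq)
        if len(s) < L:
            continue
        for start in range(0, len(s) - L + 1):
            window = s[start : start + L]
            penalty, status = duplex_penalty(m, window, gu_penalty)
            if penalty <= threshold:
                sites.append(
                    TargetSite(
                        mirna_id=mirna_id,
                        transcript_id=tid,
                        start1=start + 1,
                        end1=start + L,
                        penalty=penalty,
                        status=status,
                    )
                )
    sites.sort(key=lambda t: (t.penalty, t.transcript_id, t.start1))
    return sites


def cleavage_position(site: TargetSite) -> int:
    """Transcript coordinate paired to miRNA position 10: t1 + L - 10."""
    L = site.end1 - site.start1 + 1
    if L < 10:
        raise ValueError("site shorter than 10 nt has no canonical cleavage position")
    return site.start1 + L - 10


def degradome_support(
    site: TargetSite,
    degradome: pd.DataFrame,
    window: int = DEFAULT_CLEAVAGE_WINDOW,
) -> DegradomeEvidence:
    """Grade degradome tag support at the site's expected cleavage position.

    Categories: 4 = exactly one supporting read; 0 = unique transcript-wide
    maximum; 1 = tied maximum; 2 = above the median of nonzero positions;
    3 = any remaining nonzero support; "none" = no tags in the window (or an
    unknown transcript).
    """
    pos = cleavage_position(site)
    sub = degradome[degradome["transcript"] == site.transcript_id]
    if sub.empty:
        return DegradomeEvidence(site, pos, 0, 0, CATEGORY_NONE)
    counts = sub.groupby("pos_1based")["count"].sum()
    in_window = counts[
        (counts.index >= pos - window) & (counts.index <= pos + window)
    ]
    evidence = int(in_window.sum())
    max_count = int(counts.max())
    if evidence == 0:
        return DegradomeEvidence(site, pos, 0, max_count, CATEGORY_NONE)
    if evidence == 1:
        return DegradomeEvidence(site, pos, 1, max_count, 4)
    if evidence >= max_count:
        # the window aggregate meets the best single position on the transcript
        peak = int(in_window.max())
        n_at_max = int((counts == max_count).sum())
        if peak == max_count and n_at_max == 1:
            return DegradomeEvidence(site, pos, evidence, max_count, 0)
        if peak == max_count:
            return DegradomeEvidence(site, pos, evidence, max_count, 1)
    median = float(np.median(counts[counts > 0]))
    category = 2 if evidence > median else 3
    return DegradomeEvidence(site, pos, evidence, max_count, category)


def target_report(
    evidences: list[DegradomeEvidence], has_degradome: bool = True
) -> pd.DataFrame:
    """Flat TSV view of predicted sites with their degradome grading."""
    rows = []
    for ev in evidences:
        s = ev.site
        rows.append(
            {
                "mirna": s.mirna_id,
                "transcript": s.transcript_id,
                "start1": s.start1,
                "end1": s.end1,
                "penalty": s.penalty,
                "cleavage_pos": ev.cleavage_pos if has_degradome else "NA",
                "evidence_count": ev.evidence_count if has_degradome else "NA",
                "category": ev.category if has_degradome else "NA",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna", "transcript", "start1", "end1", "penalty",
            "cleavage_pos", "evidence_count", "category",
        ],
    )
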