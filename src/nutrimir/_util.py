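"""Small shared helpers: sequence alphabet handling and rounding dialects."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def normalize_seq(seq: str) -> str:
    """Uppercase and map RNA to DNA alphabet (U -> T).

    All internal sequence handling is DNA-space; genome matching demands it.
    """
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (5 rounds up in magnitude), unlike banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(abs(x))).quantize(q, rounding=ROUND_HALF_UP)
    out = float(d)
    return -out if x < 0 else out


def percent_mixed_precision(x: float) -> float:
    """Percentage rounding dialect used in the class-composition table.

    Values below 10% print with 2 decimals, values at or above 10% with 1.
    """
    return round_half_away(x, 2) if x < 10 else round_half_away(x, 1)
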