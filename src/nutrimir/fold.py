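"""Nested secondary-structure prediction by weighted base-pair maximization.

A Nussinov-style dynamic program maximizes the summed pair weights
(G:C = 3, A:U = 2, G:U = 1) over all pseudoknot-free structures with a
minimum hairpin loop of 3 unpaired nucleotides. The traceback is fully
deterministic: when leaving position i unpaired ties pairing it, i stays
unpaired; among tying partners the smallest j wins. This keeps every fold
reproducible and directly checkable against exhaustive enumeration, which a
thermodynamic minimum-free-energy engine (pluggable via the same dot-bracket
contract) is not.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from ._util import normalize_seq

MIN_LOOP = 3
MAX_FOLD_LEN = 400

# pair weights in DNA alphabet (U normalized to T)
PAIR_WEIGHTS = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "T"): 2, ("T", "A"): 2,
    ("G", "T"): 1, ("T", "G"): 1,
}

FoldEngine = Callable[[str], tuple[str, float]]


def pair_weight(a: str, b: str) -> int:
    return PAIR_WEIGHTS.get((a, b), 0)


def fold_rna(seq: str, min_loop: int = MIN_LOOP) -> tuple[str, int]:
    """Optimal dot-bracket structure and its pairing score.

    Raises on characters outside {A,C,G,T,U} or length > 400 (the DP is cubic).
    """
    s = normalize_seq(seq)
    if any(c not in "ACGT" for c in s):
        raise ValueError(f"invalid character in sequence: {seq!r}")
    n = len(s)
    if n > MAX_FOLD_LEN:
        raise ValueError(f"sequence longer than {MAX_FOLD_LEN} nt")
    if n == 0:
        return "", 0

    # P[i, j] = weight of pairing i with j (0 if not pairable)
    enc = np.frombuffer(s.encode(), dtype=np.uint8)
    P = np.zeros((n, n), dtype=np.int32)
    for (a, b), w in PAIR_WEIGHTS.items():
        P[np.ix_(enc == ord(a), enc == ord(b))] = w

    # W padded to (n+1, n+1): W[i, j] for i <= j, zero-width spans read 0
    W = np.zeros((n + 1, n + 1), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = W[i + 1, j]  # i unpaired
            ks = np.arange(i + min_loop + 1, j + 1)
            cand = P[i, ks] + W[i + 1, ks - 1] + W[ks + 1, j]
            pairable = cand[P[i, ks] > 0]
            if pairable.size:
                best = max(best, int(pairable.max()))
            W[i, j] = best

    # deterministic traceback
    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= min_loop:
            continue
        if W[i, j] == W[i + 1, j]:  # prefer i unpaired on ties
            stack.append((i + 1, j))
            continue
        for k in range(i + min_loop + 1, j + 1):  # smallest partner j wins ties
            if P[i, k] and P[i, k] + W[i + 1, k - 1] + W[k + 1, j] == W[i, j]:
                structure[i], structure[k] = "(", ")"
                stack.append((i + 1, k - 1))
                stack.append((k + 1, j))
                break
    return "".join(structure), int(W[0, n - 1])


def pair_table(structure: str) -> dict[int, int]:
    """0-based position -> partner for every paired position (symmetric)."""
    partners: dict[int, int] = {}
    opens: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            opens.append(i)
        elif c == ")":
            if not opens:
                raise ValueError("unbalanced structure")
            j = opens.pop()
            partners[i] = j
            partners[j] = i
        elif c != ".":
            raise ValueError(f"invalid structure character {c!r}")
    if opens:
        raise ValueError("unbalanced structure")
    return partners


def structure_score(seq: str, structure: str) -> int:
    """Score an arbitrary dot-bracket structure under the pair weights."""
    s = normalize_seq(seq)
    pt = pair_table(structure)
    return sum(pair_weight(s[i], s[j]) for i, j in pt.items() if i < j)


def enumerate_structures(seq: str, min_loop: int = MIN_LOOP):
    """Yield every nested structure of ``seq`` (exhaustive; oracle for tiny n)."""
    s = normalize_seq(seq)
    n = len(s)

    def rec(i: int, j: int):
        # all structures of s[i..j] inclusive
        if i > j:
            yield ""
            return
        # i unpaired
        for rest in rec(i + 1, j):
            yield "." + rest
        for k in range(i + min_loop + 1, j + 1):
            if pair_weight(s[i], s[k]):
                for inner in rec(i + 1, k - 1):
                    for outer in rec(k + 1, j):
                        yield "(" + inner + ")" + outer

    yield from rec(0, n - 1)


def best_score_bruteforce(seq: str, min_loop: int = MIN_LOOP) -> int:
    """Exhaustive-enumeration optimum score (independent of the DP)."""
    return max(
        structure_score(seq, st) for st in enumerate_structures(seq, min_loop)
    )
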