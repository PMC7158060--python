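"""Maximum base-pairing secondary-structure stand-in.

A Nussinov-style dynamic program (canonical AU/GC plus wobble GU pairs,
minimum hairpin loop of 3 unpaired bases) supplies the pairing indicator
used by the structural meta-profile. It maximises the number of pairs in a
non-crossing matching; it is not a thermodynamic model. An external
thermodynamic folder can be plugged in through the same call signature
(sequence in, per-base pairing indicator out) for publication-grade
profiles.
"""
from __future__ import annotations

import numpy as np

MIN_LOOP = 3
_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"),
          ("G", "U"), ("U", "G")}


def _canon(sequence: str) -> str:
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"invalid characters for folding: {sorted(bad)}")
    return seq


def can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


def fold_pairs(sequence: str) -> list[tuple[int, int]]:
    """Optimal (maximum-cardinality) list of base pairs (i, j), i < j.

    Deterministic: ties resolve toward leaving i unpaired, then toward the
    smallest pairing partner.
    """
    seq = _canon(sequence)
    n = len(seq)
    if n > 200:
        raise ValueError("window longer than 200 nt")
    if n == 0:
        return []
    N = np.zeros((n + 1, n + 1), dtype=np.int32)  # N[i][j], j exclusive-ish
    # N[i][j] = max pairs in seq[i..j] inclusive; use (n,n) table
    M = np.zeros((n, n), dtype=np.int32)
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = M[i + 1, j] if i + 1 <= j else 0
            for k in range(i + MIN_LOOP + 1, j + 1):
                if can_pair(seq[i], seq[k]):
                    left = M[i + 1, k - 1] if k - 1 >= i + 1 else 0
                    right = M[k + 1, j] if k + 1 <= j else 0
                    if left + right + 1 > best:
                        best = left + right + 1
            M[i, j] = best
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= MIN_LOOP:
            continue
        if M[i, j] == M[i + 1, j]:
            stack.append((i + 1, j))
            continue
        for k in range(i + MIN_LOOP + 1, j + 1):
            if can_pair(seq[i], seq[k]):
                left = M[i + 1, k - 1] if k - 1 >= i + 1 else 0
                right = M[k + 1, j] if k + 1 <= j else 0
                if left + right + 1 == M[i, j]:
                    pairs.append((i, k))
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    break
    return sorted(pairs)


def fold_window(sequence: str) -> np.ndarray:
    """Per-base pairing indicator for the computed maximum matching."""
    seq = _canon(sequence)
    paired = np.zeros(len(seq), dtype=bool)
    for i, j in fold_pairs(sequence):
        paired[i] = paired[j] = True
    return paired
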