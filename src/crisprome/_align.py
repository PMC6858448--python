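"""Pairwise spacer alignment with free terminal gaps.

Spacer clustering follows the centroid-clustering convention of scoring a
global alignment in which terminal (end) gaps carry zero penalty: length
differences and small offsets between homologous spacers are not punished.
Scoring inside the aligned core is match +1, mismatch -1, internal gap -1.

Identity is defined as

    identity = matches / max(core_columns, min(len_a, len_b))

where ``core_columns`` are the alignment columns excluding terminal gaps.
The ``min(len_a, len_b)`` floor keeps the measure meaningful for degenerate
dovetail optima (a short perfect terminal overlap between otherwise unrelated
sequences would otherwise score identity 1.0); for full-length alignments the
floor is inactive and internal gaps count against identity, exactly as in the
zero-end-gap-penalty convention.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .iupac import encode

__all__ = ["semi_global_identity", "mismatch_distance", "align_stats"]


@njit(cache=False)
def _dp_free_endgap(a, b):  # pragma: no cover - exercised via wrapper
    """Best free-end-gap alignment of mask arrays a, b.

    Returns (score, core_columns) of the optimal path; ties broken by
    preferring diagonal over gap-in-b over gap-in-a moves and, at the end,
    the smallest (row, column) cell among score maxima.
    """
    m = a.shape[0]
    n = b.shape[0]
    S = np.zeros((m + 1, n + 1), dtype=np.int64)
    C = np.zeros((m + 1, n + 1), dtype=np.int64)
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            sub = 1 if (ai & b[j - 1]) != 0 else -1
            best = S[i - 1, j - 1] + sub
            cols = C[i - 1, j - 1] + 1
            s_up = S[i - 1, j] - 1
            if s_up > best:
                best = s_up
                cols = C[i - 1, j] + 1
            s_left = S[i, j - 1] - 1
            if s_left > best:
                best = s_left
                cols = C[i, j - 1] + 1
            S[i, j] = best
            C[i, j] = cols
    # free trailing gaps: best over last row and last column
    best_s = S[m, 0]
    best_c = C[m, 0]
    for j in range(n + 1):
        if S[m, j] > best_s:
            best_s = S[m, j]
            best_c = C[m, j]
    for i in range(m + 1):
        if S[i, n] > best_s:
            best_s = S[i, n]
            best_c = C[i, n]
    return best_s, best_c


def _canonical(a: str, b: str) -> tuple[str, str]:
    # symmetry: DP tie-breaks depend on argument order, so fix one
    if (len(a), a) <= (len(b), b):
        return a, b
    return b, a


def align_stats(a: str, b: str) -> tuple[int, int]:
    """(matches, core_columns) of the optimal free-end-gap alignment."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    a, b = _canonical(a.upper(), b.upper())
    score, cols = _dp_free_endgap(encode(a), encode(b))
    # each core column shifts score+cols by +2 (match) or 0 (mismatch/gap)
    matches = (score + cols) // 2
    return int(matches), int(cols)


def semi_global_identity(a: str, b: str) -> float:
    """Identity of a and b under free terminal gaps (see module docstring)."""
    matches, cols = align_stats(a, b)
    denom = max(cols, min(len(a), len(b)))
    if denom == 0:
        return 0.0
    return matches / denom


def mismatch_distance(a: str, b: str) -> int:
    """Errors (mismatches + internal gaps + uncovered short-sequence bases)
    of the optimal free-end-gap alignment; 0 for containment."""
    matches, cols = align_stats(a, b)
    return max(cols, min(len(a), len(b))) - matches
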