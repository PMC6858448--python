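"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written straight from the definitions (per-window loops,
exhaustive enumeration), deliberately sharing no code with the package.
"""

from __future__ import annotations

import numpy as np

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def brute_scan(sequence: str, pattern: str, max_mismatch: int):
    """Per-window Hamming scan with IUPAC set intersection."""
    hits = []
    m = len(pattern)
    for s in range(len(sequence) - m + 1):
        window = sequence[s : s + m]
        mm = 0
        for p, b in zip(pattern, window):
            if not set(IUPAC[p]) & set(IUPAC[b]):
                mm += 1
        if mm <= max_mismatch:
            hits.append((s, mm))
    return hits


def enumerate_alignments(a: str, b: str):
    """All free-end-gap alignments of a and b as (score, matches, core_cols).

    Exhaustive: every choice of skipped prefix (in one sequence), core path
    (diag / gap-in-b / gap-in-a), and skipped suffix.  Scoring: match +1,
    mismatch -1, internal gap -1; terminal gaps free.  Exponential - only
    for short strings.
    """
    la, lb = len(a), len(b)
    results = []

    def rec(i, j, score, matches, cols):
        if i == la or j == lb:  # remaining bases become free trailing gaps
            results.append((score, matches, cols))
            return
        m = 1 if a[i] == b[j] else -1
        rec(i + 1, j + 1, score + m, matches + (m > 0), cols + 1)
        rec(i + 1, j, score - 1, matches, cols + 1)
        rec(i, j + 1, score - 1, matches, cols + 1)

    for i0 in range(la + 1):
        rec(i0, 0, 0, 0, 0)
    for j0 in range(1, lb + 1):
        rec(0, j0, 0, 0, 0)
    return results


def best_alignment_stats(a: str, b: str):
    """(best score, set of (matches, cols) attaining it)."""
    alns = enumerate_alignments(a, b)
    best = max(s for s, _, _ in alns)
    return best, {(m, c) for s, m, c in alns if s == best}


def eccentricity_by_enumeration(dag):
    """Longest simple path through each node, by enumerating all paths."""
    best = {n: 1 for n in dag.nodes}

    def dfs(path):
        for n in path:
            if len(path) > best[n]:
                best[n] = len(path)
        for nxt in dag.successors(path[-1]):
            if nxt not in path:
                dfs(path + [nxt])

    for n in dag.nodes:
        dfs([n])
    return best


def _max_run(flags) -> int:
    run = best = 0
    for f in flags:
        run = run + 1 if f else 0
        best = max(best, run)
    return best


def protospacer_window_scan(spacer: str, genome: str, min_identity=0.85, word_size=8):
    """All (start, strand) -> identity for full-length ungapped matches that
    contain a perfect word_size run (the seeded-search hit definition)."""
    hits = {}
    L = len(spacer)
    for strand in "+-":
        q = spacer if strand == "+" else revcomp(spacer)
        for s in range(len(genome) - L + 1):
            flags = [x == y for x, y in zip(q, genome[s : s + L])]
            ident = sum(flags) / L
            if ident >= min_identity and _max_run(flags) >= word_size:
                hits[(s, strand)] = ident
    return hits


def pair_has_overlap_match(a: str, b: str, min_identity=0.7, word_size=8) -> bool:
    """All-offsets, both-strand check for an ungapped overlap with identity
    > min_identity containing a perfect word_size run."""
    la = len(a)
    for bb in (b, revcomp(b)):
        lb = len(bb)
        for off in range(-(lb - 1), la):
            a0, a1 = max(0, off), min(la, off + lb)
            if a1 <= a0:
                continue
            flags = [a[x] == bb[x - off] for x in range(a0, a1)]
            if _max_run(flags) >= word_size and sum(flags) / len(flags) > min_identity:
                return True
    return False


def coverage_by_marking(intervals, genome_length: int) -> float:
    mask = np.zeros(genome_length, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    return mask.mean()
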