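"""IUPAC degenerate nucleotide alphabet: sets, bitmask encoding, matching.

CRISPR repeat consensuses vary between genomes, so repeats and primers are
described with degenerate IUPAC symbols (R = A/G, H = A/C/T, ...).  All motif
scanning in this package works on a 4-bit encoding (A=1, C=2, G=4, T=8) where
two symbols are compatible iff their bitmasks intersect.
"""

from __future__ import annotations

import numpy as np

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}

IUPAC_MASK: dict[str, int] = {
    sym: sum(_BASE_BIT[b] for b in bases) for sym, bases in IUPAC_SETS.items()
}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

# lookup table: ASCII code -> bitmask (0 for invalid characters)
_MASK_TABLE = np.zeros(256, dtype=np.uint8)
for _sym, _mask in IUPAC_MASK.items():
    _MASK_TABLE[ord(_sym)] = _mask
    _MASK_TABLE[ord(_sym.lower())] = _mask


class IupacError(ValueError):
    """Raised for characters outside the IUPAC nucleotide alphabet."""


def iupac_match(pattern_symbol: str, base: str) -> bool:
    """True iff *base* is compatible with degenerate *pattern_symbol*.

    Both arguments are single IUPAC characters; N matches everything.
    A degenerate base on the read side matches if the two sets intersect.
    """
    try:
        pm = IUPAC_MASK[pattern_symbol.upper()]
        bm = IUPAC_MASK[base.upper()]
    except KeyError as exc:
        raise IupacError(f"not an IUPAC nucleotide symbol: {exc.args[0]!r}") from None
    return bool(pm & bm)


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as a uint8 bitmask array; rejects non-IUPAC characters."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    masks = _MASK_TABLE[arr]
    if (masks == 0).any():
        bad = seq[int(np.argmax(masks == 0))]
        raise IupacError(f"not an IUPAC nucleotide symbol: {bad!r}")
    return masks


def validate(seq: str, label: str = "sequence") -> None:
    """Raise IupacError if *seq* is empty or contains non-IUPAC characters."""
    if not seq:
        raise IupacError(f"{label} is empty")
    encode(seq)


def reverse_complement(seq: str) -> str:
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise IupacError(f"not an IUPAC nucleotide symbol: {exc.args[0]!r}") from None


def instantiate(pattern: str, rng: np.random.Generator) -> str:
    """Draw one concrete ACGT realization of a degenerate IUPAC pattern."""
    out = []
    for sym in pattern.upper():
        bases = sorted(IUPAC_SETS.get(sym, ()))
        if not bases:
            raise IupacError(f"not an IUPAC nucleotide symbol: {sym!r}")
        out.append(bases[rng.integers(len(bases))] if len(bases) > 1 else bases[0])
    return "".join(out)
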