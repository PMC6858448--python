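"""Spacer extraction from repeat-anchored amplicon reads.

Finds degenerate repeat (and primer) motifs in each read by Hamming-style
IUPAC matching, extracts the sequences between consecutive repeat hits, and
applies the length (25-60 nt) and per-base quality (Phred strictly > 20)
filters before emitting spacer and neighbouring-spacer-pair observations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from . import iupac

logger = logging.getLogger(__name__)

__all__ = [
    "DegenerateMotif",
    "ExtractionParams",
    "SpacerObservation",
    "SpacerPairObservation",
    "ExtractionSummary",
    "scan_motif",
    "select_nonoverlapping",
    "extract_from_read",
    "extract_sample",
]


@dataclass(frozen=True)
class DegenerateMotif:
    """A named IUPAC-degenerate motif (CRISPR repeat consensus or primer)."""

    label: str
    pattern: str

    def __post_init__(self):
        iupac.validate(self.pattern, f"motif {self.label!r}")

    def __len__(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class ExtractionParams:
    max_mismatch_repeat: int = 3
    max_mismatch_primer: int = 2
    min_spacer_len: int = 25
    max_spacer_len: int = 60
    min_phred: int = 20  # strict: bases must exceed this value
    search_both_strands: bool = True

    def __post_init__(self):
        if self.min_spacer_len >= self.max_spacer_len:
            raise ValueError("min_spacer_len must be below max_spacer_len")
        if self.max_mismatch_repeat < 0 or self.max_mismatch_primer < 0:
            raise ValueError("mismatch allowances must be non-negative")


@dataclass(frozen=True)
class SpacerObservation:
    sequence: str
    repeat_type: str
    sample_id: str
    read_id: str
    unit_index: int
    qualities: tuple[int, ...]

    @property
    def min_phred(self) -> int:
        return min(self.qualities)


@dataclass(frozen=True)
class SpacerPairObservation:
    first_spacer: str
    second_spacer: str
    repeat_type: str
    sample_id: str
    read_id: str
    orientation: str = "as-read"


@dataclass
class ExtractionSummary:
    reads_scanned: int = 0
    reads_with_spacers: int = 0
    spacers_kept: int = 0
    spacers_filtered_length: int = 0
    spacers_filtered_quality: int = 0
    pairs_kept: int = 0
    reads_skipped: int = 0

    @property
    def spacers_filtered(self) -> int:
        return self.spacers_filtered_length + self.spacers_filtered_quality


def scan_motif(sequence, motif: DegenerateMotif, max_mismatch: int):
    """All windows of ``sequence`` matching ``motif`` with <= max_mismatch
    IUPAC mismatches, as (start, mismatches) sorted by start (0-based)."""
    if isinstance(sequence, str):
        enc = iupac.encode(sequence)
    else:
        enc = np.asarray(sequence, dtype=np.uint8)
    m = len(motif)
    if m == 0 or enc.shape[0] < m:
        return []
    pat = iupac.encode(motif.pattern)
    windows = sliding_window_view(enc, m)
    mism = ((windows & pat) == 0).sum(axis=1)
    starts = np.flatnonzero(mism <= max_mismatch)
    return [(int(s), int(mism[s])) for s in starts]


def select_nonoverlapping(hits, length: int):
    """Greedy left-to-right non-overlapping subset of motif hits.

    Hits are considered in (start, mismatches) order, so of two hits at the
    same start the lower-mismatch one wins; a hit is kept iff it does not
    overlap a previously kept hit.
    """
    kept = []
    last_end = -1
    for start, mm in sorted(hits):
        if start >= last_end:
            kept.append((start, mm))
            last_end = start + length
    return kept


def _oriented_views(record, repeat, params):
    """Candidate orientations of a read: (sequence, qualities, repeat hits)."""
    seq = str(record.seq).upper()
    quals = record.letter_annotations.get("phred_quality")
    if quals is None or len(quals) != len(seq):
        raise ValueError(f"read {record.id}: sequence/quality length mismatch")
    fwd_hits = scan_motif(seq, repeat, params.max_mismatch_repeat)
    if not params.search_both_strands:
        return seq, quals, fwd_hits
    rc = iupac.reverse_complement(seq)
    rc_hits = scan_motif(rc, repeat, params.max_mismatch_repeat)
    if len(rc_hits) > len(fwd_hits):
        return rc, list(reversed(quals)), rc_hits
    return seq, quals, fwd_hits


def extract_from_read(record, repeat: DegenerateMotif, primers, params: ExtractionParams,
                      sample_id: str = "sample"):
    """Extract spacers and neighbouring-spacer pairs from one read.

    Spacers are the maximal substrings strictly between consecutive
    (greedily selected, non-overlapping) repeat hits, plus the substring
    between a primer hit and the first/last repeat where a primer is found.
    If repeat hits are more numerous on the reverse complement, the read is
    flipped before extraction.  Pairs join spacers at adjacent unit indices
    where both members pass the filters.
    """
    seq, quals, hits = _oriented_views(record, repeat, params)
    repeat_hits = select_nonoverlapping(hits, len(repeat))
    if len(repeat_hits) < 1:
        return [], [], (0, 0)

    boundaries = [(s, s + len(repeat)) for s, _ in repeat_hits]
    segments = []  # (start, end) candidate spacer spans between anchors
    if primers:
        fwd, rev = primers
        p_hits = select_nonoverlapping(
            scan_motif(seq, fwd, params.max_mismatch_primer), len(fwd)
        )
        before = [h for h in p_hits if h[0] + len(fwd) < boundaries[0][0]]
        if before:
            segments.append((before[-1][0] + len(fwd), boundaries[0][0]))
        r_hits = select_nonoverlapping(
            scan_motif(seq, rev, params.max_mismatch_primer), len(rev)
        )
        after = [h for h in r_hits if h[0] > boundaries[-1][1]]
        if after:
            segments.append((boundaries[-1][1], after[0][0]))
    for (s0, e0), (s1, e1) in zip(boundaries, boundaries[1:]):
        segments.append((e0, s1))
    segments.sort()

    spacers: list[SpacerObservation | None] = []
    n_len = n_qual = 0
    for unit_index, (s, e) in enumerate(segments):
        sub = seq[s:e]
        q = quals[s:e]
        if not (params.min_spacer_len <= len(sub) <= params.max_spacer_len):
            n_len += 1
            spacers.append(None)
            continue
        if min(q) <= params.min_phred:
            n_qual += 1
            spacers.append(None)
            continue
        spacers.append(
            SpacerObservation(
                sequence=sub,
                repeat_type=repeat.label,
                sample_id=sample_id,
                read_id=record.id,
                unit_index=unit_index,
                qualities=tuple(int(x) for x in q),
            )
        )
    pairs = [
        SpacerPairObservation(
            first_spacer=a.sequence,
            second_spacer=b.sequence,
            repeat_type=repeat.label,
            sample_id=sample_id,
            read_id=record.id,
        )
        for a, b in zip(spacers, spacers[1:])
        if a is not None and b is not None
    ]
    kept = [s for s in spacers if s is not None]
    return kept, pairs, (n_len, n_qual)


def extract_sample(reads, motifs, params: ExtractionParams, sample_id: str = "sample"):
    """Run extraction over a read stream.

    ``motifs`` maps repeat-type label -> (repeat DegenerateMotif, primers or
    None); with several repeat types, each read is assigned to the type with
    the most repeat hits (ties favour label order).  Returns (spacer table,
    pair table, ExtractionSummary) with exact counts.
    """
    if isinstance(motifs, DegenerateMotif):
        motifs = {motifs.label: (motifs, None)}
    summary = ExtractionSummary()
    sp_rows, pair_rows = [], []
    labels = sorted(motifs)
    for record in reads:
        summary.reads_scanned += 1
        try:
            best = None
            for label in labels:
                repeat, primers = motifs[label]
                obs, pairs, (nl, nq) = extract_from_read(
                    record, repeat, primers, params, sample_id
                )
                score = len(obs) + len(pairs)
                if best is None or score > best[0]:
                    best = (score, obs, pairs, nl, nq)
            _, obs, pairs, nl, nq = best
        except (ValueError, iupac.IupacError) as exc:
            logger.warning("skipping unreadable read: %s", exc)
            summary.reads_skipped += 1
            continue
        summary.spacers_filtered_length += nl
        summary.spacers_filtered_quality += nq
        if obs:
            summary.reads_with_spacers += 1
        summary.spacers_kept += len(obs)
        summary.pairs_kept += len(pairs)
        for o in obs:
            sp_rows.append(
                (o.sample_id, o.read_id, o.unit_index, o.repeat_type, o.sequence, o.min_phred)
            )
        for p in pairs:
            pair_rows.append(
                (p.sample_id, p.repeat_type, p.first_spacer, p.second_spacer, p.read_id)
            )
    spacer_table = pd.DataFrame(
        sp_rows,
        columns=["sample_id", "read_id", "unit_index", "repeat_type", "sequence", "min_phred"],
    )
    pair_table = pd.DataFrame(
        pair_rows, columns=["sample_id", "repeat_type", "first", "second", "read_id"]
    )
    return spacer_table, pair_table, summary
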