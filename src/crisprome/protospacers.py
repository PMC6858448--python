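"""Protospacer search, PAM inference and the targeting/divergence test.

Spacers are matched to genomes by seed-and-extend: exact ``word_size``-mer
seeds on both strands, extended ungapped to the full spacer length, with
hits kept at identity >= ``min_identity`` over the whole spacer.  A hit
therefore requires that at least one perfect ``word_size`` word survives in
the protospacer, which is the classic seeded-search miss condition for
short, divergent matches: :func:`seed_guaranteed` reports whether the
pigeonhole principle rules such misses out for a given spacer length.

Protospacers on an aligned pair of related genomes are classified conserved
(every column of the span identical) or variable, and the coincidence of
CRISPR targeting with genome divergence is tested by comparing the observed
conserved/variable split against the split of spacers simulated at uniform
random alignment positions (chi-square goodness of fit, df = 1; a 2x2
contingency variant is reported alongside).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .iupac import reverse_complement

__all__ = [
    "MatchParams",
    "ProtospacerHit",
    "ConservationTrack",
    "CoincidenceResult",
    "GenomeIndex",
    "find_protospacers",
    "dedupe_hits",
    "seed_guaranteed",
    "pam_consensus",
    "classify_conservation",
    "coincidence_test",
    "genome_protospacer_coverage",
]


@dataclass(frozen=True)
class MatchParams:
    word_size: int = 8
    min_identity: float = 0.85
    search_both_strands: bool = True

    def __post_init__(self):
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if not 0.0 < self.min_identity <= 1.0:
            raise ValueError("min_identity must lie in (0, 1]")


@dataclass(frozen=True)
class ProtospacerHit:
    cluster_id: str
    genome_id: str
    start: int  # 0-based half-open, forward-strand coordinates
    end: int
    strand: str
    identity: float
    flank_5: str
    flank_3: str


def seed_guaranteed(spacer_len: int, min_identity: float, word_size: int = 8) -> bool:
    """True iff any hit at ``min_identity`` must contain a perfect
    ``word_size`` word (pigeonhole over the worst-case mismatch layout)."""
    max_mm = int(np.floor(spacer_len * (1.0 - min_identity)))
    longest_run = int(np.ceil((spacer_len - max_mm) / (max_mm + 1)))
    return longest_run >= word_size


class GenomeIndex:
    """Exact word index of one genome for repeated spacer searches."""

    def __init__(self, genome: str, genome_id: str = "genome", params: MatchParams = MatchParams()):
        self.genome = genome.upper()
        self.genome_id = genome_id
        self.params = params
        self._enc = np.frombuffer(self.genome.encode("ascii"), dtype=np.uint8)
        w = params.word_size
        self._index: dict[str, list[int]] = {}
        for i in range(len(self.genome) - w + 1):
            self._index.setdefault(self.genome[i : i + w], []).append(i)

    def _extend(self, query_enc: np.ndarray, start: int) -> float:
        stop = start + query_enc.shape[0]
        return float((self._enc[start:stop] == query_enc).mean())

    def search(self, spacer: str, cluster_id: str = "spacer") -> list[ProtospacerHit]:
        spacer = spacer.upper()
        L = len(spacer)
        if L > len(self.genome):
            return []
        w = self.params.word_size
        hits: dict[tuple[int, str], float] = {}
        strands = ["+", "-"] if self.params.search_both_strands else ["+"]
        for strand in strands:
            q = spacer if strand == "+" else reverse_complement(spacer)
            q_enc = np.frombuffer(q.encode("ascii"), dtype=np.uint8)
            seen: set[int] = set()
            for i in range(L - w + 1):
                for p in self._index.get(q[i : i + w], ()):
                    s = p - i
                    if s < 0 or s + L > len(self.genome) or s in seen:
                        continue
                    seen.add(s)
                    ident = self._extend(q_enc, s)
                    if ident >= self.params.min_identity:
                        hits[(s, strand)] = ident
        out = []
        for (s, strand), ident in sorted(hits.items()):
            f5 = self._flank(s - 10, s)
            f3 = self._flank(s + L, s + L + 10)
            if strand == "-":
                f5, f3 = reverse_complement(f3), reverse_complement(f5)
            out.append(
                ProtospacerHit(
                    cluster_id=cluster_id,
                    genome_id=self.genome_id,
                    start=s,
                    end=s + L,
                    strand=strand,
                    identity=ident,
                    flank_5=f5,
                    flank_3=f3,
                )
            )
        return out

    def _flank(self, a: int, b: int) -> str:
        left_pad = max(0, -a)
        right_pad = max(0, b - len(self.genome))
        core = self.genome[max(a, 0) : min(b, len(self.genome))]
        return "N" * left_pad + core + "N" * right_pad


def find_protospacers(spacer: str, genome: str, params: MatchParams = MatchParams(),
                      cluster_id: str = "spacer", genome_id: str = "genome"):
    """Seed-and-extend search of one spacer against one genome."""
    return GenomeIndex(genome, genome_id, params).search(spacer, cluster_id)


def dedupe_hits(hits, min_overlap: float = 0.5):
    """Merge same-strand hits overlapping >= ``min_overlap`` of the shorter
    span, keeping the highest identity (ties: leftmost)."""
    kept: list[ProtospacerHit] = []
    for h in sorted(hits, key=lambda h: (-h.identity, h.start, h.strand)):
        dup = False
        for k in kept:
            if k.strand != h.strand or k.genome_id != h.genome_id:
                continue
            ov = min(k.end, h.end) - max(k.start, h.start)
            if ov > 0 and ov >= min_overlap * min(k.end - k.start, h.end - h.start):
                dup = True
                break
        if not dup:
            kept.append(h)
    return sorted(kept, key=lambda h: (h.start, h.strand))


def pam_consensus(hits, flank_len: int = 10):
    """Positional base-frequency profiles of the 5' and 3' protospacer
    flanks (oriented to the protospacer strand) and a majority consensus
    (base if its frequency among non-N observations exceeds 0.5, else N)."""
    hits = list(hits)
    if len(hits) < 2:
        raise ValueError("PAM inference needs at least two hits")
    result = {}
    for side in ("flank_5", "flank_3"):
        flanks = [getattr(h, side)[-flank_len:] if side == "flank_5" else getattr(h, side)[:flank_len] for h in hits]
        width = max(len(f) for f in flanks)
        profile = pd.DataFrame(0, index=range(width), columns=list("ACGT"))
        for f in flanks:
            # right-align 5' flanks (position -1 abuts the protospacer)
            offset = width - len(f) if side == "flank_5" else 0
            for i, b in enumerate(f):
                if b in "ACGT":
                    profile.loc[offset + i, b] += 1
        totals = profile.sum(axis=1)
        consensus = []
        for pos in profile.index:
            t = totals[pos]
            if t == 0:
                consensus.append("N")
                continue
            best = profile.loc[pos].idxmax()
            consensus.append(best if profile.loc[pos, best] / t > 0.5 else "N")
        freq = profile.div(totals.replace(0, np.nan), axis=0)
        result[side] = (freq, "".join(consensus))
    return result


@dataclass
class ConservationTrack:
    """Per-column conservation of a two-genome alignment."""

    identical: np.ndarray  # bool per alignment column
    window_identity: np.ndarray
    window: int = 50

    def __post_init__(self):
        self._mismatch_cum = np.concatenate(
            [[0], np.cumsum(~self.identical)]
        )

    @property
    def n_columns(self) -> int:
        return self.identical.shape[0]

    def span_is_conserved(self, start: int, end: int) -> bool:
        """True iff every column in [start, end) is identical (no gap, no
        substitution) in both genomes."""
        return self._mismatch_cum[end] - self._mismatch_cum[start] == 0

    def spans_conserved(self, starts: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        ends = starts + lengths
        return (self._mismatch_cum[ends] - self._mismatch_cum[starts]) == 0


def classify_conservation(aln_a: str, aln_b: str, window: int = 50) -> ConservationTrack:
    """Column-wise conservation track of a 2-sequence alignment."""
    if len(aln_a) != len(aln_b):
        raise ValueError("aligned sequences must have equal length")
    if not aln_a:
        raise ValueError("empty alignment")
    a = np.frombuffer(aln_a.upper().encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(aln_b.upper().encode("ascii"), dtype=np.uint8)
    gap = ord("-")
    identical = (a == b) & (a != gap) & (b != gap)
    w = min(window, identical.shape[0])
    kernel = np.ones(w) / w
    win_id = np.convolve(identical.astype(float), kernel, mode="same")
    return ConservationTrack(identical=identical, window_identity=win_id, window=window)


@dataclass(frozen=True)
class CoincidenceResult:
    obs_conserved: int
    obs_variable: int
    sim_conserved: int
    sim_variable: int
    n_sim: int
    chi_square: float
    p_value: float
    chi_square_contingency: float
    p_value_contingency: float
    seed: int


def coincidence_test(observed_spans, track: ConservationTrack, spacer_lengths=None,
                     n_sim: int = 10_000, seed: int = 0) -> CoincidenceResult:
    """Test whether CRISPR targeting coincides with genome divergence.

    ``observed_spans``: (start, end) alignment spans of observed protospacer
    hits.  ``n_sim`` spacers are simulated at uniform random alignment
    starts with lengths resampled (with replacement) from the observed
    lengths; each simulated and observed span is classified conserved or
    variable, and the observed split is tested against the simulated
    proportions by a chi-square goodness of fit (df=1).  Deterministic for a
    given seed.
    """
    spans = [(int(s), int(e)) for s, e in observed_spans]
    if not spans:
        raise ValueError("need at least one observed hit")
    if track.identical.all() or not track.identical.any():
        raise ValueError("conservation track is degenerate (single class)")
    obs_flags = np.array([track.span_is_conserved(s, e) for s, e in spans])
    obs_c = int(obs_flags.sum())
    obs_v = len(spans) - obs_c

    if spacer_lengths is None:
        spacer_lengths = [e - s for s, e in spans]
    lengths = np.asarray(spacer_lengths, dtype=int)
    rng = np.random.default_rng(seed)
    sim_len = rng.choice(lengths, size=n_sim, replace=True)
    max_start = track.n_columns - sim_len
    if (max_start < 0).any():
        raise ValueError("spacer length exceeds alignment length")
    sim_start = (rng.random(n_sim) * (max_start + 1)).astype(int)
    sim_flags = track.spans_conserved(sim_start, sim_len)
    sim_c = int(sim_flags.sum())
    sim_v = n_sim - sim_c
    if sim_c == 0 or sim_v == 0:
        raise ValueError("simulated spacers fall in a single class")

    total = obs_c + obs_v
    expected = np.array([sim_c, sim_v], dtype=float) / n_sim * total
    chi2, pval = stats.chisquare([obs_c, obs_v], f_exp=expected)
    chi2_t, pval_t, _, _ = stats.chi2_contingency(
        [[obs_c, obs_v], [sim_c, sim_v]], correction=False
    )
    return CoincidenceResult(
        obs_conserved=obs_c,
        obs_variable=obs_v,
        sim_conserved=sim_c,
        sim_variable=sim_v,
        n_sim=n_sim,
        chi_square=float(chi2),
        p_value=float(pval),
        chi_square_contingency=float(chi2_t),
        p_value_contingency=float(pval_t),
        seed=seed,
    )


def genome_protospacer_coverage(hits, genome_length: int) -> float:
    """Fraction of the genome covered by >= 1 protospacer (interval union)."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    intervals = sorted((h.start, h.end) if hasattr(h, "start") else tuple(h) for h in hits)
    covered = 0
    cur_s = cur_e = None
    for s, e in intervals:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered / genome_length
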