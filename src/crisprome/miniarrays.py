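"""Probabilistic completeness tests for mini-CRISPR array candidates.

A 1- or 2-spacer reconstruction is either a genuine virus-borne mini-array
or a truncated fragment of a long host array.  Under independence of reads,
a spacer that truly sits inside a longer array and was sequenced N times
would have appeared in at least one neighbouring-spacer pair with
probability 1 - (1-p)^N, where p is the per-sample probability that a
sequenced spacer lands in a read with two or more spacers.  The completeness
tests below reject the "truncated fragment" null when the observed pairing
pattern would be too unlikely for a long-array spacer:

* one spacer, never in a pair, sequenced N times:  P = (1-p)^N
* two spacers, paired N times, never extended:     P = 1 - (1 - 0.5^(N-1))^2

Calls combine the test (P < alpha) with fixed conservative abundance
thresholds (100 for 1-spacer, 20 for 2-spacer candidates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "PairProbability",
    "MiniArrayCandidate",
    "MiniArrayCall",
    "estimate_pair_probability",
    "single_spacer_pvalue",
    "two_spacer_pvalue",
    "min_abundance_threshold",
    "mini_array_candidates",
    "call_mini_arrays",
    "immunity_contributions",
    "PAPER_THRESHOLDS",
]

#: conservative fixed abundance thresholds by candidate size
PAPER_THRESHOLDS: dict[int, int] = {1: 100, 2: 20}


@dataclass(frozen=True)
class PairProbability:
    sample_id: str
    p: float
    n_obs_single: int
    n_obs_multi: int


@dataclass(frozen=True)
class MiniArrayCandidate:
    cluster_ids: tuple[str, ...]
    n: int  # times sequenced (spacer abundance, or pair count for size 2)
    sample_id: str = "sample"
    component_id: int = -1

    def __post_init__(self):
        if not 1 <= len(self.cluster_ids) <= 2:
            raise ValueError("mini-array candidates carry 1 or 2 spacers")
        if self.n < 1:
            raise ValueError("abundance must be >= 1")


@dataclass(frozen=True)
class MiniArrayCall:
    candidate: MiniArrayCandidate
    p_value: float
    alpha: float
    threshold_used: int
    passes_pvalue: bool
    passes_threshold: bool

    @property
    def decision(self) -> str:
        return (
            "complete-mini-array"
            if self.passes_pvalue and self.passes_threshold
            else "possibly-truncated"
        )


def estimate_pair_probability(spacer_table: pd.DataFrame, sample_id: str = None) -> PairProbability:
    """p = fraction of spacer observations occurring in reads carrying >= 2
    spacers, from an extraction spacer table (columns read_id, sample_id)."""
    df = spacer_table
    if sample_id is not None:
        df = df[df["sample_id"] == sample_id]
    elif "sample_id" in df.columns and len(df):
        sample_id = str(df["sample_id"].iloc[0])
    if not len(df):
        raise ValueError("no spacer-bearing reads in sample")
    per_read = df.groupby("read_id").size()
    multi = per_read[per_read >= 2].sum()
    total = per_read.sum()
    return PairProbability(
        sample_id=sample_id or "sample",
        p=float(multi / total),
        n_obs_single=int(total - multi),
        n_obs_multi=int(multi),
    )


def single_spacer_pvalue(p: float, n: int) -> float:
    """P-value that a 1-spacer candidate sequenced ``n`` times with no pair
    observations is a truncated long-array spacer: (1-p)^n."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if int(n) != n or n < 1:
        raise ValueError("N must be a positive integer")
    return (1.0 - p) ** int(n)


def two_spacer_pvalue(n: int) -> float:
    """P-value that a 2-spacer candidate whose pair was sequenced ``n`` times
    is complete by chance: 1 - (1 - 0.5^(n-1))^2."""
    if int(n) != n or n < 1:
        raise ValueError("N must be a positive integer")
    x = 0.5 ** (int(n) - 1)
    # expanded form x * (2 - x) avoids the 1 - (1 - x)^2 cancellation that
    # underflows to exactly 0 once x < 2^-53
    return x * (2.0 - x)


def min_abundance_threshold(alpha: float, k_spacers: int, p: float | None = None) -> int:
    """Smallest N at which the size-``k_spacers`` completeness P-value drops
    below ``alpha`` (monotone scan; p is required for k=1)."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    if k_spacers not in (1, 2):
        raise ValueError("candidate size must be 1 or 2")
    if k_spacers == 1:
        if p is None or p <= 0.0:
            raise ValueError("k=1 threshold requires pair probability p > 0")
        pv = lambda n: single_spacer_pvalue(p, n)
    else:
        pv = two_spacer_pvalue
    n = 1
    while pv(n) >= alpha:
        n += 1
        if n > 10_000_000:  # pragma: no cover
            raise RuntimeError("no finite threshold below alpha")
    return n


def mini_array_candidates(paths, eccentricity, cluster_abundance, pair_weights=None,
                          sample_id: str = "sample", max_eccentricity: int = 2):
    """Derive candidates from reconstructed paths.

    Keeps paths of 1-2 spacers whose members all have eccentricity <=
    ``max_eccentricity`` (the screen that separates mini-array components
    from long-array fragments).  N is the cluster abundance for 1-spacer
    candidates and the pair weight for 2-spacer candidates.
    """
    out = []
    for path in paths:
        if len(path.nodes) > 2:
            continue
        if any(eccentricity.get(n, 1) > max_eccentricity for n in path.nodes):
            continue
        if len(path.nodes) == 1:
            n = int(cluster_abundance.get(path.nodes[0], 0))
        else:
            if pair_weights is not None:
                n = int(pair_weights.get(path.nodes, path.min_weight))
            else:
                n = int(path.min_weight)
        if n < 1:
            continue
        out.append(
            MiniArrayCandidate(
                cluster_ids=path.nodes,
                n=n,
                sample_id=sample_id,
                component_id=path.component_id,
            )
        )
    return out


def call_mini_arrays(candidates, pair_probability: PairProbability, alpha: float = 0.01,
                     thresholds: dict[int, int] | None = None):
    """Call complete mini-arrays: P-value < alpha AND N >= the fixed
    abundance threshold for the candidate size; both gates are reported."""
    thresholds = dict(PAPER_THRESHOLDS if thresholds is None else thresholds)
    calls = []
    for cand in candidates:
        k = len(cand.cluster_ids)
        if k == 1:
            pval = single_spacer_pvalue(pair_probability.p, cand.n)
        else:
            pval = two_spacer_pvalue(cand.n)
        thr = thresholds[k]
        calls.append(
            MiniArrayCall(
                candidate=cand,
                p_value=pval,
                alpha=alpha,
                threshold_used=thr,
                passes_pvalue=pval < alpha,
                passes_threshold=cand.n >= thr,
            )
        )
    return calls


def immunity_contributions(hits: pd.DataFrame, cluster_abundance: pd.DataFrame,
                           source_class: dict[str, str]) -> pd.DataFrame:
    """Per-sample, per-target-genome totals of targeting-spacer abundance,
    split by spacer source class (long host array vs viral mini-array).

    ``hits``: protospacer hits with columns cluster_id, genome_id.
    ``cluster_abundance``: cluster_id x sample_id abundance table.
    ``source_class``: cluster_id -> "long" | "mini" (missing -> "unknown").
    """
    rows = []
    targeting = hits[["cluster_id", "genome_id"]].drop_duplicates()
    unknown = sorted(
        set(targeting["cluster_id"]) - set(source_class)
    )
    if unknown:
        warnings.warn(f"{len(unknown)} targeting clusters without source class")
    for sample in cluster_abundance.columns:
        for genome, sub in targeting.groupby("genome_id"):
            totals: dict[str, float] = {}
            for cid in sub["cluster_id"]:
                cls = source_class.get(cid, "unknown")
                ab = float(cluster_abundance.loc[cid, sample]) if cid in cluster_abundance.index else 0.0
                totals[cls] = totals.get(cls, 0.0) + ab
            for cls, tot in sorted(totals.items()):
                rows.append((sample, genome, cls, tot))
    return pd.DataFrame(rows, columns=["sample_id", "genome_id", "source_class", "total_abundance"])
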