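"""Spacer clustering at 85% identity and diversity summaries.

Greedy centroid clustering in the tradition of the standard identity
clustering tools: sequences are processed
in descending abundance (ties broken lexicographically) and each is assigned
to the first existing centroid it matches at >= the identity threshold under
the free-end-gap identity of :mod:`crisprome._align`; otherwise it founds a
new cluster.  Also provides Good's coverage, Shannon entropy, the Chao1
richness estimate, the lost-spacer binomial confidence interval and the
cross-repeat-type spacer intersection matrix.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._align import mismatch_distance, semi_global_identity

__all__ = [
    "SpacerCluster",
    "DiversitySummary",
    "semi_global_identity",
    "cluster_spacers",
    "goods_coverage",
    "shannon_chao",
    "diversity_summary",
    "loss_confidence",
    "cross_type_intersection",
]


@dataclass
class SpacerCluster:
    cluster_id: str
    centroid: str
    members: list[str] = field(default_factory=list)
    abundance_by_sample: dict[str, int] = field(default_factory=dict)

    @property
    def total_abundance(self) -> int:
        return sum(self.abundance_by_sample.values())


def cluster_spacers(spacer_table, threshold: float = 0.85):
    """Greedy centroid clustering of spacer observations.

    ``spacer_table`` is a DataFrame with columns ``sequence`` and
    ``sample_id`` (one row per observation; a ``count`` column may replace
    repeated rows).  Returns ``(clusters, assignment)`` where assignment maps
    each distinct sequence to its cluster_id.  Deterministic.
    """
    if isinstance(spacer_table, pd.DataFrame):
        df = spacer_table.copy()
        if "count" not in df.columns:
            df["count"] = 1
        if "sample_id" not in df.columns:
            df["sample_id"] = "sample"
        counts = df.groupby("sequence")["count"].sum()
        by_sample = df.groupby(["sequence", "sample_id"])["count"].sum()
    else:  # iterable of sequences
        c = Counter(spacer_table)
        counts = pd.Series(c)
        by_sample = pd.Series(
            {(s, "sample"): n for s, n in c.items()}
        )

    order = sorted(counts.index, key=lambda s: (-counts[s], s))
    clusters: list[SpacerCluster] = []
    assignment: dict[str, str] = {}
    for seq in order:
        target = None
        for cl in clusters:
            if seq == cl.centroid or semi_global_identity(seq, cl.centroid) >= threshold:
                target = cl
                break
        if target is None:
            target = SpacerCluster(cluster_id=f"c{len(clusters):05d}", centroid=seq)
            clusters.append(target)
        target.members.append(seq)
        assignment[seq] = target.cluster_id
    for (seq, sample), n in by_sample.items():
        cl = clusters[int(assignment[seq][1:])]
        cl.abundance_by_sample[sample] = cl.abundance_by_sample.get(sample, 0) + int(n)
    return clusters, assignment


def _counts_array(cluster_counts) -> np.ndarray:
    if isinstance(cluster_counts, dict):
        cluster_counts = list(cluster_counts.values())
    arr = np.asarray(cluster_counts, dtype=float)
    if arr.size == 0:
        raise ValueError("empty count vector")
    if (arr < 1).any():
        raise ValueError("cluster counts must be >= 1")
    return arr


def goods_coverage(cluster_counts) -> float:
    """Good's criterion C = 1 - (rare clusters / total clusters), where rare
    clusters were observed only once or twice."""
    arr = _counts_array(cluster_counts)
    return 1.0 - (arr <= 2).sum() / arr.size


def shannon_chao(cluster_counts) -> tuple[float, float]:
    """Shannon entropy (nats) and the Chao1 richness estimate.

    Chao1 = S_obs + F1^2 / (2 F2); when no doubletons exist the
    bias-corrected form S_obs + F1(F1-1) / (2(F2+1)) is used.
    """
    arr = _counts_array(cluster_counts)
    p = arr / arr.sum()
    h = float(-(p * np.log(p)).sum())
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    s_obs = arr.size
    if f2 > 0:
        chao1 = s_obs + f1 * f1 / (2.0 * f2)
    else:
        chao1 = s_obs + f1 * (f1 - 1) / 2.0
    return h, float(chao1)


@dataclass(frozen=True)
class DiversitySummary:
    goods_C: float
    shannon_H: float
    chao1: float
    n_clusters: int
    n_rare: int


def diversity_summary(cluster_counts) -> DiversitySummary:
    arr = _counts_array(cluster_counts)
    h, chao1 = shannon_chao(arr)
    return DiversitySummary(
        goods_C=goods_coverage(arr),
        shannon_H=h,
        chao1=chao1,
        n_clusters=arr.size,
        n_rare=int((arr <= 2).sum()),
    )


def loss_confidence(lost: float, n: int, level: float = 0.975) -> float:
    """Half-width of the normal-approximation CI for a lost-spacer fraction:
    conf = z(level) * sqrt(lost * (1 - lost) / N)."""
    if n < 1:
        raise ValueError("group size N must be >= 1")
    if not 0.0 <= lost <= 1.0:
        raise ValueError("lost must be a fraction in [0, 1]")
    z = float(norm.ppf(level))
    return z * float(np.sqrt(lost * (1.0 - lost) / n))


def cross_type_intersection(spacer_sets: dict[str, list[str]], max_mismatch: int = 2):
    """Fraction of type-i spacers with a <=``max_mismatch`` counterpart
    (free end gaps) among type-j spacers, for every ordered type pair."""
    types = sorted(spacer_sets)
    if len(types) < 2:
        raise ValueError("need at least two repeat types")
    mat = pd.DataFrame(np.nan, index=types, columns=types)
    for ti in types:
        for tj in types:
            if ti == tj:
                continue
            src, dst = spacer_sets[ti], spacer_sets[tj]
            if not src:
                continue
            dst_set = set(dst)
            n_hit = 0
            for s in src:
                if s in dst_set or any(
                    mismatch_distance(s, t) <= max_mismatch for t in dst
                ):
                    n_hit += 1
            mat.loc[ti, tj] = n_hit / len(src)
    return mat
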