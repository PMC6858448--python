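"""Directed spacer-pair graphs and CRISPR array reconstruction.

Neighbouring-spacer pairs observed in reads define a directed graph whose
edge weights count pair observations.  Putative chimeric (PCR artifact)
edges are removed when their weight falls below a fraction (default 5%) of
the tail's outgoing weight sum and of the head's incoming weight sum; arrays
are then reconstructed as maximal source-to-sink paths, node eccentricity is
the spacer count of the longest path through a node, and graph components
are grouped by linearly correlated abundance profiles across samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ArrayPath",
    "build_pair_graph",
    "filter_chimeric_edges",
    "break_cycles",
    "reconstruct_paths",
    "node_eccentricity",
    "correlate_components",
]


@dataclass(frozen=True)
class ArrayPath:
    nodes: tuple[str, ...]
    min_weight: int
    component_id: int

    def __len__(self) -> int:
        return len(self.nodes)


def build_pair_graph(pair_table: pd.DataFrame, nodes=None) -> nx.DiGraph:
    """Directed graph from a pair table with columns ``first``/``second``
    (cluster ids); weight = exact pair multiplicity.  ``nodes`` adds clusters
    observed only singly."""
    g = nx.DiGraph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    if len(pair_table):
        counts = pair_table.groupby(["first", "second"]).size()
        for (u, v), w in counts.items():
            g.add_edge(u, v, weight=int(w), self_loop=(u == v))
    return g


def filter_chimeric_edges(g: nx.DiGraph, fraction: float = 0.05, rule: str = "either"):
    """Remove putative chimeric edges by the weight-fraction rule.

    For edge (u, v) of weight w, S_out(u) is the summed weight of u's
    outgoing edges and S_in(v) of v's incoming edges (pre-filter sums,
    single pass).  With rule="either" (default) the edge is removed when w
    falls below fraction * S_out(u) or below fraction * S_in(v); with
    rule="both", both sums must exceed w / fraction.  The default is
    "either" because a chimeric edge into an array-leader spacer (true
    in-degree 0) has an incoming sum made of chimeric traffic only, so the
    both-sums variant can never remove it; the head-side test alone also
    protects the sole outgoing edge of a rare array (w = S_out) from
    deletion only when its head is not shared, which is why "both" remains
    available for communities where arrays share terminal spacers.
    Returns (filtered graph, report).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    if rule not in ("both", "either"):
        raise ValueError("rule must be 'both' or 'either'")
    s_out = {u: sum(d["weight"] for _, _, d in g.out_edges(u, data=True)) for u in g}
    s_in = {v: sum(d["weight"] for _, _, d in g.in_edges(v, data=True)) for v in g}
    rows = []
    removed = []
    for u, v, d in g.edges(data=True):
        w = d["weight"]
        below_out = w < fraction * s_out[u]
        below_in = w < fraction * s_in[v]
        drop = (below_out and below_in) if rule == "both" else (below_out or below_in)
        if drop:
            removed.append((u, v))
        rows.append((u, v, w, drop, f"out={w}/{s_out[u]} in={w}/{s_in[v]}"))
    out = g.copy()
    out.remove_edges_from(removed)
    report = pd.DataFrame(rows, columns=["first", "second", "weight", "removed", "reason"])
    return out, report


def break_cycles(g: nx.DiGraph) -> nx.DiGraph:
    """Remove minimum-weight edges until acyclic (ties: lexicographic edge)."""
    out = g.copy()
    while True:
        try:
            cycle = nx.find_cycle(out)
        except nx.NetworkXNoCycle:
            return out
        edge = min(cycle, key=lambda e: (out.edges[e[0], e[1]]["weight"], e[0], e[1]))
        logger.info("breaking cycle at edge %s -> %s", edge[0], edge[1])
        out.remove_edge(edge[0], edge[1])


def reconstruct_paths(g: nx.DiGraph) -> list[ArrayPath]:
    """All maximal source-to-sink paths of the (cycle-broken) pair graph.

    Branches yield one path per branch; isolated nodes yield length-1 paths.
    """
    dag = break_cycles(g)
    comp_of = {}
    for ci, comp in enumerate(sorted(nx.weakly_connected_components(dag), key=min)):
        for n in comp:
            comp_of[n] = ci
    paths: list[ArrayPath] = []
    sources = sorted(n for n in dag if dag.in_degree(n) == 0)
    for src in sources:
        stack = [(src, [src])]
        while stack:
            node, path = stack.pop()
            succ = sorted(dag.successors(node))
            if not succ:
                weights = [
                    dag.edges[a, b]["weight"] for a, b in zip(path, path[1:])
                ]
                paths.append(
                    ArrayPath(tuple(path), min(weights) if weights else 0, comp_of[src])
                )
            else:
                for nxt in reversed(succ):
                    stack.append((nxt, path + [nxt]))
    return paths


def node_eccentricity(g: nx.DiGraph) -> dict[str, int]:
    """Longest-path spacer count through each node, by DP over the DAG."""
    dag = break_cycles(g)
    order = list(nx.topological_sort(dag))
    longest_in = {n: 0 for n in dag}
    for n in order:
        for _, v in dag.out_edges(n):
            longest_in[v] = max(longest_in[v], longest_in[n] + 1)
    longest_out = {n: 0 for n in dag}
    for n in reversed(order):
        for _, v in dag.out_edges(n):
            longest_out[n] = max(longest_out[n], longest_out[v] + 1)
    return {n: longest_in[n] + longest_out[n] + 1 for n in dag}


def correlate_components(
    component_profiles: pd.DataFrame, r_threshold: float = 0.9
) -> list[set]:
    """Group graph components whose abundance profiles correlate linearly.

    ``component_profiles``: component x sample counts (mean over member
    spacers).  Profiles are log10(count+1)-transformed; components are
    single-linkage grouped at Pearson r >= ``r_threshold``.
    """
    if component_profiles.shape[1] < 2:
        raise ValueError("need at least two samples to correlate components")
    logp = np.log10(component_profiles.to_numpy(dtype=float) + 1.0)
    ids = list(component_profiles.index)
    g = nx.Graph()
    g.add_nodes_from(ids)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(logp)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if corr[i, j] >= r_threshold:
                g.add_edge(ids[i], ids[j])
    return [set(c) for c in sorted(nx.connected_components(g), key=min)]
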