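"""Viral contig assembly by tiling overlapping spacers.

All-vs-all spacer matching (shared exact words, ungapped diagonal identity
over the overlap, both strands) builds an undirected match graph; each
connected component is laid out along a maximum-identity spanning tree and
collapsed to a per-column majority consensus.  Inconsistent relative
placements (conflicting offsets) split a component at its weakest
conflicting edge, replacing the manual alignment curation step of the
original workflow with a logged, deterministic rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .iupac import reverse_complement

logger = logging.getLogger(__name__)

__all__ = ["SpacerMatch", "TiledContig", "all_vs_all_matches", "tile_contigs"]


@dataclass(frozen=True)
class SpacerMatch:
    identity: float
    strand: str  # orientation of b relative to a
    offset: int  # start of (oriented) b in a's coordinate frame
    overlap: int


def _best_diagonal(a: str, b: str, word_size: int):
    """Best ungapped overlap of b against a over diagonals sharing an exact
    word; returns (identity, offset, overlap) or None."""
    la, lb = len(a), len(b)
    words: dict[str, list[int]] = {}
    for i in range(la - word_size + 1):
        words.setdefault(a[i : i + word_size], []).append(i)
    offsets = set()
    for j in range(lb - word_size + 1):
        for i in words.get(b[j : j + word_size], ()):
            offsets.add(i - j)
    if not offsets:
        return None
    ea = np.frombuffer(a.encode(), dtype=np.uint8)
    eb = np.frombuffer(b.encode(), dtype=np.uint8)
    best = None
    for off in sorted(offsets):
        a0, a1 = max(0, off), min(la, off + lb)
        if a1 <= a0:
            continue
        ov = a1 - a0
        ident = float((ea[a0:a1] == eb[a0 - off : a1 - off]).mean())
        if best is None or (ident, ov) > (best[0], best[2]):
            best = (ident, off, ov)
    return best


def all_vs_all_matches(spacers: dict[str, str], min_identity: float = 0.7,
                       word_size: int = 8) -> nx.Graph:
    """Undirected match graph: edge iff the best shared-word ungapped
    diagonal reaches identity > ``min_identity`` over the overlap (both
    strands considered)."""
    if len(spacers) < 2:
        raise ValueError("need at least two spacers")
    g = nx.Graph()
    g.add_nodes_from(sorted(spacers))
    ids = sorted(spacers)
    for i, u in enumerate(ids):
        for v in ids[i + 1 :]:
            a, b = spacers[u].upper(), spacers[v].upper()
            cand = []
            fwd = _best_diagonal(a, b, word_size)
            if fwd:
                cand.append((fwd[0], fwd[2], "+", fwd[1]))
            rev = _best_diagonal(a, reverse_complement(b), word_size)
            if rev:
                cand.append((rev[0], rev[2], "-", rev[1]))
            if not cand:
                continue
            ident, ov, strand, off = max(cand, key=lambda c: (c[0], c[1]))
            if ident > min_identity:
                g.add_edge(
                    u,
                    v,
                    match=SpacerMatch(identity=ident, strand=strand, offset=off, overlap=ov),
                )
    return g


@dataclass
class TiledContig:
    contig_id: str
    consensus: str
    members: list[tuple[str, int, str]]  # (spacer_id, offset, strand)
    depth: np.ndarray
    component_id: int


def _invert(m: SpacerMatch, la: int, lb: int) -> SpacerMatch:
    """Relation of a in b's frame, given the (a, b) relation and lengths."""
    if m.strand == "+":
        return SpacerMatch(m.identity, "+", -m.offset, m.overlap)
    return SpacerMatch(m.identity, "-", m.offset + lb - la, m.overlap)


def _layout_component(g: nx.Graph, nodes, spacers):
    """Place component members; returns (placements, conflicting_edges).

    Edge relations are stored for the id-sorted node pair (a, b): "with a
    forward, b oriented ``strand`` starts at ``offset`` in a's frame".
    """
    sub = g.subgraph(nodes)

    def relation(u, v):
        a, b = sorted((u, v))
        m = sub.edges[u, v]["match"]
        if u == a:
            return m
        return _invert(m, len(spacers[a]), len(spacers[b]))

    def expected(u, v):
        off_u, ori_u = placement[u]
        m = relation(u, v)
        lu, lv = len(spacers[u]), len(spacers[v])
        if ori_u == "+":
            return off_u + m.offset, m.strand
        ori_v = "-" if m.strand == "+" else "+"
        return off_u + lu - (m.offset + lv), ori_v

    # maximum-identity spanning forest (Kruskal with deterministic ties)
    uf = nx.utils.UnionFind(sub.nodes)
    tree = nx.Graph()
    tree.add_nodes_from(sub.nodes)
    for u, v, d in sorted(
        sub.edges(data=True), key=lambda e: (-e[2]["match"].identity, e[0], e[1])
    ):
        if uf[u] != uf[v]:
            uf.union(u, v)
            tree.add_edge(u, v)

    root = max(sorted(nodes), key=lambda n: sub.degree(n))
    placement: dict[str, tuple[int, str]] = {root: (0, "+")}
    for u, v in nx.bfs_edges(tree, root):
        placement[v] = expected(u, v)

    conflicts = []
    for u, v, d in sub.edges(data=True):
        if tree.has_edge(u, v):
            continue
        if expected(u, v) != placement[v]:
            conflicts.append((u, v, d["match"].identity))
    return placement, conflicts


def tile_contigs(g: nx.Graph, spacers: dict[str, str]):
    """Tile each match-graph component into a consensus contig.

    Layout follows a maximum-identity spanning tree from the highest-degree
    node; consensus is the per-column majority (ties: lexicographically
    smallest base).  Components whose non-tree edges imply conflicting
    offsets are split at the weakest conflicting edge (logged) and re-tiled.
    """
    work = g.copy()
    contigs: list[TiledContig] = []
    queue = [set(c) for c in sorted(nx.connected_components(work), key=min)]
    comp_counter = 0
    while queue:
        nodes = queue.pop(0)
        cid = comp_counter
        comp_counter += 1
        if len(nodes) == 1:
            (n,) = nodes
            seq = spacers[n].upper()
            contigs.append(
                TiledContig(
                    contig_id=f"contig{len(contigs):04d}",
                    consensus=seq,
                    members=[(n, 0, "+")],
                    depth=np.ones(len(seq), dtype=int),
                    component_id=cid,
                )
            )
            continue
        placement, conflicts = _layout_component(work, nodes, spacers)
        if conflicts:
            u, v, ident = min(conflicts, key=lambda c: (c[2], c[0], c[1]))
            logger.info("conflicting offsets: splitting at edge %s - %s (id %.3f)", u, v, ident)
            work.remove_edge(u, v)
            sub = work.subgraph(nodes)
            queue = [set(c) for c in sorted(nx.connected_components(sub), key=min)] + queue
            comp_counter -= 1
            continue
        base = min(off for off, _ in placement.values())
        members = sorted(
            (n, off - base, ori) for n, (off, ori) in placement.items()
        )
        length = max(off + len(spacers[n]) for n, off, _ in members)
        counts = np.zeros((length, 4), dtype=int)
        base_idx = {b: i for i, b in enumerate("ACGT")}
        for n, off, ori in members:
            seq = spacers[n].upper()
            if ori == "-":
                seq = reverse_complement(seq)
            for i, b in enumerate(seq):
                if b in base_idx:
                    counts[off + i, base_idx[b]] += 1
        depth = counts.sum(axis=1)
        cons = []
        for row, d in zip(counts, depth):
            if d == 0:
                cons.append("N")
            else:
                cons.append("ACGT"[int(np.argmax(row))])  # argmax: lexicographic tie-break
        contigs.append(
            TiledContig(
                contig_id=f"contig{len(contigs):04d}",
                consensus="".join(cons),
                members=[(n, off, ori) for n, off, ori in members],
                depth=depth,
                component_id=cid,
            )
        )
    return contigs
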