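"""Cycle/flow truss decomposition of directed graphs.

A cycle (flow) *k*-truss is a maximal connected subgraph in which
every link lies in at least *k* cycle (flow) triangles formed by links
of the subgraph.  The truss number of a link is the largest *k* at
which the link still belongs to a *k*-truss; nesting of truss levels
(``E_{k+1} ⊆ E_k``) makes the whole decomposition computable in one
peeling pass.

Two routes are provided:

* :func:`truss_numbers` — support peeling with a lazy min-heap, the
  production path (the directed analogue of the classic undirected
  k-truss peeling: repeatedly delete the link of minimum within-
  subgraph support, taking a running maximum of the deletion levels);
* :func:`naive_truss_numbers` — a direct transcription of the
  definitional fixpoint, quadratic and intended for small graphs; the
  two must agree exactly on every input.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Dict, List, Set, Tuple

import networkx as nx
import pandas as pd

from .triangles import MOTIFS, _check_motif, cycle_support, flow_support

__all__ = [
    "TrussDecomposition",
    "TrussSubgraph",
    "truss_numbers",
    "naive_truss_numbers",
    "extract_k_trusses",
    "max_truss_number",
    "decomposition_to_frame",
]

Link = Tuple[str, str]


@dataclass
class TrussDecomposition:
    """Per-link truss numbers for one motif.

    ``truss_number[(i, j)]`` is the largest k such that link i->j
    belongs to a motif k-truss.  ``links_at_least(k)`` returns the
    nested link sets E_k; E_0 is the full link set and E_{k_max+1} is
    empty.
    """

    motif: str
    truss_number: Dict[Link, int] = field(default_factory=dict)

    @property
    def k_max(self) -> int:
        """Maximum truss number over links; 0 if the graph has no links."""
        return max(self.truss_number.values(), default=0)

    def links_at_least(self, k: int) -> Set[Link]:
        if k < 0:
            raise ValueError(f"truss level must be non-negative, got {k}")
        return {e for e, t in self.truss_number.items() if t >= k}

    @property
    def links(self) -> Set[Link]:
        return set(self.truss_number)


@dataclass
class TrussSubgraph:
    """One maximal connected k-truss: a weakly connected component of E_k."""

    motif: str
    k: int
    links: Set[Link]
    nodes: Set[str]
    strongly_connected: bool

    @property
    def n_links(self) -> int:
        return len(self.links)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.links)
        return g


def _adjacency(graph: nx.DiGraph) -> tuple[Dict[str, Set[str]], Dict[str, Set[str]]]:
    out_adj = {n: set(graph.succ[n]) for n in graph.nodes()}
    in_adj = {n: set(graph.pred[n]) for n in graph.nodes()}
    return out_adj, in_adj


def _cycle_triangles_of(
    i: str, j: str, out_adj: Dict[str, Set[str]], in_adj: Dict[str, Set[str]]
) -> List[Tuple[Link, Link]]:
    """Partner-link pairs of every surviving cycle triangle through i->j."""
    return [
        ((j, w), (w, i))
        for w in out_adj[j]
        if w in in_adj[i] and w != i and w != j
    ]


def _flow_triangles_of(
    i: str, j: str, out_adj: Dict[str, Set[str]], in_adj: Dict[str, Set[str]]
) -> List[Tuple[Link, Link]]:
    """Partner-link pairs of every surviving flow triangle through i->j."""
    pairs: List[Tuple[Link, Link]] = []
    for w in out_adj[i]:
        if w == i or w == j:
            continue
        if w in out_adj[j]:  # i->j source->middle, sink w
            pairs.append(((j, w), (i, w)))
        if w in in_adj[j]:  # i->j source->sink, middle w
            pairs.append(((i, w), (w, j)))
    for w in in_adj[i]:
        if w == i or w == j:
            continue
        if w in in_adj[j]:  # i->j middle->sink, source w
            pairs.append(((w, i), (w, j)))
    return pairs


def truss_numbers(graph: nx.DiGraph, motif: str) -> TrussDecomposition:
    """Truss decomposition by support peeling.

    Computes initial supports, then repeatedly removes the link of
    minimum remaining support (ties broken lexicographically so the
    pass is bit-reproducible), assigning it the running maximum of the
    deletion supports, and decrements the supports of the two partner
    links of every still-present triangle through the removed link.
    Runs in roughly O(sum of supports + m log m).
    """
    _check_motif(motif)
    support_fn = cycle_support if motif == "cycle" else flow_support
    triangles_of = _cycle_triangles_of if motif == "cycle" else _flow_triangles_of

    out_adj, in_adj = _adjacency(graph)
    support: Dict[Link, int] = {
        (u, v): support_fn(graph, u, v) for u, v in graph.edges()
    }
    heap: List[Tuple[int, Link]] = [(s, e) for e, s in support.items()]
    heapq.heapify(heap)

    truss: Dict[Link, int] = {}
    level = 0
    alive = set(support)
    while heap:
        s, e = heapq.heappop(heap)
        if e not in alive or s != support[e]:
            continue  # stale heap entry
        level = max(level, s)
        truss[e] = level
        alive.discard(e)
        i, j = e
        partners = triangles_of(i, j, out_adj, in_adj)
        out_adj[i].discard(j)
        in_adj[j].discard(i)
        for e1, e2 in partners:
            for p in (e1, e2):
                support[p] -= 1
                heapq.heappush(heap, (support[p], p))
    return TrussDecomposition(motif=motif, truss_number=truss)


def naive_truss_numbers(graph: nx.DiGraph, motif: str) -> TrussDecomposition:
    """Definitional fixpoint decomposition (small-graph oracle).

    For k = 1, 2, ...: repeatedly delete links whose within-subgraph
    support is below k until stable; a link deleted while peeling to
    the level-k fixpoint has truss number k - 1.  Terminates because
    supports are finite.
    """
    _check_motif(motif)
    support_fn = cycle_support if motif == "cycle" else flow_support

    g = graph.copy()
    truss: Dict[Link, int] = {}
    k = 1
    while g.number_of_edges() > 0:
        while True:
            doomed = [
                (u, v) for u, v in g.edges() if support_fn(g, u, v) < k
            ]
            if not doomed:
                break
            for e in doomed:
                truss[e] = k - 1
            g.remove_edges_from(doomed)
        k += 1
    return TrussDecomposition(motif=motif, truss_number=truss)


def extract_k_trusses(
    graph: nx.DiGraph,
    motif: str,
    k: int,
    decomposition: TrussDecomposition | None = None,
) -> List[TrussSubgraph]:
    """Maximal connected motif k-trusses of *graph*.

    Returns the weakly connected components of the subgraph induced by
    E_k (the links with truss number >= k), sorted by decreasing link
    count then lexicographic node order.  Their link sets are pairwise
    disjoint; node sets may overlap.  A cycle truss with k >= 1 is
    additionally strongly connected (every link lies on a directed
    3-cycle within it), which is recorded in the result.
    """
    if k < 0:
        raise ValueError(f"truss level must be non-negative, got {k}")
    dec = decomposition if decomposition is not None else truss_numbers(graph, motif)
    if dec.motif != motif:
        raise ValueError(f"decomposition is for motif {dec.motif!r}, requested {motif!r}")
    links = dec.links_at_least(k)
    sub = nx.DiGraph()
    sub.add_edges_from(links)
    out: List[TrussSubgraph] = []
    for comp in nx.weakly_connected_components(sub):
        comp_g = sub.subgraph(comp)
        out.append(
            TrussSubgraph(
                motif=motif,
                k=k,
                links=set(comp_g.edges()),
                nodes=set(comp),
                strongly_connected=nx.is_strongly_connected(comp_g),
            )
        )
    out.sort(key=lambda t: (-t.n_links, sorted(t.nodes)))
    return out


def max_truss_number(decomposition: TrussDecomposition) -> int:
    """Maximum truss number over links (0 for a link-free graph)."""
    return decomposition.k_max


def decomposition_to_frame(
    cycle_dec: TrussDecomposition, flow_dec: TrussDecomposition
) -> pd.DataFrame:
    """One row per link with both truss numbers (source, target, k_cycle, k_flow)."""
    if set(cycle_dec.truss_number) != set(flow_dec.truss_number):
        raise ValueError("cycle and flow decompositions cover different link sets")
    rows = [
        {
            "source": u,
            "target": v,
            "k_cycle": cycle_dec.truss_number[(u, v)],
            "k_flow": flow_dec.truss_number[(u, v)],
        }
        for u, v in sorted(cycle_dec.truss_number)
    ]
    return pd.DataFrame(rows, columns=["source", "target", "k_cycle", "k_flow"])
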