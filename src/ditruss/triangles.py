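"""Directed-triangle classification and per-link support counting.

Two triangle motifs are recognised:

* **cycle** triangle — three nodes each with out-degree 1 within the
  triangle, i.e. a directed 3-cycle ``i -> j -> w -> i``;
* **flow** triangle (feedforward loop) — three nodes with out-degrees
  2, 1 and 0 within the triangle: a source, a middle and a sink, with
  links ``source -> middle``, ``middle -> sink`` and ``source -> sink``.

A triangle is identified with its set of three links, not its node
set: a bidirectionally connected triple of nodes carries 2 distinct
cycle triangles and 6 distinct flow triangles.  The *support* of a
link for a motif is the number of distinct triangles of that motif
whose link set contains it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Tuple

import networkx as nx
import pandas as pd

__all__ = [
    "MOTIFS",
    "LinkSupportMap",
    "cycle_support",
    "flow_support",
    "support_map",
    "enumerate_triangles",
    "support_to_frame",
]

MOTIFS = ("cycle", "flow")

Link = Tuple[str, str]
Triangle = FrozenSet[Link]


def _check_motif(motif: str) -> None:
    if motif not in MOTIFS:
        raise ValueError(f"unknown motif {motif!r}; expected one of {MOTIFS}")


def _check_link(graph: nx.DiGraph, i: str, j: str) -> None:
    if not graph.has_edge(i, j):
        raise KeyError(f"link {i!r} -> {j!r} is not in the graph")


@dataclass
class LinkSupportMap:
    """Per-link triangle counts for one motif.

    ``support`` maps every link of the source graph to the number of
    motif triangles containing it.  The sum of supports is exactly
    three times the number of triangles, since each triangle has three
    links.
    """

    motif: str
    support: Dict[Link, int] = field(default_factory=dict)

    def __getitem__(self, link: Link) -> int:
        return self.support[link]

    def total(self) -> int:
        return sum(self.support.values())


def cycle_support(graph: nx.DiGraph, i: str, j: str) -> int:
    """Number of cycle triangles containing the link ``i -> j``.

    Each third node ``w`` with ``j -> w`` and ``w -> i`` closes one
    directed 3-cycle through the link.
    """
    _check_link(graph, i, j)
    succ_j = graph.succ[j]
    pred_i = graph.pred[i]
    return sum(1 for w in succ_j if w in pred_i and w != i and w != j)


def flow_support(graph: nx.DiGraph, i: str, j: str) -> int:
    """Number of flow triangles (feedforward loops) containing ``i -> j``.

    The link can play three roles; each (role, third node) pair is a
    distinct triangle:

    * source -> middle: sink ``w`` with ``i -> w`` and ``j -> w``;
    * middle -> sink: source ``w`` with ``w -> i`` and ``w -> j``;
    * source -> sink: middle ``w`` with ``i -> w`` and ``w -> j``.
    """
    _check_link(graph, i, j)
    succ_i, pred_i = graph.succ[i], graph.pred[i]
    succ_j, pred_j = graph.succ[j], graph.pred[j]
    n = 0
    for w in succ_i:
        if w == i or w == j:
            continue
        if w in succ_j:  # i source, j middle, w sink
            n += 1
        if w in pred_j:  # i source, w middle, j sink
            n += 1
    for w in pred_i:
        if w == i or w == j:
            continue
        if w in pred_j:  # w source, i middle, j sink
            n += 1
    return n


def support_map(graph: nx.DiGraph, motif: str) -> LinkSupportMap:
    """Support of every link of *graph* for *motif*."""
    _check_motif(motif)
    fn = cycle_support if motif == "cycle" else flow_support
    return LinkSupportMap(
        motif=motif, support={(u, v): fn(graph, u, v) for u, v in graph.edges()}
    )


def enumerate_triangles(graph: nx.DiGraph, motif: str) -> List[Triangle]:
    """All motif triangles of *graph*, each as a frozen set of 3 links.

    The list is duplicate-free and sorted for reproducible output.
    """
    _check_motif(motif)
    out: List[Triangle] = []
    if motif == "cycle":
        # i -> j -> w -> i; count once by requiring i to be the least label.
        for i, j in graph.edges():
            if j < i:
                continue
            for w in graph.succ[j]:
                if w > i and w != j and i in graph.succ[w]:
                    out.append(frozenset(((i, j), (j, w), (w, i))))
    else:
        # Each flow triangle found exactly once via its source->middle
        # link (s, m) and the common successor t.
        for s, m in graph.edges():
            succ_m = graph.succ[m]
            for t in graph.succ[s]:
                if t != m and t != s and t in succ_m:
                    out.append(frozenset(((s, m), (m, t), (s, t))))
    return sorted(out, key=sorted)


def support_to_frame(smap: LinkSupportMap) -> pd.DataFrame:
    """Tabulate a support map as a DataFrame (source, target, support, motif)."""
    rows = [
        {"source": u, "target": v, "support": s, "motif": smap.motif}
        for (u, v), s in sorted(smap.support.items())
    ]
    return pd.DataFrame(rows, columns=["source", "target", "support", "motif"])
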