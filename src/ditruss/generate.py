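"""Seeded synthetic directed networks for testing and demonstration.

Deterministic structured generators (complete bidirectional graphs,
directed cycles, transitive tournaments), a seeded Erdos-Renyi noise
model, and a planted-truss benchmark that embeds truss-rich blocks in
sparse noise with known ground truth.  Node labels are opaque strings
of the form ``n<index>``.

Reference truss structure of the building blocks:

* complete bidirectional graph on n nodes — every link has cycle truss
  number n - 2 and flow truss number 3(n - 2);
* transitive tournament on n nodes — acyclic, every link has flow
  truss number n - 2 and cycle truss number 0;
* directed n-cycle with n >= 4 — triangle-free, all truss numbers 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from typing import List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

__all__ = [
    "complete_bidirectional",
    "directed_cycle",
    "transitive_tournament",
    "er_directed",
    "PlantedBlock",
    "planted_truss",
]

Link = Tuple[str, str]


def _labels(n: int, offset: int = 0) -> List[str]:
    return [f"n{i + offset}" for i in range(n)]


def complete_bidirectional(n: int) -> nx.DiGraph:
    """Complete graph on *n* nodes with every pair linked in both directions."""
    if n < 1:
        raise ValueError(f"need n >= 1, got {n}")
    g = nx.DiGraph()
    labels = _labels(n)
    g.add_nodes_from(labels)
    g.add_edges_from(permutations(labels, 2))
    return g


def directed_cycle(n: int) -> nx.DiGraph:
    """Directed cycle n0 -> n1 -> ... -> n(n-1) -> n0; n >= 3."""
    if n < 3:
        raise ValueError(f"need n >= 3 for a directed cycle, got {n}")
    labels = _labels(n)
    g = nx.DiGraph()
    g.add_edges_from(zip(labels, labels[1:] + labels[:1]))
    return g


def transitive_tournament(n: int) -> nx.DiGraph:
    """Acyclic tournament: link i -> j for every i < j; n >= 2."""
    if n < 2:
        raise ValueError(f"need n >= 2 for a tournament, got {n}")
    labels = _labels(n)
    g = nx.DiGraph()
    g.add_nodes_from(labels)
    g.add_edges_from(combinations(labels, 2))
    return g


def er_directed(n: int, p: float, seed: int = 0) -> nx.DiGraph:
    """Directed Erdos-Renyi graph: each ordered pair linked with probability *p*."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"link probability must be in [0, 1], got {p}")
    if n < 1:
        raise ValueError(f"need n >= 1, got {n}")
    rng = np.random.default_rng(seed)
    labels = _labels(n)
    g = nx.DiGraph()
    g.add_nodes_from(labels)
    if p > 0:
        mask = rng.random((n, n)) < p
        np.fill_diagonal(mask, False)
        for i, j in zip(*np.nonzero(mask)):
            g.add_edge(labels[i], labels[j])
    return g


@dataclass
class PlantedBlock:
    """Ground truth of one embedded block.

    ``kind`` is ``"bidirectional"`` (cycle- and flow-truss-rich) or
    ``"tournament"`` (flow-truss only); ``links`` is the set of links
    the block contributed.
    """

    kind: str
    nodes: Tuple[str, ...]
    links: Set[Link]


_BLOCK_KINDS = ("bidirectional", "tournament")


def planted_truss(
    noise_n: int,
    noise_p: float,
    blocks: Sequence[Tuple[str, int]],
    seed: int = 0,
    block_nodes: Optional[Sequence[Sequence[str]]] = None,
) -> tuple[nx.DiGraph, List[PlantedBlock]]:
    """Embed truss-rich blocks into sparse directed noise.

    Parameters
    ----------
    noise_n, noise_p
        Size and link probability of the Erdos-Renyi background.
    blocks
        Sequence of ``(kind, size)`` pairs with kind in
        ``{"bidirectional", "tournament"}`` and size >= 3.  A
        bidirectional block of size b plants links with cycle truss
        number >= b - 2; a tournament block plants flow structure only.
    seed
        Drives both the noise graph and the choice of block nodes.
    block_nodes
        Optional explicit (disjoint) node subsets, one per block; by
        default disjoint subsets are drawn from the noise nodes.

    Returns
    -------
    (graph, planted)
        The composite graph and one :class:`PlantedBlock` per block;
        a planted link set includes every link of the block (links
        that coincided with noise links are still ground truth).
    """
    for kind, b in blocks:
        if kind not in _BLOCK_KINDS:
            raise ValueError(f"unknown block kind {kind!r}; expected one of {_BLOCK_KINDS}")
        if b < 3:
            raise ValueError(f"block size must be >= 3, got {b}")
    g = er_directed(noise_n, noise_p, seed=seed)
    all_nodes = sorted(g.nodes())

    if block_nodes is None:
        need = sum(b for _, b in blocks)
        if need > noise_n:
            raise ValueError(f"blocks need {need} nodes but the noise graph has {noise_n}")
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
        chosen = [str(n) for n in rng.permutation(all_nodes)]
        block_nodes = []
        pos = 0
        for _, b in blocks:
            block_nodes.append(chosen[pos : pos + b])
            pos += b
    else:
        flat = [n for sub in block_nodes for n in sub]
        if len(set(flat)) != len(flat):
            raise ValueError("block node sets overlap; ground truth would be ambiguous")
        missing = set(flat) - set(all_nodes)
        if missing:
            raise ValueError(f"block nodes not in the noise graph: {sorted(missing)}")

    planted: List[PlantedBlock] = []
    for (kind, b), nodes in zip(blocks, block_nodes):
        nodes = tuple(str(n) for n in nodes)
        if kind == "bidirectional":
            links = set(permutations(nodes, 2))
        else:
            links = set(combinations(sorted(nodes), 2))
        # Clean embedding: stray noise links among block nodes (e.g. the
        # reverse of a tournament link) would join the planted truss and
        # blur the ground truth, so the intra-block subgraph is exactly
        # the block.
        g.remove_edges_from(list(permutations(nodes, 2)))
        g.add_edges_from(links)
        planted.append(PlantedBlock(kind=kind, nodes=nodes, links=links))
    return g, planted
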