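"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's role-intersection
counting and peeling paths: triangles are classified by exhaustive
inspection of every 3-link subset over every 3-node combination, so
they can arbitrate the production implementations.
"""

from collections import Counter
from itertools import combinations

import networkx as nx
import pytest

import ditruss as dt


def brute_triangles(graph: nx.DiGraph, motif: str):
    """All motif triangles as frozen 3-link sets, by exhaustive enumeration."""
    found = set()
    for trio in combinations(sorted(graph.nodes()), 3):
        trio_set = set(trio)
        links = [
            (u, v)
            for u, v in graph.edges()
            if u in trio_set and v in trio_set
        ]
        for three in combinations(links, 3):
            pairs = {frozenset(e) for e in three}
            if len(pairs) != 3:
                continue  # some node pair covered twice: not a triangle
            out_deg = Counter(u for u, _ in three)
            degs = sorted(out_deg.get(n, 0) for n in trio)
            if motif == "cycle" and degs == [1, 1, 1]:
                found.add(frozenset(three))
            elif motif == "flow" and degs == [0, 1, 2]:
                found.add(frozenset(three))
    return found


def brute_support(graph: nx.DiGraph, motif: str):
    """Per-link triangle counts derived from the brute-force enumeration."""
    support = {e: 0 for e in graph.edges()}
    for tri in brute_triangles(graph, motif):
        for e in tri:
            support[e] += 1
    return support


def random_small_graph(seed: int, max_n: int = 7) -> nx.DiGraph:
    """A seeded random directed graph with at most *max_n* nodes."""
    import numpy as np

    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, max_n + 1))
    p = float(rng.uniform(0.1, 0.7))
    return dt.er_directed(n, p, seed=int(rng.integers(0, 2**31 - 1)))


def recovery_scores(planted_links, dec: dt.TrussDecomposition):
    """Precision/recall of the planted links at the decomposition's top level."""
    top = dec.links_at_least(dec.k_max)
    planted = set(planted_links)
    if not top:
        return 0.0, 0.0
    tp = len(top & planted)
    return tp / len(top), tp / len(planted)


@pytest.fixture
def three_cycle() -> nx.DiGraph:
    g, _ = dt.read_edge_list(iter(["a b", "b c", "c a"]))
    return g


@pytest.fixture
def feedforward() -> nx.DiGraph:
    g, _ = dt.read_edge_list(iter(["a b", "b c", "a c"]))
    return g
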