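"""Degree-preserving randomization (directed configuration-model null).

The null model preserves every node's in-degree and out-degree while
randomizing which nodes are connected, sampled by a Markov chain of
directed double-edge swaps: pick links (a->b) and (c->d) and replace
them with (a->d) and (c->b), rejecting any swap that would create a
self-loop or a duplicate directed link.  This destroys triangles in
expectation, which is what the D (truss-orientedness) measure exploits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List

import networkx as nx
import numpy as np

__all__ = ["RewireReport", "degree_preserving_rewire", "randomized_ensemble"]

#: Successful swaps per link by default; a standard mixing heuristic.
DEFAULT_SWAP_FACTOR = 10.0

#: Attempts allowed per requested successful swap before giving up
#: (terminates the chain on frozen graphs such as complete ones).
ATTEMPT_CAP_FACTOR = 100


@dataclass
class RewireReport:
    """Provenance of one rewiring run."""

    attempted: int
    successful: int
    target: int
    seed: int
    swap_factor: float

    @property
    def exhausted(self) -> bool:
        """True if the attempt cap was hit before reaching the target."""
        return self.successful < self.target


def degree_preserving_rewire(
    graph: nx.DiGraph,
    swap_factor: float = DEFAULT_SWAP_FACTOR,
    seed: int = 0,
) -> tuple[nx.DiGraph, RewireReport]:
    """Randomize *graph* by directed double-edge swaps.

    Runs until ``ceil(swap_factor * |E|)`` successful swaps or until
    the attempt cap (100x the target) is hit.  The result has exactly
    the in- and out-degree of every node of the input, the same |E|,
    and is simple.  Deterministic for a fixed seed.  A swap_factor of
    0 returns the graph unchanged (identity null ensemble).
    """
    if swap_factor < 0:
        raise ValueError(f"swap_factor must be >= 0, got {swap_factor}")
    g = graph.copy()
    m = g.number_of_edges()
    target = int(math.ceil(swap_factor * m))
    if m < 2 or target == 0:
        return g, RewireReport(0, 0, target if m >= 2 else 0, seed, swap_factor)

    rng = np.random.default_rng(seed)
    links: List[tuple] = sorted(g.edges())  # canonical order: seed-stable runs
    index = {e: i for i, e in enumerate(links)}
    present = set(links)

    attempted = successful = 0
    cap = ATTEMPT_CAP_FACTOR * target
    while successful < target and attempted < cap:
        attempted += 1
        x, y = rng.integers(0, m, size=2)
        if x == y:
            continue
        a, b = links[x]
        c, d = links[y]
        if a == d or c == b:
            continue  # would create a self-loop
        e1, e2 = (a, d), (c, b)
        if e1 in present or e2 in present:
            continue  # would create a duplicate link
        for old, new in (((a, b), e1), ((c, d), e2)):
            present.discard(old)
            present.add(new)
            i = index.pop(old)
            links[i] = new
            index[new] = i
            g.remove_edge(*old)
            g.add_edge(*new)
        successful += 1
    return g, RewireReport(attempted, successful, target, int(seed), swap_factor)


def replicate_seeds(master_seed: int, n: int) -> List[int]:
    """Reproducible per-replicate seeds derived from a master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n)
    return [int(s) & 0x7FFFFFFF for s in state]


def randomized_ensemble(
    graph: nx.DiGraph,
    n_replicates: int = 100,
    seed: int = 0,
    swap_factor: float = DEFAULT_SWAP_FACTOR,
) -> List[nx.DiGraph]:
    """*n_replicates* independent degree-preserving rewirings.

    Per-replicate seeds are derived from *seed* through a seed
    sequence, so the whole ensemble is reproducible.  100 replicates
    is the conventional ensemble size for the D measure.
    """
    if n_replicates < 1:
        raise ValueError(f"n_replicates must be >= 1, got {n_replicates}")
    return [
        degree_preserving_rewire(graph, swap_factor=swap_factor, seed=s)[0]
        for s in replicate_seeds(seed, n_replicates)
    ]
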