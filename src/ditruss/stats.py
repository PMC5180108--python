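"""Truss-number statistics: distributions, the D measure, the R overlap.

All statistics are computed over the per-link truss-number multiset
(one value per link, not per truss).

* ``distribution`` — frequency f(k), cumulative F(k) and median of a
  decomposition's truss numbers.
* ``d_measure`` — truss-orientedness against a degree-preserving
  randomized ensemble:

      D = (1/K) * sum_{k=0}^{K} (F_rand(k) - F_orig(k)),
      K = min{k : F_orig(k) > 0.9 and F_rand(k) > 0.9}.

  D is positive when links of the original network carry larger truss
  numbers than expected under the configuration-model null.
* ``r_measure`` — overlap of cohesive cycle and flow trusses: among
  links strictly above the median in either truss number, the fraction
  strictly above the median in both.
* ``joint_distribution`` — the joint (k_cycle, k_flow) proportion table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .decomposition import TrussDecomposition, truss_numbers
from .randomize import DEFAULT_SWAP_FACTOR, randomized_ensemble
from .triangles import _check_motif

__all__ = [
    "TrussNumberDistribution",
    "DResult",
    "RResult",
    "distribution",
    "d_from_distributions",
    "d_measure",
    "r_measure",
    "joint_distribution",
]


@dataclass
class TrussNumberDistribution:
    """Frequency distribution of per-link truss numbers.

    ``f[k]`` is the fraction of links with truss number k (indexed
    0..k_max, summing to 1); ``F`` is its running cumulative sum;
    ``median`` is the sample median of the link truss-number multiset
    (mean of the two middle order statistics for an even link count,
    so it may be half-integral).
    """

    f: np.ndarray
    F: np.ndarray
    median: float
    n_links: int

    @property
    def k_max(self) -> int:
        return len(self.f) - 1

    def cumulative(self, k: int) -> float:
        """F(k), extended with F = 1 beyond k_max."""
        return 1.0 if k >= len(self.F) else float(self.F[k])


def distribution(decomposition: TrussDecomposition) -> TrussNumberDistribution:
    """Frequency/cumulative distribution and median of a decomposition."""
    values = np.fromiter(decomposition.truss_number.values(), dtype=np.int64)
    if values.size == 0:
        raise ValueError("truss-number distribution is undefined for a graph with no links")
    counts = np.bincount(values)
    f = counts / values.size
    return TrussNumberDistribution(
        f=f, F=np.cumsum(f), median=float(np.median(values)), n_links=int(values.size)
    )


@dataclass
class DResult:
    """The D truss-orientedness statistic and its provenance."""

    D: float
    K: int
    motif: str
    n_replicates: int
    seed: int
    swap_factor: float
    F_orig: np.ndarray
    F_rand: np.ndarray
    degenerate: bool = False  # K == 0: both networks essentially truss-free


def d_from_distributions(
    F_orig: np.ndarray, F_rand: np.ndarray, threshold: float = 0.9
) -> tuple[float, int]:
    """Evaluate D and the cutoff K from two cumulative distributions.

    Both arrays are cumulative over k = 0, 1, ... and are treated as 1
    beyond their last entry.  K is the smallest k at which both exceed
    *threshold*; when K = 0 the normalisation 1/K is undefined and D
    is reported as 0 (both distributions are concentrated at k = 0 and
    every term of the sum is bounded by 1 - threshold).
    """

    def cum(F: np.ndarray, k: int) -> float:
        return 1.0 if k >= len(F) else float(F[k])

    k = 0
    while not (cum(F_orig, k) > threshold and cum(F_rand, k) > threshold):
        k += 1
    K = k
    if K == 0:
        return 0.0, 0
    total = sum(cum(F_rand, k) - cum(F_orig, k) for k in range(K + 1))
    return total / K, K


def d_measure(
    graph: nx.DiGraph,
    motif: str,
    n_replicates: int = 100,
    seed: int = 0,
    swap_factor: float = DEFAULT_SWAP_FACTOR,
) -> DResult:
    """Truss-orientedness D of *graph* for *motif*.

    Decomposes the original graph and each of *n_replicates* degree-
    preserving rewirings; the null frequency distribution f_rand is
    the arithmetic mean of the per-replicate f's (equivalent to
    pooling links, since |E| is conserved by the rewiring).
    """
    _check_motif(motif)
    if graph.number_of_edges() == 0:
        raise ValueError("D is undefined for a graph with no links")
    d_orig = distribution(truss_numbers(graph, motif))
    reps = [
        distribution(truss_numbers(g, motif))
        for g in randomized_ensemble(
            graph, n_replicates=n_replicates, seed=seed, swap_factor=swap_factor
        )
    ]
    width = max([d_orig.k_max] + [r.k_max for r in reps]) + 1
    padded = np.stack(
        [np.pad(r.f, (0, width - len(r.f))) for r in reps]
    )
    if np.all(padded == padded[0]):
        f_rand = padded[0]  # identical replicates: keep the mean exact
    else:
        f_rand = padded.mean(axis=0)
    F_rand = np.cumsum(f_rand)
    F_orig = np.pad(d_orig.F, (0, width - len(d_orig.F)), constant_values=1.0)
    D, K = d_from_distributions(F_orig, F_rand)
    return DResult(
        D=D,
        K=K,
        motif=motif,
        n_replicates=n_replicates,
        seed=int(seed),
        swap_factor=swap_factor,
        F_orig=F_orig,
        F_rand=F_rand,
        degenerate=(K == 0),
    )


@dataclass
class RResult:
    """Overlap R between cohesive cycle and flow trusses.

    ``R = |{e : k_c(e) > med_c and k_f(e) > med_f}| /
         |{e : k_c(e) > med_c or  k_f(e) > med_f}|``

    with strict inequalities against the medians of the two per-link
    truss-number multisets.  When no link exceeds either median (e.g.
    all truss numbers equal), the denominator is empty and R is
    undefined, flagged rather than reported as 0.
    """

    R: Optional[float]
    defined: bool
    k_cycle_median: float
    k_flow_median: float
    numerator: int
    denominator: int


def _check_same_links(a: TrussDecomposition, b: TrussDecomposition) -> None:
    if set(a.truss_number) != set(b.truss_number):
        raise ValueError("decompositions cover different link sets")


def r_measure(
    cycle_dec: TrussDecomposition, flow_dec: TrussDecomposition
) -> RResult:
    """Overlap of links with above-median cycle and flow truss numbers."""
    _check_same_links(cycle_dec, flow_dec)
    med_c = distribution(cycle_dec).median
    med_f = distribution(flow_dec).median
    num = den = 0
    for e, kc in cycle_dec.truss_number.items():
        kf = flow_dec.truss_number[e]
        above_c, above_f = kc > med_c, kf > med_f
        if above_c and above_f:
            num += 1
        if above_c or above_f:
            den += 1
    if den == 0:
        return RResult(None, False, med_c, med_f, 0, 0)
    return RResult(num / den, True, med_c, med_f, num, den)


def joint_distribution(
    cycle_dec: TrussDecomposition, flow_dec: TrussDecomposition
) -> pd.DataFrame:
    """Joint proportion table of (k_cycle, k_flow) over links.

    Rows are cycle truss numbers 0..k_c_max, columns flow truss
    numbers 0..k_f_max; cells are fractions of links and sum to 1.
    Row/column sums equal the marginal frequency distributions.
    """
    _check_same_links(cycle_dec, flow_dec)
    if not cycle_dec.truss_number:
        raise ValueError("joint distribution is undefined for a graph with no links")
    table = np.zeros((cycle_dec.k_max + 1, flow_dec.k_max + 1))
    for e, kc in cycle_dec.truss_number.items():
        table[kc, flow_dec.truss_number[e]] += 1
    table /= table.sum()
    return pd.DataFrame(
        table,
        index=pd.Index(range(cycle_dec.k_max + 1), name="k_cycle"),
        columns=pd.Index(range(flow_dec.k_max + 1), name="k_flow"),
    )
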