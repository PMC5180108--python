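# Methods

## Model

`ditruss` operates on simple directed graphs: no self-loops, no
duplicate links in the same direction; a bidirectional pair *i→j*,
*j→i* is two links. Links are unweighted. Two directed triangle
motifs are recognised — the directed 3-cycle ("cycle triangle") and
the feedforward loop ("flow triangle", out-degrees 2/1/0). The other
five directed triangle types are intentionally out of scope.

A triangle is identified with its **set of three links**, not its node
set. This matters for bidirectionally connected triples, which carry
2 cycle and 6 flow triangles; it is also what makes the closed form
for complete bidirectional graphs hold (cycle truss number *n*−2, flow
truss number 3(*n*−2) on every link), which the test suite uses as an
anchor for *n* = 3..8.

The motif *support* of a link is the number of motif triangles whose
link set contains it. A cycle (flow) *k*-truss is a maximal connected
subgraph in which every link has within-subgraph support ≥ *k*. The
truss number of a link is the largest *k* at which it belongs to a
*k*-truss; the surviving link sets *E<sub>k</sub>* are nested.

### Connectivity convention

"Connected" is read as **weakly connected** when delineating maximal
trusses. Flow trusses are generally not strongly connected (a layered
feedforward structure has sources and sinks), so weak connectivity is
the only uniform choice; truss *numbers* are unaffected by the
convention, only component boundaries depend on it. Cycle trusses
with *k* ≥ 1 are nevertheless strongly connected as a theorem (every
link lies on a directed 3-cycle inside the component, and mutual
reachability propagates across weak connections), and the
implementation asserts and reports this per component.

### Level bound

The truss level is not asserted to be bounded by any function of the
maximum degree. Under the total-degree convention (in + out), the
complete bidirectional graph on *n* nodes has d_max = 2(*n*−1) while
its flow truss level is 3(*n*−2), which exceeds d_max − 1 for *n* ≥ 5;
d_max is therefore reported informationally only.

## Algorithms

### Peeling (production path)

Initial supports are computed by role-based neighbor intersections:
for *i→j*, cycle support is |succ(*j*) ∩ pred(*i*)|, and flow support
is the sum over the three roles the link can play (source→middle,
middle→sink, source→sink), each a two-set intersection, with the
endpoints excluded. Distinct (role, third-node) combinations are
distinct triangles and are all counted.

Decomposition then repeatedly removes the link of minimum remaining
support, assigns it the running maximum of the removal supports, and
decrements the supports of the two partner links of every still-present
triangle through the removed link. This is the directed analogue of
the classical undirected k-truss peeling (equivalently: degeneracy
ordering of the hypergraph whose vertices are links and whose
hyperedges are triangles). A lazy min-heap keyed by (support, link)
gives O((Σ support + m) log m) time; the lexicographic tie-break makes
the pass bit-reproducible, although truss numbers themselves are
order-independent.

### Definitional fixpoint (oracle path)

`naive_truss_numbers` transcribes the definition directly: for
*k* = 1, 2, …, repeatedly delete links whose within-subgraph support is
below *k* until stable; a link deleted while peeling to the level-*k*
fixpoint has truss number *k*−1. It is quadratic and kept solely as
an independent oracle: the suite requires exact agreement with the
peeling path on hundreds of random graphs (≤ 7 nodes, both motifs)
plus all structured fixtures, and separately validates the support
counts against exhaustive classification of every 3-link subset of
every 3-node combination.

### Randomization

The null model is the directed configuration model, sampled by
directed double-edge swaps: (a→b), (c→d) → (a→d), (c→b), rejecting
swaps that would create a self-loop or duplicate link. In- and
out-degrees of every node and |E| are conserved exactly; reciprocity
and triangle counts are not (deliberately — triangle attrition under
the null is what D measures). Defaults: 10 successful swaps per link
(a standard mixing heuristic; the choice is not critical because D is
an ensemble average), attempt cap of 100× the target so frozen graphs
(e.g. complete bidirectional ones, where every swap is rejected)
terminate with a flagged report. Ensemble seeds are spawned from a
master seed through `numpy.random.SeedSequence`, so ensembles are
reproducible end to end. `swap_factor=0` yields the identity
ensemble, used to verify D = 0 exactly.

## Statistics

All statistics are computed over the per-link truss-number multiset.

* **Distributions.** f(k) is the fraction of links with truss number
  k; F is its cumulative sum; the median is the sample median (mean of
  the two middle order statistics for even link counts, so it can be
  half-integral — strict comparisons in R remain well defined).
* **D.** F_rand is the cumulative of the arithmetic mean of the
  per-replicate f's; since |E| is conserved by the rewiring this
  equals pooling all replicate links. The cutoff K is the smallest k
  at which both cumulatives exceed 0.9. When K = 0 (both networks
  essentially truss-free) the 1/K normalisation is undefined and D is
  reported as 0 with a `degenerate` flag; every term of the sum is
  bounded by 0.1 in that regime. Note D is an average of K+1 terms
  divided by K, so for distributions with F_orig(K) barely above 0.9
  it can exceed 1 by a sliver; the attainable extremes on concentrated
  distributions are exactly ±1 and the bound holds in all randomized
  trials. If every replicate's f equals the first one the mean is
  taken exactly (no floating-point drift), so the identity-ensemble
  contract D = 0 holds to the bit.
* **R.** Strict inequalities against the two medians. An empty
  denominator set (e.g. all truss numbers equal) makes R undefined;
  this is flagged explicitly rather than coerced to 0, which would
  misclassify perfectly truss-covered graphs.
* **Joint table.** Proportion of links per (k_cycle, k_flow) cell;
  marginals equal the two univariate f's exactly.

## Synthetic data

The generators produce the package's entire test surface; nothing is
downloaded.

* Structured graphs with known decompositions: complete bidirectional
  graphs (cycle- and flow-truss-rich), transitive tournaments (flow
  support uniformly n−2, no cycles), directed n-cycles (triangle-free
  for n ≥ 4).
* Seeded directed Erdős–Rényi noise.
* `planted_truss`: truss-rich blocks embedded at randomly chosen
  disjoint node subsets inside sparse ER noise, returning the planted
  link sets as ground truth. Block node sets must be disjoint, and
  the intra-block subgraph is made *exactly* the block (any stray
  noise link between block nodes is removed before embedding): a
  reverse noise link inside a tournament block would otherwise join
  the planted truss at top level and make the ground truth ambiguous.

The planted benchmark emulates the situation the method targets — a
cohesive directed module inside a sparse background — and recovery of
the planted links at the top truss level is the package's
parameter-recovery check. Defaults used throughout (60 noise nodes at
link probability 0.01, one block of 5–6 nodes) keep the background far
from percolating into triangles, which is what makes exact recovery
the correct expectation. What passing these tests does **not** show:
real networks have heavy-tailed degrees, reciprocity correlations and
overlapping modules that ER noise lacks, so recovery rates here do not
transfer to empirical data; on real data the decomposition is exact
regardless (it is combinatorial), but the discriminative power of
D and R must be judged against the degree-preserving null, not against
these fixtures.

## Numerical and edge-case choices

* k_max of a link-free graph is 0.
* Truss numbers attach to links; node membership is induced.
* Distribution, D and R are undefined (raised or flagged) for graphs
  with no links, rather than silently 0.
* Edge-list parsing drops self-loops and duplicate links with a
  warning and a cleanup report by default (real edge lists are dirty;
  the model assumes simple graphs); `--strict` raises instead.
  Fields beyond source/target (e.g. weights) are ignored.
* All iteration orders that reach output files are canonicalized
  (sorted links/components), so identical configurations produce
  byte-identical outputs regardless of hash randomization.

## Problem sizes

The test suite and the acceptance script run on graphs of roughly
20–100 links: large enough that the peeling path, the null ensemble
and the statistics are all exercised non-trivially, small enough that
the quadratic definitional oracle can arbitrate every decomposition.
The peeling implementation itself is near-linear in the triangle count
and handles much larger networks; only the oracle comparisons are kept
small.

## Known limitations

* Weighted and temporal networks are out of scope; the motif set is
  fixed to the two triangle types.
* The double-edge-swap chain samples the degree-sequence space
  approximately uniformly; no exact-uniformity guarantee is made, and
  reciprocity is not preserved.
* Truss maintenance under edge insertion/deletion is not supported;
  each call decomposes from scratch.
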