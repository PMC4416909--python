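# Methods

## Problem formulation

A partition of an undirected, unweighted simple graph is scored by
modularity `Q = Σ_C [l_C/m − (k_C/2m)²]`, split into two objectives to be
maximized jointly: the intra-community edge fraction `IntraQ = Σ_C l_C/m`
and the shifted degree penalty `InterQ = 1 − Σ_C (k_C/2m)²`.  The constant
shift places both objectives in [0, 1] without changing optima, and
`Q = IntraQ + InterQ − 1` holds as an exact identity (asserted to 1e−12 in
the tests).  The two terms pull in opposite directions with respect to
community size — splitting any community can only lower `IntraQ` and raise
`InterQ` — so the Pareto front of the bi-objective problem spans partitions
from one community (IntraQ = 1) to all-singletons, and a single run exposes
the network's structure at multiple resolutions.

Solutions use the group-based encoding: a length-n vector of community
labels, decoded by grouping nodes with equal labels.  Many label vectors
encode one partition; a first-appearance renumbering gives a canonical form
used for deduplication, and all objective values are invariant under
relabeling (tested).

## Search procedure

Each generation evolves six populations in turn:

1. **Dominant population D** — nondominated members of the combined
   population, truncated to at most `SD` by descending NSGA-II crowding
   distance (boundary solutions +∞; interior solutions sum normalized
   neighbour gaps per objective; zero objective ranges contribute zero;
   ties keep original order via stable sort).
2. **Active population AP** — the first `SA` of D by descending crowding
   distance (all of D when it is small enough); the untruncated D is kept
   as the elitism archive.
3. **Clone population CL** — each active member copied `q_i ≥ 1` times,
   `Σ q_i = SC`, proportional to its crowding-distance share.  The source
   immune algorithm does not print its quota formula; here infinite
   (boundary) distances are capped at twice the largest finite distance
   (1 if none), and quotas are rounded by largest remainder — bounded,
   deterministic, and preserving "more clones to less crowded".
4. **Evolutionary offspring EO** — each clone crosses with an active
   member drawn uniformly with replacement.  One-way crossover picks a
   source parent by fair coin and a uniform node v, and transplants v's
   entire source community into the destination copy; labels therefore
   never leave the union of the parents' labels.  Neighbor-restricted
   mutation then rewrites each node's label, with probability `p_m`, by a
   uniformly chosen neighbour's pre-pass label (synchronous read,
   sequential write, so node order is irrelevant).
5. **Local search offspring LO** — see below; applied to D and to the
   nondominated members of EO.
6. **Combination** — the next population is LO¹ ∪ LO² ∪ D.  Retaining the
   unrefined D is a deliberate choice: refining the incumbent best-Q
   solution along a non-central weight direction can lower its Q, and with
   a refined-only union the incumbent is occasionally lost (observed on
   the karate network).  Since a dominating point always has at least the
   dominated point's Q, dominance filtering over a set containing D can
   never lower the best Q, restoring the elitism guarantee the external
   dominant population exists for.  Duplicates collapse at the next
   generation's nondominated filter, and the final archive is the
   deduplicated nondominated set after `Gmax` generations.

## Local search

Each nondominated individual is refined under its own scalarized fitness
`S(X) = ω₁·IntraQ + ω₂·InterQ = Σ_C S(C) + ω₂` with
`S(C) = ω₁·l_C/m − ω₂·(k_C/2m)²`.  The weight vector is the pseudonormal
vector: with the front sorted ascending by IntraQ (equivalently descending
by InterQ — the reversed-order property of a 2-d nondominated front,
asserted before use), an interior member's two sort neighbours define a
secant, and

```
ω = ( (f₂(X¹)−f₂(X²))/π , (f₁(X²)−f₁(X¹))/π ),   π = both numerators summed
```

is the unit-sum normal to it.  The max-IntraQ boundary searches with
(1, 0), the max-InterQ boundary with (0, 1); a singleton front falls back
to (½, ½).  Objective-coincident duplicates are collapsed before the front
is built (a duplicate pair would give π = 0); any residual degenerate
neighbour pair also falls back to (½, ½).

Refinement is label propagation: sweeps visit all nodes in a fresh random
permutation, moving each node to the adjacent community (its own included)
with maximal increment

```
ΔS_i = (1/m) Σ_{j≠i} (ω₁·A_ij − ω₂·k_i·k_j/2m) · δ(x_j, c)
     = (1/m) [ ω₁·e(i,c) − ω₂·k_i·K_c/2m ]
```

where `e(i,c)` counts i's edges into the candidate community and `K_c` its
total degree excluding i.  The increment equals the from-scratch fitness
difference of isolating v and re-inserting it (oracle-tested to 1e−10).
Ties that include the current label keep the current label — this
guarantees per-update monotonicity of S and sweep termination — and other
exact ties break uniformly at random.  Sweeps stop when none changes a
label or after `MI` sweeps.  With ω = (½, ½), `S = (Q+1)/2`, so the
procedure is exactly LPAm and its fixed points are single-node-move
Q-optimal.  Community degree totals are maintained incrementally, making a
sweep O(m).

## Parameters

| name    | meaning                          | default | notes |
|---------|----------------------------------|---------|-------|
| `gmax`  | generations                      | 10      | benchmark-scale setting; small real networks converge in a few generations |
| `sd`    | max dominant population          | 100     | 100–110 used for 128-node benchmarks |
| `sa`    | max active population            | `sd/5`  | |
| `sc`    | clone population size            | `sd`    | |
| `p_m`   | mutation probability per node    | 0.01    | |
| `mi`    | local-search sweep cap           | 1       | recovery is insensitive to `mi`; pure label propagation (`mode="lsa"`) uses ~10 |
| `alpha` | init label-spread fraction       | 0.3     | ⌊α·n⌋ random nodes flood their label over their neighbours, sequentially |
| `mode`  | `mmcd` / `moa` / `lsa`           | mmcd    | `moa`: no local search; `lsa`: local search only, ω=(½,½), from singletons |

`seed` feeds a single numpy Generator threaded through every stochastic
operator; runs are bit-for-bit reproducible.

## Synthetic benchmarks

`generate_gn` plants four 32-node communities in a 128-node graph, joining
pairs independently with `p_in = 16(1−μ)/31` and `p_out = 16μ/96` so the
expected intra/inter degrees are 16(1−μ) and 16μ (expected degree 16
overall).  `generate_hier_gn` plants 16 communities of 16 nodes nested
four-per-supercommunity in a 256-node graph with expected per-node edge
counts (10, 5, 2) to its own community, its sibling communities, and the
rest.  Both are expectation-only Bernoulli (stochastic block model)
constructions — node degrees fluctuate binomially around their
expectations.  Calibration (mean degree, intra-community degree) is tested
within three standard errors over 20 replicates.

What this does not emulate: degree-conditioned instances (each node with
exactly 16 edges), heterogeneous degree or community-size distributions
(consume externally generated LFR files via `load_lfr` for that), weights,
directions, overlap.  Consequences for interpretation: at mixing μ ≥ 0.3,
a few nodes in a Bernoulli draw end up with a majority of external edges,
and the planted partition then is *not* the modularity optimum of the
realized graph.  In those instances the search returns partitions with
Q at or above the planted partition's Q while exact-recovery NMI falls
short of 1 (an independent Louvain implementation misclassifies the same
instances).  Exact-recovery statements at higher mixing are therefore
statements about the generator as much as about the search.

## Numerical choices and degenerate inputs

* Internal node ids are 0-based contiguous; an id-map restores original
  labels on output.  Self-loops are rejected (the objectives assume a
  simple graph); weighted input is rejected unless explicitly coerced to
  unit weights; isolated nodes are allowed but warned about — every ΔS
  term for them is empty and their label never changes.
* Objectives are undefined on edgeless graphs (m = 0) and raise.
* NMI uses natural logarithms with 0·ln 0 = 0; when both partitions are
  trivial single communities the degenerate 0/0 resolves to 1, and any
  nontrivial partition scores 0 against a single community.
* Float ties in the label-update argmax are compared exactly; the
  symmetric cases that produce ties yield identical arithmetic.
* Crowding-distance normalization spans the population being ranked.

## Problem sizes in the test suite

Unit and property tests use graphs of 3–30 nodes with brute-force oracles
(pairwise dominance, exhaustive enumeration of all 203 partitions of a
6-node graph, from-scratch fitness recomputation).  End-to-end checks use
the bundled 34-node karate network (10 runs), 128-node planted benchmarks
(10 runs per mixing value) and one 256-node nested benchmark run — sizes
chosen so the full suite completes in about a minute while still exercising
the algorithm at the scale the benchmark family defines.  Full LFR sweeps
and large real-network corpora are out of scope for the suite; the CLI
(`bench`, `run`, `eval`) scripts such experiments.

## Known limitations

* The archive's attainable envelope (best IntraQ per community count) is
  monotone in community count only as a strong tendency (rank correlation
  ≈ −0.99); isolated adjacent-pair inversions occur when the archive lacks
  a good partition at some count.
* No weighted/directed/overlapping variants; modularity's resolution limit
  is inherited within each fixed weight direction, though the multi-
  resolution archive mitigates it in aggregate.
* Proportional-cloning quotas follow this package's declared allocation
  (capped distances, largest remainder); other immune-algorithm
  implementations may allocate differently.
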