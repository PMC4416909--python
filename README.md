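# mmcd — multi-objective memetic community detection

`mmcd` detects community structure in undirected, unweighted networks by
treating the two complementary terms of Newman–Girvan modularity as
conflicting objectives and returning, from a single run, a **Pareto archive
of partitions at multiple resolutions** — rather than the one partition a
single-objective method commits to.  It is aimed at network analysts
(systems biology, social networks, infrastructure) who want to inspect a
network's community structure across scales, including nested hierarchical
structure.

## The model

For a graph with `m` edges, a partition `X` with communities `C` scores

```
Q      = Σ_C [ l_C/m − (k_C/2m)² ]          (modularity)
IntraQ = Σ_C l_C/m                    ∈ [0, 1]
InterQ = 1 − Σ_C (k_C/2m)²            ∈ [0, 1)
```

where `l_C` is the number of edges inside `C` and `k_C` the total degree of
its members, so `Q = IntraQ + InterQ − 1` exactly.  `IntraQ` favours few
large communities, `InterQ` many small ones; maximizing both
simultaneously — `max F(X) = (IntraQ, InterQ)` — spreads solutions across
resolution scales.

The search is a memetic (hybrid) algorithm:

* **Global layer** — an immune-inspired multi-objective evolutionary loop
  (NNIA-style): nondominated filtering with NSGA-II crowding distance,
  proportional cloning of the least crowded solutions, one-way crossover
  for the group-based label encoding, and neighbor-restricted mutation.
* **Local layer** — each nondominated solution is refined by
  label-propagation local search under its own scalarized fitness
  `S(X) = ω₁·IntraQ + ω₂·InterQ`.  The weight vector is the
  **pseudonormal vector**: the unit-sum normal to the secant through the
  solution's two nearest front neighbours, approximating the front's
  normal direction; boundary solutions push straight along one axis.
  A node moves to the adjacent community with maximal closed-form gain
  `ΔS_i = (1/m)[ω₁·e(i,C) − ω₂·k_i·K_C/2m]`.  With ω = (½, ½) this is
  exactly the modularity-specialized label propagation algorithm (LPAm).

Partition similarity is scored with normalized mutual information (Danon
confusion-matrix form); planted-partition generators (the 128-node
four-community benchmark and its 256-node two-level nested extension)
provide ground-truthed test instances.

## Worked example

```python
import mmcd

g, factions = mmcd.karate_club()                 # bundled 34-node network
archive = mmcd.run_mmcd(g, mmcd.MMCDConfig(sd=100, gmax=10, seed=1))
best, = mmcd.model_select(archive, "modularity")
print(f"archive size: {len(archive)}")
print(f"best Q: {best.objectives.q:.4f}  communities: {best.decode().k}")
print(f"true-split Q: {mmcd.modularity(g, factions):.4f}")
```

prints

```
archive size: 60
best Q: 0.4198  communities: 4
true-split Q: 0.3715
```

The archive holds the full resolution sweep in one run: the maximum-
modularity partition (Q = 0.4198, four communities), a three-community
solution with Q = 0.4020, and a two-community solution (Q = 0.3718) nearly
identical to the club's real two-faction split (Q = 0.3715) — the partition
a pure modularity maximizer would never report.
`archive.to_dataframe(truth=factions)` tabulates IntraQ, InterQ, Q,
community count and NMI per solution.

The same workflow is available from the shell:

```sh
mmcd run karate.edges --truth factions.txt --sd 100 --gmax 10 --seed 1 --out out/
mmcd bench gn --mu 0.0:0.6:0.05 --reps 10 --seed 3 --out benchmarks/
mmcd eval graph.edges partition.txt --truth truth.txt
```

`run` writes a per-solution front table (CSV), the selected partition files
and a run log.  `--mode moa` drops the local search (ablation), `--mode
lsa` runs the label-propagation search alone (LPAm).

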