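"""Generational loop, configuration, model selection and result export.

One generation evolves six populations in turn: the nondominated members of
the combined population form the dominant population D (crowding-truncated
to SD); its least crowded members form the active population AP (size SA);
AP is proportionally cloned to CL (size SC); one-way crossover with random
active partners plus neighbor mutation turns CL into the evolutionary
offspring EO; the label-propagation local search refines D and EO into LO1
and LO2, whose union seeds the next generation.  Carrying the refined
dominant population forward provides elitism.

Ablation modes: ``moa`` drops the local search entirely (next generation is
EO union D); ``lsa`` drops the evolutionary layer and runs the local search
alone from the all-singleton start with equal weights, which is exactly the
modularity-specialized label propagation algorithm (LPAm).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import evolution, local_search
from .encoding import Individual, PartitionView, init_population
from .graph_core import Graph, write_partition
from .objectives import evaluate, nmi

__all__ = ["MMCDConfig", "GenerationStats", "ParetoArchive", "run_mmcd", "model_select", "export_results"]

MODES = ("mmcd", "moa", "lsa")
SELECT_CRITERIA = ("modularity", "nmi", "all")


@dataclass
class MMCDConfig:
    """Run parameters.

    Defaults follow the experimental settings for benchmark-scale networks:
    dominant population SD = 100 with SA = SD/5 and SC = SD, mutation
    probability 0.01, one local-search sweep per call (MI = 1), initial
    spread fraction alpha = 0.3, ten generations.
    """

    gmax: int = 10
    sd: int = 100
    sa: Optional[int] = None
    sc: Optional[int] = None
    p_m: float = 0.01
    mi: int = 1
    alpha: float = 0.3
    seed: Optional[int] = None
    mode: str = "mmcd"
    select: str = "modularity"

    def __post_init__(self) -> None:
        if self.sa is None:
            self.sa = max(1, self.sd // 5)
        if self.sc is None:
            self.sc = self.sd
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.select not in SELECT_CRITERIA:
            raise ValueError(f"select must be one of {SELECT_CRITERIA}")
        if not (1 <= self.sa <= self.sd):
            raise ValueError("need 1 <= SA <= SD")
        if self.sc < self.sa:
            raise ValueError("need SC >= SA")
        if not 0.0 <= self.p_m <= 1.0:
            raise ValueError("mutation probability must lie in [0, 1]")
        if self.gmax < 1 or self.mi < 1 or self.sd < 1:
            raise ValueError("Gmax, MI and SD must be >= 1")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


@dataclass
class GenerationStats:
    generation: int
    front_size: int
    best_q: float


@dataclass
class ParetoArchive:
    """Deduplicated nondominated partitions of a finished run."""

    members: list[Individual]
    history: list[GenerationStats] = field(default_factory=list)
    config: Optional[MMCDConfig] = None

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def best_q(self) -> float:
        return max(ind.objectives.q for ind in self.members)

    def to_dataframe(self, graph: Graph | None = None, truth: PartitionView | None = None) -> pd.DataFrame:
        rows = []
        for i, ind in enumerate(self.members):
            pt = ind.objectives
            row = {
                "solution": i,
                "intra_q": pt.intra,
                "inter_q": pt.inter,
                "q": pt.q,
                "communities": ind.decode().k,
            }
            if truth is not None:
                row["nmi"] = nmi(ind, truth)
            rows.append(row)
        return pd.DataFrame(rows).sort_values("communities").reset_index(drop=True)


def _evaluate_all(g: Graph, pop: Sequence[Individual]) -> None:
    for ind in pop:
        evaluate(g, ind)


def _dedup_canonical(pop: Sequence[Individual]) -> list[Individual]:
    seen: set[bytes] = set()
    out = []
    for ind in pop:
        key = ind.canonical_key()
        if key not in seen:
            seen.add(key)
            out.append(ind)
    return out


def run_mmcd(g: Graph, cfg: MMCDConfig) -> ParetoArchive:
    """Run the configured search and return the final Pareto archive."""
    if g.m == 0:
        raise ValueError("cannot partition an edgeless graph")
    rng = np.random.default_rng(cfg.seed)

    if cfg.mode == "lsa":
        ind = local_search.local_search_individual(
            g, Individual(np.arange(g.n)), local_search.WeightVector(0.5, 0.5), cfg.mi, rng
        )
        evaluate(g, ind)
        return ParetoArchive(members=[ind], history=[], config=cfg)

    population = init_population(g, cfg.sd, cfg.alpha, rng)
    _evaluate_all(g, population)
    history: list[GenerationStats] = []
    for gen in range(cfg.gmax):
        dominant = evolution.truncate_dominant(evolution.nondominated_filter(population), cfg.sd)
        active = evolution.select_active(dominant, cfg.sa)
        clones = evolution.proportional_clone(active, cfg.sc)
        offspring = []
        for clone in clones:
            partner = active[int(rng.integers(len(active)))]
            child = evolution.one_way_crossover(clone, partner, rng)
            child = evolution.neighbor_mutation(child, g, cfg.p_m, rng)
            offspring.append(child)
        _evaluate_all(g, offspring)
        if cfg.mode == "mmcd":
            refined_dominant = local_search.local_search_population(dominant, g, cfg.mi, rng)
            refined_offspring = local_search.local_search_population(offspring, g, cfg.mi, rng)
            # the unrefined dominant population is retained for elitism: a
            # refinement step along a non-central weight direction may lower
            # Q, and dominance filtering alone can then lose the incumbent
            population = refined_dominant + refined_offspring + dominant
        else:  # moa: no local search
            population = offspring + dominant
        _evaluate_all(g, population)
        history.append(
            GenerationStats(
                generation=gen + 1,
                front_size=len(dominant),
                best_q=max(ind.objectives.q for ind in population),
            )
        )
    final = _dedup_canonical(evolution.nondominated_filter(population))
    return ParetoArchive(members=final, history=history, config=cfg)


def model_select(
    archive: ParetoArchive,
    criterion: str = "modularity",
    truth: PartitionView | None = None,
) -> list[Individual]:
    """Pick archive member(s) by criterion; ties return all tied members."""
    if criterion not in SELECT_CRITERIA:
        raise ValueError(f"criterion must be one of {SELECT_CRITERIA}")
    members = list(archive.members)
    if criterion == "all":
        return sorted(members, key=lambda ind: ind.decode().k)
    if criterion == "modularity":
        scores = [ind.objectives.q for ind in members]
    else:
        if truth is None:
            raise ValueError("NMI-based selection requires a ground-truth partition")
        scores = [nmi(ind, truth) for ind in members]
    best = max(scores)
    return [ind for ind, s in zip(members, scores) if s == best]


def export_results(
    archive: ParetoArchive,
    selections: Sequence[Individual],
    out_dir,
    graph: Graph,
    truth: PartitionView | None = None,
) -> dict[str, Path]:
    """Write the front table (CSV), selected partitions and a run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    front_path = out / "front.csv"
    archive.to_dataframe(graph, truth).to_csv(front_path, index=False)
    paths["front"] = front_path

    for i, ind in enumerate(selections):
        p = out / f"partition_{i}.txt"
        write_partition(ind.decode(), graph, p)
        paths[f"partition_{i}"] = p

    log_path = out / "run.log"
    with open(log_path, "w") as fh:
        if archive.config is not None:
            fh.write("config: " + str(dataclasses.asdict(archive.config)) + "\n")
        fh.write(f"archive size: {len(archive)}\n")
        for st in archive.history:
            fh.write(
                f"generation {st.generation}: front size {st.front_size}, best Q {st.best_q:.6f}\n"
            )
    paths["log"] = log_path
    return paths
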