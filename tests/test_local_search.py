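import itertools

import numpy as np
import pytest

from mmcd import (
    Individual,
    ObjectivePoint,
    PartitionView,
    WeightVector,
    delta_fitness,
    local_search_individual,
    local_search_population,
    modularity,
    pseudonormal_vector,
    scalarized_fitness,
    update_node_label,
)

from conftest import random_graph

HALF = WeightVector(0.5, 0.5)
FRONT3 = [ObjectivePoint(0.2, 0.8), ObjectivePoint(0.5, 0.5), ObjectivePoint(0.8, 0.2)]


def set_partitions(n):
    """All partitions of {0..n-1} as label vectors (restricted growth strings)."""
    def rec(prefix, k):
        i = len(prefix)
        if i == n:
            yield list(prefix)
            return
        for lab in range(k + 1):
            yield from rec(prefix + [lab], max(k, lab + 1))

    yield from rec([], 0)


class TestPseudonormalVector:
    def test_interior_point(self):
        w = pseudonormal_vector(FRONT3, 1)
        assert w == pytest.approx((0.5, 0.5))

    def test_boundaries_align_with_axes(self):
        assert pseudonormal_vector(FRONT3, 2) == (1.0, 0.0)  # max IntraQ
        assert pseudonormal_vector(FRONT3, 0) == (0.0, 1.0)  # max InterQ

    def test_singleton_front_fallback(self):
        assert pseudonormal_vector([ObjectivePoint(0.4, 0.6)], 0) == (0.5, 0.5)

    def test_asymmetric_secant(self):
        front = [ObjectivePoint(0.1, 0.9), ObjectivePoint(0.2, 0.6), ObjectivePoint(0.5, 0.5)]
        w = pseudonormal_vector(front, 1)
        # secant from (0.1,0.9) to (0.5,0.5): df1=0.4, df2=0.4 -> (0.5,0.5)
        assert w == pytest.approx((0.5, 0.5))
        assert w.w1 + w.w2 == pytest.approx(1.0, abs=1e-12)

    def test_dominated_front_rejected(self):
        bad = [ObjectivePoint(0.2, 0.2), ObjectivePoint(0.5, 0.5)]
        with pytest.raises(ValueError, match="reversed-order"):
            pseudonormal_vector(bad, 0)

    def test_weights_nonnegative_and_normalized(self, rng):
        f1 = np.sort(rng.random(8))
        f2 = np.sort(rng.random(8))[::-1]
        front = [ObjectivePoint(a, b) for a, b in zip(f1, f2)]
        for i in range(8):
            w = pseudonormal_vector(front, i).validate()
            assert w.w1 >= 0 and w.w2 >= 0


class TestScalarizedFitness:
    def test_equal_weights_reduce_to_modularity(self, barbell, rng):
        for _ in range(10):
            p = Individual(rng.integers(0, 6, size=6))
            s = scalarized_fitness(barbell, p, HALF)
            assert s == pytest.approx((modularity(barbell, p) + 1) / 2, abs=1e-12)

    def test_barbell_two_triangle_value(self, barbell):
        p = PartitionView([0, 0, 0, 1, 1, 1])
        assert scalarized_fitness(barbell, p, HALF) == pytest.approx((6 / 7 - 0.5 + 1) / 2)

    def test_pure_intra_weight_on_single_community(self, barbell):
        p = PartitionView([0] * 6)
        assert scalarized_fitness(barbell, p, WeightVector(1.0, 0.0)) == pytest.approx(1.0)


class TestDeltaFitness:
    def test_barbell_hand_values(self, barbell):
        ind = Individual([1, 1, 1, 2, 2, 2])
        # node 3 (index 2): staying home gains 4/49, defecting loses 1/28
        assert delta_fitness(barbell, ind, 2, ind.labels[2], HALF) == pytest.approx(4 / 49)
        assert delta_fitness(barbell, ind, 2, ind.labels[3], HALF) == pytest.approx(-1 / 28)

    def test_non_adjacent_target_rejected(self, barbell):
        ind = Individual([1, 1, 1, 2, 2, 3])
        with pytest.raises(ValueError, match="not adjacent"):
            delta_fitness(barbell, ind, 0, 3, HALF)  # node 1 has no edge into {6}

    def test_no_edges_into_target_with_pure_intra_weight(self, barbell):
        ind = Individual([1, 1, 1, 2, 2, 2])
        d = delta_fitness(barbell, ind, 2, ind.labels[3], WeightVector(1.0, 0.0))
        assert d <= 1 / 7 + 1e-12  # only the single bridge edge can contribute

    def test_increment_matches_from_scratch_difference(self, rng):
        # moving v out of isolation into an adjacent community must change the
        # scalarized fitness by exactly the closed-form increment
        for _ in range(100):
            g = random_graph(rng, int(rng.integers(4, 30)))
            labels = rng.integers(0, max(2, g.n // 2), size=g.n)
            v = int(rng.integers(g.n))
            if not g.neighbors[v]:
                continue
            target = int(labels[g.neighbors[v][int(rng.integers(len(g.neighbors[v])))]])
            w1 = rng.random()
            w = WeightVector(w1, 1.0 - w1)
            isolated = labels.copy()
            isolated[v] = g.n  # fresh singleton community
            moved = labels.copy()
            moved[v] = target
            expected = scalarized_fitness(g, Individual(moved), w) - scalarized_fitness(
                g, Individual(isolated), w
            )
            got = delta_fitness(g, Individual(labels), v, target, w)
            assert abs(got - expected) < 1e-10


class TestUpdateNodeLabel:
    def test_keeps_winning_home_community(self, barbell, rng):
        ind = Individual([1, 1, 1, 2, 2, 2])
        out, changed = update_node_label(barbell, ind, 2, HALF, rng)
        assert not changed and out.labels.tolist() == ind.labels.tolist()

    def test_moves_to_better_community(self, barbell, rng):
        ind = Individual([1, 1, 1, 1, 2, 2])
        out, changed = update_node_label(barbell, ind, 3, HALF, rng)
        assert changed and out.labels[3] == 2

    def test_isolated_node_unchanged(self, rng):
        from mmcd import Graph

        g = Graph(np.array([[0, 1], [0, 2], [1, 2]]), n=4)
        ind = Individual([0, 0, 0, 3])
        out, changed = update_node_label(g, ind, 3, HALF, rng)
        assert not changed and out.labels[3] == 3

    def test_single_update_never_decreases_fitness(self, rng):
        for _ in range(30):
            g = random_graph(rng, 12)
            ind = Individual(rng.integers(0, 6, size=12))
            w1 = rng.random()
            w = WeightVector(w1, 1.0 - w1)
            before = scalarized_fitness(g, ind, w)
            out, _ = update_node_label(g, ind, int(rng.integers(12)), w, rng)
            assert scalarized_fitness(g, out, w) >= before - 1e-12


class TestLocalSearchIndividual:
    def test_local_optimum_is_fixed_point(self, barbell, rng):
        ind = Individual([0, 0, 0, 1, 1, 1])
        out = local_search_individual(barbell, ind, HALF, 5, rng)
        assert out.canonical_key() == ind.canonical_key()

    def test_reaches_exhaustive_q_optimum_from_singletons(self, barbell):
        best_q, best = max(
            ((modularity(barbell, PartitionView(p)), p) for p in set_partitions(6)),
            key=lambda t: t[0],
        )
        assert best_q == pytest.approx(6 / 7 - 0.5)
        for seed in range(10):  # every sweep order reaches the optimum
            out = local_search_individual(
                barbell, Individual(range(6)), HALF, 10, np.random.default_rng(seed)
            )
            assert out.decode() == PartitionView(best)

    def test_equal_weights_yield_single_move_q_optimality(self, rng):
        # LPAm fixed points: no single-node move can increase modularity
        for _ in range(5):
            g = random_graph(rng, 15)
            out = local_search_individual(g, Individual(range(15)), HALF, 50, rng)
            for v in range(g.n):
                for lab in {int(out.labels[u]) for u in g.neighbors[v]}:
                    assert delta_fitness(g, out, v, lab, HALF) <= delta_fitness(
                        g, out, v, int(out.labels[v]), HALF
                    ) + 1e-12

    def test_fitness_monotone_across_sweeps(self, rng):
        for _ in range(10):
            g = random_graph(rng, 20)
            w1 = rng.random()
            w = WeightVector(w1, 1.0 - w1)
            ind = Individual(rng.integers(0, 10, size=20))
            before = scalarized_fitness(g, ind, w)
            out = local_search_individual(g, ind, w, 3, rng)
            assert scalarized_fitness(g, out, w) >= before - 1e-12


class TestLocalSearchPopulation:
    def _evaluated(self, g, label_sets):
        from mmcd import evaluate

        pop = [Individual(ls) for ls in label_sets]
        for ind in pop:
            evaluate(g, ind)
        return pop

    def test_population_of_one_uses_fallback_weights(self, barbell, rng):
        pop = self._evaluated(barbell, [range(6)])
        out = local_search_population(pop, barbell, 10, rng)
        assert len(out) == 1
        assert out[0].decode() == PartitionView([0, 0, 0, 1, 1, 1])

    def test_duplicates_refined_once_and_restored(self, barbell, rng):
        pop = self._evaluated(barbell, [[0, 0, 0, 1, 1, 1]] * 3)
        out = local_search_population(pop, barbell, 5, rng)
        assert len(out) == 3
        keys = {ind.canonical_key() for ind in out}
        assert len(keys) == 1

    def test_dominated_members_are_discarded(self, barbell, rng):
        # the lopsided 4+2 split is dominated by the two-triangle partition
        pop = self._evaluated(barbell, [[0, 0, 0, 1, 1, 1], [0, 0, 0, 0, 1, 1]])
        out = local_search_population(pop, barbell, 5, rng)
        assert len(out) == 1
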