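"""Genome encoding, mutation operators, crossover and the compatibility distance."""

import json

import numpy as np
import pytest

from swimneat.genome import (
    CompatibilityCoefficients,
    ConnectionGene,
    Genome,
    InnovationRegistry,
    NodeGene,
    NodeType,
    compatibility_distance,
    crossover,
    minimal_genome,
    mutate_add_connection,
    mutate_add_node,
    mutate_weights,
)

from conftest import make_random_genome


def build_genome(innovation_weights: dict[int, float],
                 pair_of: dict[int, tuple[int, int]] | None = None) -> Genome:
    """Hand-built genome over shared node ids 0,1 (inputs), 2 (bias), 3 (out)."""
    g = Genome()
    for nid, nt in ((0, NodeType.INPUT), (1, NodeType.INPUT),
                    (2, NodeType.BIAS), (3, NodeType.OUTPUT)):
        g.nodes[nid] = NodeGene(nid, nt)
    default_pairs = {1: (0, 3), 2: (1, 3), 3: (2, 3), 4: (0, 3), 5: (1, 3)}
    pair_of = pair_of or default_pairs
    for innov, w in innovation_weights.items():
        a, b = pair_of[innov]
        # hand genomes may reuse pairs across innovations; disable duplicates
        enabled = (a, b) not in [(c.in_node, c.out_node)
                                 for c in g.connections.values() if c.enabled]
        g.connections[innov] = ConnectionGene(a, b, w, enabled, innov)
    return g


class TestMinimalGenome:
    @pytest.mark.parametrize("n_in,n_out,n_nodes,n_conns",
                             [(2, 1, 4, 3), (1, 1, 3, 2), (3, 2, 6, 8)])
    def test_structure(self, registry, rng, n_in, n_out, n_nodes, n_conns):
        g = minimal_genome(n_in, n_out, registry, rng)
        assert len(g.nodes) == n_nodes
        assert len(g.connections) == n_conns
        g.validate()

    def test_shared_registry_aligns_innovations(self, registry, rng):
        a = minimal_genome(2, 1, registry, rng)
        b = minimal_genome(2, 1, registry, rng)
        assert set(a.connections) == set(b.connections)
        for innov in a.connections:
            ca, cb = a.connections[innov], b.connections[innov]
            assert (ca.in_node, ca.out_node) == (cb.in_node, cb.out_node)

    def test_invalid_counts_rejected(self, registry, rng):
        with pytest.raises(ValueError):
            minimal_genome(0, 1, registry, rng)
        with pytest.raises(ValueError):
            minimal_genome(2, 0, registry, rng)


class TestAddConnection:
    def test_saturated_genome_unchanged(self, registry, rng):
        g = minimal_genome(2, 1, registry, rng)
        before = set(g.connections)
        mutate_add_connection(g, registry, rng)
        assert set(g.connections) == before

    def test_adds_one_after_node_split(self, registry, rng):
        g = minimal_genome(2, 1, registry, rng)
        mutate_add_node(g, registry, rng)
        n = len(g.connections)
        mutate_add_connection(g, registry, rng)
        assert len(g.connections) == n + 1
        g.validate()

    def test_same_pair_same_generation_same_innovation(self, registry, rng):
        g1 = minimal_genome(1, 1, registry, rng)
        g2 = minimal_genome(1, 1, registry, rng)
        # split the same connection in both so an unlinked pair exists
        for g in (g1, g2):
            conn = g.enabled_connections()[0]
            conn_innov = conn.innovation
            node_id, _, _ = registry.split_connection(
                conn_innov, conn.in_node, conn.out_node)
        mutate_add_node(g1, registry, rng)  # deterministic: one candidate each
        mutate_add_node(g2, registry, rng)
        mutate_add_connection(g1, registry, rng)
        mutate_add_connection(g2, registry, rng)
        for innov in set(g1.connections) & set(g2.connections):
            c1, c2 = g1.connections[innov], g2.connections[innov]
            assert (c1.in_node, c1.out_node) == (c2.in_node, c2.out_node)


class TestAddNode:
    def test_split_counts_and_weight_convention(self, registry, rng):
        g = minimal_genome(1, 1, registry, rng)
        # keep exactly one enabled connection so the split target is forced
        conns = list(g.connections.values())
        conns[1].enabled = False
        old = conns[0]
        w = old.weight
        n_nodes, n_conns = len(g.nodes), len(g.connections)
        mutate_add_node(g, registry, rng)
        assert len(g.nodes) == n_nodes + 1
        assert len(g.connections) == n_conns + 2
        assert not old.enabled
        new_in = [c for c in g.enabled_connections() if c.in_node == old.in_node
                  and c.out_node not in (old.out_node,)]
        new_out = [c for c in g.enabled_connections() if c.out_node == old.out_node
                   and c.in_node not in (old.in_node,)]
        assert len(new_in) == 1 and new_in[0].weight == 1.0
        assert len(new_out) == 1 and new_out[0].weight == w

    def test_double_split(self, registry, rng):
        g = minimal_genome(2, 1, registry, rng)
        mutate_add_node(g, registry, rng)
        registry.reset()
        mutate_add_node(g, registry, rng)
        assert len(g.nodes) == 6
        assert sum(1 for c in g.connections.values() if not c.enabled) == 2
        # arity is conserved
        assert g.n_inputs == 2 and g.n_outputs == 1


class TestMutateWeights:
    def test_zero_sigma_zero_reset_is_identity(self, registry, rng):
        g = minimal_genome(2, 1, registry, rng)
        before = [c.weight for c in g.connections.values()]
        mutate_weights(g, 1.0, 0.0, 0.0, rng)
        assert [c.weight for c in g.connections.values()] == before

    def test_seeded_reproducibility(self, registry):
        results = []
        for _ in range(2):
            g = minimal_genome(2, 1, InnovationRegistry(),
                               np.random.default_rng(7))
            mutate_weights(g, 1.0, 0.5, 0.1, np.random.default_rng(99))
            results.append([c.weight for c in g.connections.values()])
        assert results[0] == results[1]

    def test_clamp_holds_under_repeated_mutation(self, registry, rng):
        g = minimal_genome(2, 2, registry, rng)
        for _ in range(1000):
            mutate_weights(g, 1.0, 2.0, 0.05, rng)
            assert all(abs(c.weight) <= 8.0 for c in g.connections.values())


class TestCrossover:
    def test_self_cross_preserves_structure(self, registry, rng):
        g = make_random_genome(registry, rng)
        g.raw_fitness = 1.0
        child = crossover(g, g, rng)
        assert set(child.connections) == set(g.connections)
        assert set(child.nodes) == set(g.nodes)
        for innov, c in child.connections.items():
            o = g.connections[innov]
            assert (c.in_node, c.out_node, c.weight, c.enabled) == \
                (o.in_node, o.out_node, o.weight, o.enabled)

    def test_fitter_parent_contributes_nonmatching(self, rng):
        a = build_genome({1: 0.1, 2: 0.2, 3: 0.3})
        b = build_genome({1: 0.1, 2: 0.2, 4: 0.4, 5: 0.5})
        a.raw_fitness, b.raw_fitness = 2.0, 1.0
        child = crossover(a, b, rng)
        assert set(child.connections) == {1, 2, 3}

    def test_matching_weights_inherited_never_blended(self, rng):
        a = build_genome({1: 0.1, 2: 0.2})
        b = build_genome({1: 0.9, 2: 0.7})
        a.raw_fitness, b.raw_fitness = 2.0, 1.0
        for _ in range(20):
            child = crossover(a, b, rng)
            assert child.connections[1].weight in (0.1, 0.9)
            assert child.connections[2].weight in (0.2, 0.7)

    def test_unset_fitness_rejected(self, rng):
        a = build_genome({1: 0.1})
        b = build_genome({1: 0.2})
        with pytest.raises(ValueError):
            crossover(a, b, rng)

    def test_child_innovation_set_rule_on_random_pairs(self, random_population, rng):
        for i in range(0, len(random_population) - 1, 2):
            a, b = random_population[i], random_population[i + 1]
            a.raw_fitness, b.raw_fitness = 2.0, 1.0
            child = crossover(a, b, rng, feed_forward=True)
            matching = set(a.connections) & set(b.connections)
            expected = matching | (set(a.connections) - set(b.connections))
            # feed-forward guard may drop genes that would close a cycle
            assert set(child.connections) <= expected
            assert matching <= set(child.connections)


class TestCompatibilityDistance:
    def test_identical_genomes_distance_zero(self, registry, rng):
        g = make_random_genome(registry, rng)
        assert compatibility_distance(g, g) == 0.0

    def test_hand_enumerated_alignment(self):
        # A {1,2,3} vs B {1,2,4,5}: E=2 (4,5 beyond A's max 3), D=1 (A's 3),
        # matched weights equal so Wbar=0; with c1=c2=1, c3=0.4, N=1: delta=3
        a = build_genome({1: 0.5, 2: 0.5, 3: 0.5})
        b = build_genome({1: 0.5, 2: 0.5, 4: 0.5, 5: 0.5})
        coeff = CompatibilityCoefficients(1.0, 1.0, 0.4)
        assert compatibility_distance(a, b, coeff) == pytest.approx(3.0)

    def test_weight_difference_only(self):
        a = build_genome({1: 0.5})
        b = build_genome({1: 1.0})
        coeff = CompatibilityCoefficients(1.0, 1.0, 0.4)
        assert compatibility_distance(a, b, coeff) == pytest.approx(0.2)

    def test_agrees_with_bruteforce_oracle_on_population(self, random_population):
        """Independent gene-by-gene alignment over all pairs of 20 genomes."""
        coeff = CompatibilityCoefficients(1.0, 1.0, 0.4, N_threshold=20)

        def oracle(a, b):
            ia, ib = set(a.connections), set(b.connections)
            if not ia and not ib:
                return 0.0
            max_a = max(ia) if ia else -1
            max_b = max(ib) if ib else -1
            match, disjoint, excess, diffs = 0, 0, 0, []
            for innov in ia | ib:
                if innov in ia and innov in ib:
                    diffs.append(abs(a.connections[innov].weight
                                     - b.connections[innov].weight))
                elif innov in ia:
                    if innov > max_b:
                        excess += 1
                    else:
                        disjoint += 1
                else:
                    if innov > max_a:
                        excess += 1
                    else:
                        disjoint += 1
            n = max(len(ia), len(ib))
            n = 1 if n < coeff.N_threshold else n
            wbar = sum(diffs) / len(diffs) if diffs else 0.0
            return coeff.c1 * excess / n + coeff.c2 * disjoint / n + coeff.c3 * wbar

        pop = random_population
        for i in range(len(pop)):
            for j in range(i, len(pop)):
                d = compatibility_distance(pop[i], pop[j], coeff)
                assert d == pytest.approx(oracle(pop[i], pop[j]), abs=1e-12)
                assert d == pytest.approx(
                    compatibility_distance(pop[j], pop[i], coeff), abs=1e-12)
                assert d >= 0

    def test_innovation_consistency_across_population(self, random_population):
        seen: dict[int, tuple[int, int]] = {}
        for g in random_population:
            for innov, c in g.connections.items():
                pair = (c.in_node, c.out_node)
                assert seen.setdefault(innov, pair) == pair


class TestSerialization:
    def test_json_round_trip_lossless(self, registry, rng):
        g = make_random_genome(registry, rng)
        g.raw_fitness = 3.25
        g2 = Genome.from_json(g.to_json())
        assert set(g2.nodes) == set(g.nodes)
        for nid in g.nodes:
            assert g2.nodes[nid].node_type == g.nodes[nid].node_type
        assert set(g2.connections) == set(g.connections)
        for innov, c in g.connections.items():
            c2 = g2.connections[innov]
            assert (c2.in_node, c2.out_node, c2.weight, c2.enabled) == \
                (c.in_node, c.out_node, c.weight, c.enabled)
        assert g2.raw_fitness == g.raw_fitness
        # and the serialized form is valid JSON with the documented layout
        payload = json.loads(g.to_json())
        assert {"nodes", "connections"} <= payload.keys()
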