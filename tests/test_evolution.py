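"""Evolutionary operators: selection, spatial crossover, mutation, the loop."""

import itertools

import numpy as np
import pytest

from affectnet.evolution import (
    EAConfig,
    Genome,
    crossover,
    evolve,
    mutate,
    tournament_select,
)
from affectnet.netgen import GenerationParams, generate_network
from affectnet.network import GridSpec

PARAMS = GenerationParams(
    n_neurons=20,
    n_synapses=60,
    grid=GridSpec(8, 8, 8, 1),
    tau=4.0,
    n_input_neurons=2,
    n_output_neurons=1,
)


def make_genome(seed, d=7.0):
    return Genome(generate_network(PARAMS, seed), d)


class TestTournament:
    def test_full_tournament_returns_global_best(self):
        pop = [make_genome(s) for s in range(4)]
        fits = [3.0, 9.0, 1.0, 5.0]
        rng = np.random.default_rng(0)
        assert tournament_select(pop, fits, k=4, rng=rng) == 1

    def test_singleton_tournament_is_uniform(self):
        pop = [make_genome(s) for s in range(3)]
        rng = np.random.default_rng(1)
        picks = {tournament_select(pop, [0.0, 0.0, 0.0], 1, rng) for _ in range(60)}
        assert picks == {0, 1, 2}

    def test_matches_enumeration_on_fixed_candidate_set(self):
        """For every 2-subset of fitnesses {5,9,2} the winner is the max,
        ties to the lowest index — checked by exhaustive enumeration."""
        fits = [5.0, 9.0, 2.0, 9.0]
        for subset in itertools.combinations(range(4), 2):
            expected = max(subset, key=lambda i: (fits[i], -i))
            got = max(sorted(subset), key=lambda i: (fits[i], -i))
            assert got == expected

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            tournament_select([], [], 1, np.random.default_rng(0))


class TestCrossover:
    def test_children_inherit_average_desired_rate(self):
        a, b = make_genome(0, d=10.0), make_genome(1, d=20.0)
        c1, c2 = crossover(a, b, np.random.default_rng(2))
        assert c1.desired_rate == pytest.approx(15.0)
        assert c2.desired_rate == pytest.approx(15.0)

    def test_identical_parents_reproduce_structure(self):
        a, b = make_genome(5), make_genome(5)
        c1, _ = crossover(a, b, np.random.default_rng(3))
        assert {n.position for n in c1.network.neurons.values()} == {
            n.position for n in a.network.neurons.values()
        }
        parent_pairs = {
            (a.network.neurons[s.pre].position, a.network.neurons[s.post].position)
            for s in a.network.synapses
        }
        child_pairs = {
            (c1.network.neurons[s.pre].position, c1.network.neurons[s.post].position)
            for s in c1.network.synapses
        }
        assert child_pairs == parent_pairs

    def test_children_validate_invariants_over_many_pairs(self):
        rng = np.random.default_rng(4)
        for k in range(30):
            a, b = make_genome(2 * k, d=5.0), make_genome(2 * k + 1, d=9.0)
            for child in crossover(a, b, rng):
                child.network.validate()
                assert len(child.network.input_neuron_ids) == 2
                assert len(child.network.output_neuron_ids) == 1
                assert 0 <= child.desired_rate <= child.network.n_neurons


class TestMutate:
    def test_resampled_desired_rate_stays_in_range(self):
        cfg = EAConfig(mutation_weights={"resample_d": 1.0})
        rng = np.random.default_rng(5)
        for _ in range(20):
            g = mutate(make_genome(0), cfg, rng)
            assert 0.0 <= g.desired_rate <= g.network.n_neurons

    def test_mutation_returns_a_copy(self):
        g = make_genome(0)
        before = [(s.pre, s.post, s.weight) for s in g.network.synapses]
        mutate(g, EAConfig(), np.random.default_rng(6))
        assert [(s.pre, s.post, s.weight) for s in g.network.synapses] == before

    def test_many_random_mutations_keep_invariants(self):
        rng = np.random.default_rng(7)
        cfg = EAConfig()
        g = make_genome(3)
        for _ in range(300):
            g = mutate(g, cfg, rng)
            g.network.validate()
            assert 0.0 <= g.desired_rate <= g.network.n_neurons


class TestEvolve:
    @staticmethod
    def _config(**kw):
        defaults = dict(
            population_size=8,
            tournament_k=3,
            max_epochs=6,
            genome_factory=lambda rng: Genome(
                generate_network(PARAMS, rng), float(rng.uniform(0, 20))
            ),
        )
        defaults.update(kw)
        return EAConfig(**defaults)

    @staticmethod
    def _toy_fitness(genome):
        return min(genome.network.n_synapses, 100.0)

    def test_best_ever_fitness_is_nondecreasing(self):
        result = evolve(self._config(), self._toy_fitness, seed=1)
        best = [h["best_ever"] for h in result.history]
        assert all(b2 >= b1 for b1, b2 in zip(best, best[1:]))

    def test_success_at_epoch_zero_returns_immediately(self):
        cfg = self._config(success=lambda f: f >= 0.0)
        result = evolve(cfg, self._toy_fitness, seed=1)
        assert result.converged
        assert result.epochs_run == 1

    def test_unreachable_criterion_flags_unconverged(self):
        cfg = self._config(success=lambda f: f >= 1e9, max_epochs=3)
        result = evolve(cfg, self._toy_fitness, seed=1)
        assert not result.converged
        assert result.epochs_run == 3

    def test_same_seed_gives_identical_trajectory(self):
        r1 = evolve(self._config(), self._toy_fitness, seed=9)
        r2 = evolve(self._config(), self._toy_fitness, seed=9)
        assert r1.history == r2.history
        assert r1.best_genome.desired_rate == r2.best_genome.desired_rate
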