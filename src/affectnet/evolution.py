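"""Evolutionary training of network topology, weights, thresholds and the
desired-firing-rate trait.

Genomes are networks manipulated directly (no indirect encoding) together
with the desired firing rate d, which is evolved like any other trait:
crossover gives both children the parents' average d, and one mutation type
resamples d uniformly on [0, number of neurons].  Parents are chosen by
tournament selection; one elite is carried over unchanged each epoch, so
best-ever fitness is nondecreasing.

Structural crossover splits both parents by a random axis-aligned plane
through the grid and exchanges the two sides' neurons; synapses whose
endpoints both survive are inherited, and a synapse left dangling by the
exchange is reattached to the nearest surviving neuron.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .network import (
    NetworkModel,
    NeuronState,
    SynapseState,
    neuron_distance,
)

__all__ = ["Genome", "EAConfig", "EvolutionResult", "tournament_select", "crossover", "mutate", "evolve"]

MUTATION_TYPES = (
    "add_neuron",
    "delete_neuron",
    "add_synapse",
    "delete_synapse",
    "perturb_weight",
    "perturb_threshold",
    "resample_d",
)


@dataclass
class Genome:
    """A network plus its evolved desired firing rate."""

    network: NetworkModel
    desired_rate: float

    def __post_init__(self) -> None:
        self.desired_rate = float(
            min(max(self.desired_rate, 0.0), self.network.n_neurons)
        )

    def copy(self) -> "Genome":
        return Genome(copy.deepcopy(self.network), self.desired_rate)


@dataclass
class EAConfig:
    population_size: int = 50
    tournament_k: int = 5
    crossover_prob: float = 0.9
    mutation_prob: float = 0.9
    mutation_weights: Dict[str, float] = field(
        default_factory=lambda: {t: 1.0 for t in MUTATION_TYPES}
    )
    max_epochs: int = 100
    elitism: int = 1
    success: Optional[Callable[[float], bool]] = None
    genome_factory: Optional[Callable[[np.random.Generator], Genome]] = None
    perturb_sigma: float = 0.1

    def validate(self) -> None:
        if self.population_size < 2:
            raise ValueError("population size must be >= 2")
        for name in ("crossover_prob", "mutation_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.tournament_k > self.population_size:
            raise ValueError("tournament size exceeds population size")


@dataclass
class EvolutionResult:
    best_genome: Genome
    best_fitness: float
    converged: bool
    epochs_run: int
    history: List[Dict[str, float]]  # per-epoch best/mean fitness


def tournament_select(
    population: Sequence[Genome],
    fitnesses: Sequence[float],
    k: int,
    rng: np.random.Generator,
) -> int:
    """Index of the fittest of k distinct uniformly sampled candidates.

    Ties go to the lowest index among the sampled candidates.
    """
    if not population:
        raise ValueError("empty population")
    if k > len(population):
        raise ValueError("tournament size exceeds population size")
    candidates = sorted(rng.choice(len(population), size=k, replace=False))
    return max(candidates, key=lambda i: (fitnesses[i], -i))


def _clamp_unit(v: float) -> float:
    return -1.0 if v < -1.0 else 1.0 if v > 1.0 else v


def _assemble_child(
    io_parent: NetworkModel,
    left_parent: NetworkModel,
    right_parent: NetworkModel,
    axis: int,
    cut: float,
    d_child: float,
) -> Genome:
    """Build one crossover child: IO neurons from `io_parent`, non-IO neurons
    from `left_parent` below the cut and `right_parent` at/above it."""
    io_ids = set(io_parent.input_neuron_ids) | set(io_parent.output_neuron_ids)
    chosen: List[Tuple[NetworkModel, int]] = [(io_parent, nid) for nid in
                                              list(io_parent.input_neuron_ids) + list(io_parent.output_neuron_ids)]
    taken = {io_parent.neurons[nid].position for _, nid in chosen}
    for parent, side in ((left_parent, 0), (right_parent, 1)):
        parent_io = set(parent.input_neuron_ids) | set(parent.output_neuron_ids)
        for nid, n in parent.neurons.items():
            if nid in parent_io:
                continue
            on_right = n.position[axis] >= cut
            if (side == 1) != on_right:
                continue
            if n.position in taken:
                continue  # positions collide across parents: first writer wins
            taken.add(n.position)
            chosen.append((parent, nid))

    id_map: Dict[Tuple[int, int], int] = {}
    neurons: Dict[int, NeuronState] = {}
    for new_id, (parent, nid) in enumerate(chosen):
        id_map[(id(parent), nid)] = new_id
        old = parent.neurons[nid]
        neurons[new_id] = NeuronState(
            id=new_id,
            position=old.position,
            threshold=old.threshold,
            refractory_period=old.refractory_period,
            is_input=old.is_input,
            is_output=old.is_output,
        )
    n_io = len(io_ids)
    input_ids = [id_map[(id(io_parent), nid)] for nid in io_parent.input_neuron_ids]
    output_ids = [id_map[(id(io_parent), nid)] for nid in io_parent.output_neuron_ids]

    positions = np.array([neurons[i].position for i in range(len(neurons))])

    def nearest(pos: Tuple[float, float, float], exclude: int) -> int:
        d = np.linalg.norm(positions - np.asarray(pos), axis=1)
        d[exclude] = np.inf
        return int(np.argmin(d))

    synapses: List[SynapseState] = []
    pairs = set()
    for parent in (left_parent, right_parent) if left_parent is not right_parent else (left_parent,):
        for s in parent.synapses:
            pre = id_map.get((id(parent), s.pre))
            post = id_map.get((id(parent), s.post))
            if pre is None and post is None:
                continue
            if pre is None:
                post_ = post
                pre = nearest(parent.neurons[s.pre].position, post_)
            elif post is None:
                post = nearest(parent.neurons[s.post].position, pre)
            if pre == post or (pre, post) in pairs:
                continue
            pairs.add((pre, post))
            synapses.append(
                SynapseState(
                    pre=pre,
                    post=post,
                    weight=s.weight,
                    distance=neuron_distance(neurons[pre].position, neurons[post].position),
                )
            )
    child_net = NetworkModel(
        neurons=neurons,
        synapses=synapses,
        grid=io_parent.grid,
        plasticity=copy.deepcopy(io_parent.plasticity),
        input_neuron_ids=input_ids,
        output_neuron_ids=output_ids,
    )
    child_net.rebuild_index()
    return Genome(child_net, d_child)


def crossover(
    parent_a: Genome, parent_b: Genome, rng: np.random.Generator
) -> Tuple[Genome, Genome]:
    """Exchange the two sides of a random axis-aligned plane between parents.

    Both children inherit the parents' average desired firing rate (clamped
    to [0, child neuron count]); child 1 keeps parent A's designated
    input/output neurons, child 2 keeps parent B's.
    """
    net_a, net_b = parent_a.network, parent_b.network
    axis = int(rng.integers(0, 3))
    m = (net_a.grid.mx, net_a.grid.my, net_a.grid.mz)[axis]
    cut = float(rng.uniform(-m, m))
    d_mean = (parent_a.desired_rate + parent_b.desired_rate) / 2.0
    child1 = _assemble_child(net_a, net_a, net_b, axis, cut, d_mean)
    child2 = _assemble_child(net_b, net_b, net_a, axis, cut, d_mean)
    return child1, child2


def mutate(genome: Genome, config: EAConfig, rng: np.random.Generator) -> Genome:
    """Apply one sampled mutation from the menu; impossible draws resample."""
    g = genome.copy()
    net = g.network
    types = list(config.mutation_weights)
    probs = np.array([config.mutation_weights[t] for t in types], dtype=float)
    probs /= probs.sum()
    io_ids = set(net.input_neuron_ids) | set(net.output_neuron_ids)
    for _ in range(50):
        kind = types[int(rng.choice(len(types), p=probs))]
        if kind == "add_neuron":
            pos = _free_site(net, rng)
            if pos is None:
                continue
            nid = max(net.neurons) + 1
            net.neurons[nid] = NeuronState(id=nid, position=pos, threshold=0.5)
        elif kind == "delete_neuron":
            deletable = [i for i in net.neurons if i not in io_ids]
            if not deletable:
                continue
            victim = deletable[int(rng.integers(len(deletable)))]
            del net.neurons[victim]
            net.synapses = [s for s in net.synapses if victim not in (s.pre, s.post)]
        elif kind == "add_synapse":
            pair = _free_pair(net, rng)
            if pair is None:
                continue
            pre, post = pair
            net.synapses.append(
                SynapseState(
                    pre=pre,
                    post=post,
                    weight=float(rng.uniform(-1, 1)),
                    distance=neuron_distance(
                        net.neurons[pre].position, net.neurons[post].position
                    ),
                )
            )
        elif kind == "delete_synapse":
            if not net.synapses:
                continue
            del net.synapses[int(rng.integers(len(net.synapses)))]
        elif kind == "perturb_weight":
            if not net.synapses:
                continue
            s = net.synapses[int(rng.integers(len(net.synapses)))]
            s.weight = _clamp_unit(s.weight + float(rng.normal(0, config.perturb_sigma)))
        elif kind == "perturb_threshold":
            nid = list(net.neurons)[int(rng.integers(len(net.neurons)))]
            n = net.neurons[nid]
            n.threshold = _clamp_unit(
                n.threshold + float(rng.normal(0, config.perturb_sigma))
            )
        elif kind == "resample_d":
            g.desired_rate = float(rng.uniform(0, net.n_neurons))
        else:
            raise ValueError(f"unknown mutation type {kind}")
        break
    g.desired_rate = float(min(max(g.desired_rate, 0.0), net.n_neurons))
    net.invalidate_index()
    net.rebuild_index()
    return g


def _free_site(net: NetworkModel, rng: np.random.Generator, attempts: int = 100):
    per_axis = net.grid.sites_per_axis()
    g = net.grid.g
    taken = {n.position for n in net.neurons.values()}
    for _ in range(attempts):
        idx = rng.integers(0, per_axis, size=3)
        pos = (
            float(idx[0] * g - net.grid.mx),
            float(idx[1] * g - net.grid.my),
            float(idx[2] * g - net.grid.mz),
        )
        if pos not in taken:
            return pos
    return None


def _free_pair(net: NetworkModel, rng: np.random.Generator, attempts: int = 100):
    ids = list(net.neurons)
    if len(ids) < 2:
        return None
    existing = {(s.pre, s.post) for s in net.synapses}
    for _ in range(attempts):
        pre, post = (ids[int(i)] for i in rng.choice(len(ids), size=2, replace=False))
        if (pre, post) not in existing:
            return pre, post
    return None


def evolve(
    config: EAConfig,
    fitness_fn: Callable[[Genome], float],
    seed: int = 0,
) -> EvolutionResult:
    """Generational loop: evaluate, select, crossover, mutate, with elitism.

    Stops when ``config.success(best_fitness)`` holds or after
    ``max_epochs`` generations (flagged unconverged).  The same seed yields
    an identical trajectory.
    """
    config.validate()
    if config.genome_factory is None:
        raise ValueError("EAConfig.genome_factory is required")
    rng = np.random.default_rng(seed)
    population = [config.genome_factory(rng) for _ in range(config.population_size)]

    best_genome: Optional[Genome] = None
    best_fitness = -math.inf
    history: List[Dict[str, float]] = []
    converged = False
    epochs = 0
    for epoch in range(config.max_epochs):
        epochs = epoch + 1
        fitnesses = [fitness_fn(g) for g in population]
        order = int(np.argmax(fitnesses))
        if fitnesses[order] > best_fitness:
            best_fitness = fitnesses[order]
            best_genome = population[order].copy()
        history.append(
            {
                "epoch": float(epoch),
                "best": float(max(fitnesses)),
                "mean": float(np.mean(fitnesses)),
                "best_ever": float(best_fitness),
            }
        )
        if config.success is not None and config.success(best_fitness):
            converged = True
            break
        next_pop: List[Genome] = [
            population[i].copy()
            for i in np.argsort(fitnesses)[::-1][: config.elitism]
        ]
        while len(next_pop) < config.population_size:
            ia = tournament_select(population, fitnesses, config.tournament_k, rng)
            ib = tournament_select(population, fitnesses, config.tournament_k, rng)
            if rng.uniform() < config.crossover_prob:
                c1, c2 = crossover(population[ia], population[ib], rng)
            else:
                c1, c2 = population[ia].copy(), population[ib].copy()
            for child in (c1, c2):
                if len(next_pop) >= config.population_size:
                    break
                if rng.uniform() < config.mutation_prob:
                    child = mutate(child, config, rng)
                next_pop.append(child)
        population = next_pop
    assert best_genome is not None
    return EvolutionResult(
        best_genome=best_genome,
        best_fitness=best_fitness,
        converged=converged,
        epochs_run=epochs,
        history=history,
    )
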