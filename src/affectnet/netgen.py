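"""Seeded generation of random networks and exogenous input pulse trains.

A network realization places ``n_neurons`` at distinct uniformly random
grid sites and draws ``n_synapses`` distinct directed pairs with a
proximity bias: the probability of a pair is proportional to
``exp(-distance / tau)``, so spatially close neurons are more likely to be
connected.  Synapse weights are i.i.d. uniform on [-1, 1] and all
thresholds start at 0.5.  The environment drives a single designated input
neuron with pulses at exponentially distributed intervals (default mean
rate 0.1 pulses per unit time, i.e. mean gap 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy.spatial.distance import cdist

from .network import (
    GridSpec,
    NetworkModel,
    NeuronState,
    PlasticityParams,
    SynapseState,
)

__all__ = ["GenerationParams", "generate_network", "input_pulse_times"]

RngLike = Union[int, np.random.Generator]


def _as_rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class GenerationParams:
    n_neurons: int = 1000
    n_synapses: int = 10000
    grid: GridSpec = field(default_factory=GridSpec)
    initial_threshold: float = 0.5
    weight_low: float = -1.0
    weight_high: float = 1.0
    tau: float = 20.0  # proximity length scale for synapse placement, grid units
    n_input_neurons: int = 1
    n_output_neurons: int = 0
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)

    def validate(self) -> None:
        sites = self.grid.sites_per_axis() ** 3
        if self.n_neurons > sites:
            raise ValueError(f"{self.n_neurons} neurons exceed {sites} grid sites")
        if self.n_neurons < 1:
            raise ValueError("need at least one neuron")
        max_pairs = self.n_neurons * (self.n_neurons - 1)
        if self.n_synapses > max_pairs:
            raise ValueError(
                f"{self.n_synapses} synapses exceed {max_pairs} distinct directed pairs"
            )
        if self.n_input_neurons + self.n_output_neurons > self.n_neurons:
            raise ValueError("more designated IO neurons than neurons")
        if self.tau <= 0:
            raise ValueError("proximity scale tau must be positive")


def _sample_positions(params: GenerationParams, rng: np.random.Generator) -> np.ndarray:
    """Distinct uniform grid sites, coordinates in [-M, M) as multiples of g."""
    per_axis = params.grid.sites_per_axis()
    g = params.grid.g
    chosen: dict = {}
    while len(chosen) < params.n_neurons:
        need = params.n_neurons - len(chosen)
        draw = rng.integers(0, per_axis, size=(max(need * 2, 16), 3))
        for row in draw:
            key = (int(row[0]), int(row[1]), int(row[2]))
            if key not in chosen:
                chosen[key] = None
                if len(chosen) == params.n_neurons:
                    break
    idx = np.array(list(chosen.keys()), dtype=float)
    offsets = np.array([params.grid.mx, params.grid.my, params.grid.mz])
    return idx * g - offsets


def _sample_synapse_pairs(
    positions: np.ndarray, n_synapses: int, tau: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distinct directed pairs, P(i->j) proportional to exp(-dist(i,j)/tau).

    Sampling without replacement uses the Gumbel top-k trick on the pair
    logits, which is exact and vectorizes over all n*(n-1) candidates.
    """
    dist = cdist(positions, positions)
    logits = -dist / tau
    np.fill_diagonal(logits, -np.inf)
    keys = logits + rng.gumbel(size=logits.shape)
    flat = keys.ravel()
    top = np.argpartition(flat, -n_synapses)[-n_synapses:]
    top = top[np.argsort(flat[top])[::-1]]  # deterministic order, best first
    n = positions.shape[0]
    pre, post = np.divmod(top, n)
    return pre, post, dist[pre, post]


def generate_network(params: GenerationParams, seed: RngLike = 0) -> NetworkModel:
    """Draw one seeded network realization; same seed gives an identical network."""
    params.validate()
    rng = _as_rng(seed)
    positions = _sample_positions(params, rng)
    pre, post, distances = _sample_synapse_pairs(
        positions, params.n_synapses, params.tau, rng
    )
    weights = rng.uniform(params.weight_low, params.weight_high, size=params.n_synapses)

    io_ids = rng.choice(
        params.n_neurons,
        size=params.n_input_neurons + params.n_output_neurons,
        replace=False,
    )
    input_ids = [int(i) for i in io_ids[: params.n_input_neurons]]
    output_ids = [int(i) for i in io_ids[params.n_input_neurons :]]

    neurons = {
        i: NeuronState(
            id=i,
            position=(float(p[0]), float(p[1]), float(p[2])),
            threshold=params.initial_threshold,
            is_input=i in input_ids,
            is_output=i in output_ids,
        )
        for i, p in enumerate(positions)
    }
    synapses = [
        SynapseState(pre=int(a), post=int(b), weight=float(w), distance=float(d))
        for a, b, w, d in zip(pre, post, weights, distances)
    ]
    net = NetworkModel(
        neurons=neurons,
        synapses=synapses,
        grid=params.grid,
        plasticity=PlasticityParams(
            params.plasticity.step, params.plasticity.refractory, params.plasticity.enabled
        ),
        input_neuron_ids=input_ids,
        output_neuron_ids=output_ids,
    )
    net.rebuild_index()
    return net


def input_pulse_times(rate: float = 0.1, t_end: float = 10000.0, seed: RngLike = 0) -> np.ndarray:
    """Sorted pulse times on (0, t_end] with i.i.d. exponential(1/rate) gaps."""
    if rate <= 0:
        raise ValueError(f"pulse rate must be positive, got {rate}")
    if t_end <= 0:
        return np.empty(0)
    rng = _as_rng(seed)
    mean_gap = 1.0 / rate
    chunk = max(int(t_end * rate * 1.2) + 16, 64)
    times = np.cumsum(rng.exponential(mean_gap, size=chunk))
    while times[-1] <= t_end:  # rarely needed: extend until we pass t_end
        extra = np.cumsum(rng.exponential(mean_gap, size=chunk)) + times[-1]
        times = np.concatenate([times, extra])
    return times[times <= t_end]
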