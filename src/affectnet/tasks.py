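"""Task wiring: genome factories and EA configurations for applications."""

from __future__ import annotations

import numpy as np

from .evolution import EAConfig, Genome
from .netgen import GenerationParams, generate_network
from .network import GridSpec

__all__ = ["random_cartpole_genome", "cartpole_ea_config"]

# Cart-pole networks are small: ~25 neurons on a compact grid, 12 designated
# input neurons (3 ranges x 4 state variables) and 2 output neurons.
CARTPOLE_GRID = GridSpec(mx=10.0, my=10.0, mz=10.0, g=1.0)


def random_cartpole_genome(
    rng: np.random.Generator,
    n_neurons: int = 25,
    n_synapses: int = 220,
) -> Genome:
    params = GenerationParams(
        n_neurons=n_neurons,
        n_synapses=n_synapses,
        grid=CARTPOLE_GRID,
        tau=5.0,
        n_input_neurons=12,
        n_output_neurons=2,
    )
    net = generate_network(params, rng)
    desired_rate = float(rng.uniform(0, n_neurons))
    return Genome(net, desired_rate)


def cartpole_ea_config(
    population_size: int = 50,
    max_epochs: int = 100,
    success_fitness: float = 300.0,
) -> EAConfig:
    """EA setup for cart-pole: succeed when all six starts reach the cap."""
    return EAConfig(
        population_size=population_size,
        max_epochs=max_epochs,
        success=lambda best: best >= success_fitness,
        genome_factory=random_cartpole_genome,
    )
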