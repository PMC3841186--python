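"""Neuron and synapse model: charge accumulation, threshold firing, geometry.

Neurons live on a discrete 3-D grid and carry a charge that accumulates
until it reaches the neuron's threshold.  When the threshold is reached and
the neuron is outside its refractory period it fires: the charge resets to
zero (neutral) and one packet of charge is dispatched along every outgoing
synapse.  Charge and threshold values are bounded to [-1, 1].  A synapse's
propagation delay equals the Euclidean distance between its endpoints
(charge travels one grid unit per unit of simulation time; there is no
myelination).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

Position = Tuple[float, float, float]

CHARGE_MIN = -1.0
CHARGE_MAX = 1.0


def _clamp(value: float, lo: float = CHARGE_MIN, hi: float = CHARGE_MAX) -> float:
    return lo if value < lo else hi if value > hi else value


@dataclass(slots=True)
class GridSpec:
    """Bounds of the 3-D grid neurons may occupy.

    Coordinates are integral multiples of the granularity ``g`` in
    ``[-M, M)`` per axis, so the default (M=100, g=1) allows 200 distinct
    values per axis.
    """

    mx: float = 100.0
    my: float = 100.0
    mz: float = 100.0
    g: float = 1.0

    def contains(self, pos: Sequence[float]) -> bool:
        for coord, m in zip(pos, (self.mx, self.my, self.mz)):
            if not (-m <= coord < m):
                return False
            ratio = coord / self.g
            if abs(ratio - round(ratio)) > 1e-9:
                return False
        return True

    def sites_per_axis(self) -> int:
        return int(round(2 * self.mx / self.g))


@dataclass(slots=True)
class PlasticityParams:
    """LTP/LTD parameters: fixed weight step and per-synapse refractory period."""

    step: float = 0.001
    refractory: float = 10.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"plasticity step must be positive, got {self.step}")
        if self.refractory < 0:
            raise ValueError(f"plasticity refractory must be >= 0, got {self.refractory}")


@dataclass(slots=True)
class NeuronState:
    id: int
    position: Position
    threshold: float = 0.5
    charge: float = 0.0
    refractory_period: float = 1.0
    last_fire_time: Optional[float] = None
    is_input: bool = False
    is_output: bool = False

    def in_refractory(self, time: float) -> bool:
        return self.last_fire_time is not None and (time - self.last_fire_time) < self.refractory_period


@dataclass(slots=True)
class SynapseState:
    pre: int
    post: int
    weight: float
    distance: float
    last_plasticity_time: Optional[float] = None


@dataclass(slots=True)
class ChargeOutcome:
    fired: bool
    new_charge: float


@dataclass(slots=True)
class Arrival:
    """A packet of charge in flight: `amount` reaches `post` at `time`."""

    post: int
    time: float
    amount: float
    synapse: SynapseState


@dataclass
class NetworkModel:
    """A spiking network: neurons on a grid plus directed weighted synapses."""

    neurons: Dict[int, NeuronState] = field(default_factory=dict)
    synapses: List[SynapseState] = field(default_factory=list)
    grid: GridSpec = field(default_factory=GridSpec)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    input_neuron_ids: List[int] = field(default_factory=list)
    output_neuron_ids: List[int] = field(default_factory=list)
    _outgoing: Optional[Dict[int, List[SynapseState]]] = field(
        default=None, repr=False, compare=False
    )

    # ------------------------------------------------------------------
    # indexing
    def rebuild_index(self) -> None:
        out: Dict[int, List[SynapseState]] = {}
        for s in self.synapses:
            out.setdefault(s.pre, []).append(s)
        self._outgoing = out

    def outgoing(self, neuron_id: int) -> List[SynapseState]:
        if self._outgoing is None:
            self.rebuild_index()
        assert self._outgoing is not None
        return self._outgoing.get(neuron_id, [])

    def invalidate_index(self) -> None:
        self._outgoing = None

    # ------------------------------------------------------------------
    # convenience
    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    @property
    def n_synapses(self) -> int:
        return len(self.synapses)

    def weights(self) -> List[float]:
        return [s.weight for s in self.synapses]

    def mean_threshold(self) -> float:
        return sum(n.threshold for n in self.neurons.values()) / len(self.neurons)

    def reset_dynamic_state(self) -> None:
        """Zero all charges and forget firing/plasticity history (weights kept)."""
        for n in self.neurons.values():
            n.charge = 0.0
            n.last_fire_time = None
        for s in self.synapses:
            s.last_plasticity_time = None

    # ------------------------------------------------------------------
    # validation
    def validate(self) -> None:
        """Raise ValueError on any violated structural invariant."""
        seen_positions: Dict[Position, int] = {}
        for nid, n in self.neurons.items():
            if nid != n.id:
                raise ValueError(f"neuron keyed {nid} carries id {n.id}")
            if not self.grid.contains(n.position):
                raise ValueError(f"neuron {nid} position {n.position} off grid")
            if n.position in seen_positions:
                raise ValueError(
                    f"neurons {seen_positions[n.position]} and {nid} share position {n.position}"
                )
            seen_positions[n.position] = nid
            if not (CHARGE_MIN <= n.threshold <= CHARGE_MAX):
                raise ValueError(f"neuron {nid} threshold {n.threshold} out of [-1,1]")
            if not (CHARGE_MIN <= n.charge <= CHARGE_MAX):
                raise ValueError(f"neuron {nid} charge {n.charge} out of [-1,1]")
        pairs = set()
        for s in self.synapses:
            if s.pre not in self.neurons or s.post not in self.neurons:
                raise ValueError(f"synapse {s.pre}->{s.post} references missing neuron")
            if s.pre == s.post:
                raise ValueError(f"self-synapse on neuron {s.pre}")
            if (s.pre, s.post) in pairs:
                raise ValueError(f"duplicate synapse {s.pre}->{s.post}")
            pairs.add((s.pre, s.post))
            if not (CHARGE_MIN <= s.weight <= CHARGE_MAX):
                raise ValueError(f"synapse {s.pre}->{s.post} weight {s.weight} out of [-1,1]")
            expected = neuron_distance(
                self.neurons[s.pre].position, self.neurons[s.post].position
            )
            if abs(s.distance - expected) > 1e-9:
                raise ValueError(
                    f"synapse {s.pre}->{s.post} distance {s.distance} != geometric {expected}"
                )
        for nid in list(self.input_neuron_ids) + list(self.output_neuron_ids):
            if nid not in self.neurons:
                raise ValueError(f"designated IO neuron {nid} does not exist")


# ----------------------------------------------------------------------
# operations


def neuron_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Euclidean distance between two grid positions (= propagation delay)."""
    return math.dist(a, b)


def add_charge(network: NetworkModel, neuron: int, amount: float, time: float) -> ChargeOutcome:
    """Deposit `amount` of charge on a neuron at `time`; fire it if able.

    The charge is clamped to [-1, 1] after accumulation.  If the clamped
    charge reaches the threshold and the neuron is outside its refractory
    period, the neuron fires: the outcome reports ``fired=True`` and the
    charge is reset to zero.  Inside the refractory period charge is
    retained but the neuron cannot fire.
    """
    try:
        n = network.neurons[neuron]
    except KeyError:
        raise KeyError(f"unknown neuron id {neuron}") from None
    if not math.isfinite(amount):
        raise ValueError(f"non-finite charge amount {amount}")
    n.charge = _clamp(n.charge + amount)
    if n.charge >= n.threshold and not n.in_refractory(time):
        n.charge = 0.0
        n.last_fire_time = time
        return ChargeOutcome(fired=True, new_charge=0.0)
    return ChargeOutcome(fired=False, new_charge=n.charge)


def fire_neuron(network: NetworkModel, neuron: int, time: float) -> List[Arrival]:
    """Charge-arrival descriptors produced by a neuron firing at `time`.

    One descriptor per outgoing synapse: the packet carries the synapse
    weight and arrives after a delay equal to the synapse distance.  Calling
    this for a neuron strictly inside its refractory period (i.e. one that
    cannot have fired at `time`) is a contract violation.
    """
    n = network.neurons[neuron]
    if n.last_fire_time is not None and 0.0 < time - n.last_fire_time < n.refractory_period:
        raise RuntimeError(
            f"neuron {neuron} fired at {n.last_fire_time} and is refractory at {time}"
        )
    return [
        Arrival(post=s.post, time=time + s.distance, amount=s.weight, synapse=s)
        for s in network.outgoing(neuron)
    ]
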