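"""Discrete-event simulation engine.

Event types: charge addition, neuron firing, network-wide threshold
adjustment, input pulses from the environment, changes in the desired
firing rate, and (for applications) output observations.  Events are kept
in a priority queue ordered by time; events at equal times are processed in
insertion order, which makes every simulation a deterministic function of
the network, the schedule and the seeds that produced them.

Time is continuous: one unit of simulation time is the time charge takes to
travel one grid unit, and synapse distances need not be integral.  When an
affective controller is attached, threshold-adjustment events fire at exact
multiples of its window length ``w``.

Firing is evaluated at charge-arrival time only: lowering thresholds below
a neuron's stored charge does not by itself fire the neuron — it fires on
its next charge arrival.
"""

from __future__ import annotations

import enum
import heapq
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .affective import AffectiveState, apply_threshold_change
from .network import NetworkModel, SynapseState, fire_neuron

__all__ = [
    "EventType",
    "Event",
    "EventQueue",
    "QueueExhausted",
    "SimulationTrace",
    "Simulator",
    "run",
    "measured_firing_rate",
]

INPUT_PULSE_AMOUNT = 1.0  # a pulse fires any non-refractory neuron (thresholds <= 1)


class EventType(enum.Enum):
    CHARGE_ADDITION = "charge_addition"
    NEURON_FIRE = "neuron_fire"
    THRESHOLD_ADJUSTMENT = "threshold_adjustment"
    INPUT_PULSE = "input_pulse"
    DESIRED_RATE_CHANGE = "desired_rate_change"
    OUTPUT_OBSERVATION = "output_observation"


@dataclass(slots=True)
class Event:
    """A timestamped tagged record; payload fields depend on the type."""

    time: float
    type: EventType
    neuron: Optional[int] = None
    amount: Optional[float] = None
    synapse: Optional[SynapseState] = None
    rate: Optional[float] = None
    sequence_number: int = -1


class QueueExhausted(Exception):
    """Raised when popping from an empty event queue."""


class EventQueue:
    """Priority queue ordered by (time, insertion sequence)."""

    def __init__(self) -> None:
        self._heap: List[Tuple[float, int, Event]] = []
        self._seq = 0
        self._now = 0.0

    def __len__(self) -> int:
        return len(self._heap)

    @property
    def now(self) -> float:
        return self._now

    def push(self, event: Event) -> "EventQueue":
        if event.time < 0:
            raise ValueError(f"event time must be >= 0, got {event.time}")
        if event.time < self._now:
            raise ValueError(
                f"cannot schedule event at {event.time}: simulation time is {self._now}"
            )
        event.sequence_number = self._seq
        heapq.heappush(self._heap, (event.time, self._seq, event))
        self._seq += 1
        return self

    def peek_time(self) -> Optional[float]:
        return self._heap[0][0] if self._heap else None

    def pop(self) -> Event:
        if not self._heap:
            raise QueueExhausted("event queue is empty")
        time, _, event = heapq.heappop(self._heap)
        self._now = time
        return event


# Spec-surface alias: scheduling is the queue's push.
def schedule_event(queue: EventQueue, event: Event) -> EventQueue:
    return queue.push(event)


@dataclass
class SimulationTrace:
    """Time-sorted record of a simulation run."""

    firing_events: List[Tuple[float, int]] = field(default_factory=list)
    threshold_series: List[Tuple[float, float]] = field(default_factory=list)
    # (window end time, firings per unit time averaged over the window)
    rate_series: List[Tuple[float, float]] = field(default_factory=list)
    desired_series: List[Tuple[float, float]] = field(default_factory=list)
    weight_snapshots: List[Tuple[float, List[int]]] = field(default_factory=list)
    event_log: Optional[List[Event]] = None
    t_end: float = 0.0

    def firing_times(self) -> List[float]:
        return [t for t, _ in self.firing_events]

    def rate_values(self) -> List[float]:
        return [r for _, r in self.rate_series]


def measured_firing_rate(trace: SimulationTrace, t: float, w: float) -> int:
    """Count of firing events with time in the half-open window (t-w, t]."""
    if t < w:
        raise ValueError(f"window end {t} precedes window length {w}")
    times = trace.firing_times()
    return bisect_right(times, t) - bisect_right(times, t - w)


# internal event tags (heap entries are plain tuples for speed)
_CHARGE, _PULSE, _ADJUST, _RATE_CHANGE, _FIRE, _OUTPUT = range(6)

_TAG_TO_TYPE = {
    _CHARGE: EventType.CHARGE_ADDITION,
    _PULSE: EventType.INPUT_PULSE,
    _ADJUST: EventType.THRESHOLD_ADJUSTMENT,
    _RATE_CHANGE: EventType.DESIRED_RATE_CHANGE,
    _FIRE: EventType.NEURON_FIRE,
    _OUTPUT: EventType.OUTPUT_OBSERVATION,
}

_TYPE_TO_TAG = {v: k for k, v in _TAG_TO_TYPE.items()}


class Simulator:
    """Stepwise discrete-event simulator bound to one network.

    Supports incremental ``run_until`` calls with persistent state (event
    queue, charges, controller memory), which applications such as the
    cart-pole loop use to interleave environment steps with network time.

    The internal queue holds plain ``(time, seq, tag, neuron, amount,
    synapse)`` tuples rather than :class:`Event` objects: the charge-arrival
    path runs millions of times per simulation and tuple events roughly
    halve its cost.  Ordering semantics are identical to
    :class:`EventQueue` — (time, insertion sequence).
    """

    def __init__(
        self,
        network: NetworkModel,
        affective: Optional[AffectiveState] = None,
        *,
        record_event_log: bool = False,
        weight_snapshot_every: Optional[float] = None,
        histogram_fn=None,
    ) -> None:
        self.network = network
        self.affective = affective
        self._heap: List[tuple] = []
        self._seq = 0
        self._now = 0.0
        self.trace = SimulationTrace()
        if record_event_log:
            self.trace.event_log = []
        self._window_count = 0
        self._snapshot_every = weight_snapshot_every
        self._histogram_fn = histogram_fn
        self._last_snapshot = -1.0
        network.rebuild_index()  # built once, reused across windows
        if affective is not None:
            self._push(affective.w, _ADJUST, -1, 0.0, None)

    # -- scheduling ---------------------------------------------------------
    def _push(self, time: float, tag: int, neuron: int, amount: float, synapse) -> None:
        if time < self._now:
            raise ValueError(
                f"cannot schedule event at {time}: simulation time is {self._now}"
            )
        heapq.heappush(self._heap, (time, self._seq, tag, neuron, amount, synapse))
        self._seq += 1

    def schedule(self, event: Event) -> None:
        """Schedule a public Event (used by run() to adopt a caller's queue)."""
        tag = _TYPE_TO_TAG[event.type]
        amount = event.amount if event.amount is not None else 0.0
        if tag == _RATE_CHANGE:
            amount = event.rate
        self._push(event.time, tag, event.neuron if event.neuron is not None else -1,
                   amount, event.synapse)

    def schedule_pulse(self, time: float, neuron: Optional[int] = None) -> None:
        if neuron is None:
            if not self.network.input_neuron_ids:
                raise ValueError("network has no designated input neuron")
            neuron = self.network.input_neuron_ids[0]
        self._push(time, _PULSE, neuron, INPUT_PULSE_AMOUNT, None)

    def schedule_pulses(self, times: Sequence[float], neuron: Optional[int] = None) -> None:
        for t in times:
            self.schedule_pulse(float(t), neuron)

    def schedule_charge(self, time: float, neuron: int, amount: float) -> None:
        self._push(time, _CHARGE, neuron, amount, None)

    def schedule_desired_rate(self, time: float, rate: float) -> None:
        self._push(time, _RATE_CHANGE, -1, rate, None)

    # -- main loop ----------------------------------------------------------
    def run_until(self, t_end: float) -> SimulationTrace:
        """Process all events with time <= t_end; later events stay queued."""
        heap = self._heap
        pop = heapq.heappop
        push = heapq.heappush
        neurons = self.network.neurons
        plast = self.network.plasticity
        plast_on = plast.enabled
        plast_step = plast.step
        plast_refr = plast.refractory
        self.network.rebuild_index()  # evolution may have touched topology
        outgoing = self.network._outgoing
        empty: tuple = ()
        firings = self.trace.firing_events
        log = self.trace.event_log

        while heap:
            entry = heap[0]
            t = entry[0]
            if t > t_end:
                break
            pop(heap)
            self._now = t
            tag = entry[2]
            if log is not None:
                self._log_entry(entry)
            if tag == _CHARGE or tag == _PULSE:
                nid = entry[3]
                amount = entry[4]
                syn = entry[5]
                n = neurons[nid]
                last = n.last_fire_time
                was_refr = last is not None and (t - last) < n.refractory_period
                c = n.charge + amount
                if c < -1.0:
                    c = -1.0
                elif c > 1.0:
                    c = 1.0
                if c >= n.threshold and not was_refr:
                    n.charge = 0.0
                    n.last_fire_time = t
                    firings.append((t, nid))
                    self._window_count += 1
                    if syn is not None and plast_on:
                        # LTP credits the synapse whose arrival crossed threshold
                        lp = syn.last_plasticity_time
                        if lp is None or t - lp >= plast_refr:
                            w = syn.weight + plast_step
                            syn.weight = 1.0 if w > 1.0 else w
                            syn.last_plasticity_time = t
                    if log is not None:
                        log.append(Event(t, EventType.NEURON_FIRE, neuron=nid))
                    seq = self._seq
                    for s in outgoing.get(nid, empty):
                        push(heap, (t + s.distance, seq, _CHARGE, s.post, s.weight, s))
                        seq += 1
                    self._seq = seq
                else:
                    n.charge = c
                    if was_refr and syn is not None and plast_on:
                        lp = syn.last_plasticity_time
                        if lp is None or t - lp >= plast_refr:
                            w = syn.weight - plast_step
                            syn.weight = -1.0 if w < -1.0 else w
                            syn.last_plasticity_time = t
            elif tag == _ADJUST:
                self._handle_adjustment(t)
            elif tag == _RATE_CHANGE:
                if self.affective is not None:
                    self.affective.d = entry[4]
                self.trace.desired_series.append((t, entry[4]))
            elif tag == _FIRE:
                self._propagate(t, entry[3])
            elif tag == _OUTPUT:
                pass  # marker event; applications read firing counts off the trace
            else:  # pragma: no cover - tags are closed
                raise RuntimeError(f"malformed event {entry}")
        self.trace.t_end = max(self.trace.t_end, t_end)
        return self.trace

    def _log_entry(self, entry: tuple) -> None:
        t, _, tag, nid, amount, syn = entry
        self.trace.event_log.append(
            Event(
                t,
                _TAG_TO_TYPE[tag],
                neuron=nid if nid >= 0 else None,
                amount=amount if tag in (_CHARGE, _PULSE) else None,
                synapse=syn,
                rate=amount if tag == _RATE_CHANGE else None,
            )
        )

    def _propagate(self, time: float, neuron: int) -> None:
        for arr in fire_neuron(self.network, neuron, time):
            self._push(arr.time, _CHARGE, arr.post, arr.amount, arr.synapse)

    def _handle_adjustment(self, time: float) -> None:
        aff = self.affective
        rate = self._window_count / aff.w  # firings per unit time over the window
        self._window_count = 0
        delta = aff.update(rate, time)
        apply_threshold_change(self.network, delta)
        self.trace.rate_series.append((time, rate))
        self.trace.threshold_series.append((time, self.network.mean_threshold()))
        self.trace.desired_series.append((time, aff.d))
        if (
            self._snapshot_every is not None
            and self._histogram_fn is not None
            and time - self._last_snapshot >= self._snapshot_every - 1e-9
        ):
            self.trace.weight_snapshots.append(
                (time, self._histogram_fn(self.network.weights()))
            )
            self._last_snapshot = time
        self._push(time + aff.w, _ADJUST, -1, 0.0, None)


def run(
    network: NetworkModel,
    queue: EventQueue,
    t_end: float,
    affective: Optional[AffectiveState] = None,
    *,
    record_event_log: bool = False,
    weight_snapshot_every: Optional[float] = None,
    histogram_fn=None,
) -> SimulationTrace:
    """One-shot simulation: drain `queue` through a fresh simulator until t_end."""
    if t_end <= 0:
        raise ValueError(f"t_end must be positive, got {t_end}")
    sim = Simulator(
        network,
        affective,
        record_event_log=record_event_log,
        weight_snapshot_every=weight_snapshot_every,
        histogram_fn=histogram_fn,
    )
    # adopt the caller's pre-scheduled events, preserving their order
    while len(queue):
        sim.schedule(queue.pop())
    return sim.run_until(t_end)
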