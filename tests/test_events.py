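"""Event queue ordering, the simulation loop, and rate measurement."""

import itertools

import pytest

from affectnet.affective import AffectiveState
from affectnet.events import (
    Event,
    EventQueue,
    EventType,
    QueueExhausted,
    SimulationTrace,
    Simulator,
    measured_firing_rate,
    run,
    schedule_event,
)

from conftest import build_network


class TestEventQueue:
    def test_pops_in_time_order(self):
        q = EventQueue()
        q.push(Event(5.0, EventType.INPUT_PULSE, neuron=0))
        q.push(Event(3.0, EventType.INPUT_PULSE, neuron=0))
        assert q.pop().time == 3.0
        assert q.pop().time == 5.0

    def test_equal_times_pop_in_insertion_order(self):
        # exhaustive check over all insertion orders of four same-time events
        for perm in itertools.permutations(range(4)):
            q = EventQueue()
            for label in perm:
                q.push(Event(3.0, EventType.INPUT_PULSE, neuron=label))
            popped = [q.pop().neuron for _ in range(4)]
            assert popped == list(perm)

    def test_empty_pop_signals_exhaustion(self):
        with pytest.raises(QueueExhausted):
            EventQueue().pop()

    def test_scheduling_into_the_past_rejected(self):
        q = EventQueue()
        q.push(Event(5.0, EventType.INPUT_PULSE, neuron=0))
        q.pop()
        with pytest.raises(ValueError):
            schedule_event(q, Event(4.0, EventType.INPUT_PULSE, neuron=0))


class TestRun:
    def test_no_events_yields_empty_trace(self, chain):
        trace = run(chain, EventQueue(), t_end=100.0)
        assert trace.firing_events == []

    def test_two_neuron_chain_hand_simulation(self, chain):
        """Pulse at t=0 fires A immediately; its charge packet (weight 1.0,
        distance 1) fires B at t=1."""
        sim = Simulator(chain)
        sim.schedule_pulse(0.0)
        trace = sim.run_until(10.0)
        assert trace.firing_events == [(0.0, 0), (1.0, 1)]

    def test_causality_arrivals_strictly_after_firing(self):
        net = build_network(
            [(0, 0, 0), (0, 0, 3), (0, 4, 0)],
            [(0, 1, 1.0), (0, 2, 1.0), (1, 2, 1.0)],
            input_ids=(0,),
        )
        sim = Simulator(net, record_event_log=True)
        sim.schedule_pulse(0.0)
        sim.run_until(50.0)
        fire_times = {}
        for ev in sim.trace.event_log:
            if ev.type is EventType.NEURON_FIRE:
                fire_times.setdefault(ev.neuron, ev.time)
            if ev.type is EventType.CHARGE_ADDITION and ev.synapse is not None:
                assert ev.time > fire_times[ev.synapse.pre]

    def test_threshold_adjustments_at_exact_window_multiples(self, chain):
        aff = AffectiveState(d=5.0, alpha=0.0, lambda_=0.0, w=10.0)
        sim = Simulator(chain, aff)
        trace = sim.run_until(100.0)
        assert [t for t, _ in trace.rate_series] == pytest.approx(
            [10.0 * k for k in range(1, 11)]
        )

    def test_deterministic_replay_is_bit_identical(self):
        from affectnet.experiments import run_rate_control
        from affectnet.netgen import GenerationParams
        from affectnet.network import GridSpec

        params = GenerationParams(
            n_neurons=50, n_synapses=300, grid=GridSpec(20, 20, 20, 1)
        )
        kwargs = dict(
            genparams=params,
            controller=AffectiveState(d=10.0, w=10.0),
            d_schedule=[(0.0, 10.0)],
            t_end=500.0,
            seed=7,
        )
        a = run_rate_control(**kwargs)
        b = run_rate_control(**kwargs)
        assert a.trace.firing_events == b.trace.firing_events
        assert a.trace.rate_series == b.trace.rate_series
        assert a.network.weights() == b.network.weights()

    def test_unit_interval_firing_count_bounded_by_neuron_count(self):
        """With refractory period 1, no unit-length interval can contain more
        firings than there are neurons, even under saturating drive."""
        n = 10
        positions = [(i, 0, 0) for i in range(n)]
        synapses = [(i, j, 1.0) for i in range(n) for j in range(n) if i != j]
        net = build_network(
            positions, synapses, threshold=-1.0, grid=None, input_ids=(0,)
        )
        sim = Simulator(net)
        for k in range(20):
            sim.schedule_pulse(0.5 * k)  # drive hard
        trace = sim.run_until(30.0)
        times = trace.firing_times()
        for t0 in range(30):
            count = sum(1 for t in times if t0 < t <= t0 + 1)
            assert count <= n

    def test_lowered_threshold_fires_only_on_next_arrival(self, chain):
        """An affective threshold drop below stored charge must not fire a
        neuron by itself; the neuron fires on its next charge arrival."""
        net = chain
        net.neurons[1].charge = 0.4
        aff = AffectiveState(d=100.0, alpha=0.001, lambda_=0.0, w=10.0)
        sim = Simulator(net, aff)
        sim.run_until(40.0)  # thresholds fall to -0.5 with zero firing
        assert net.neurons[1].threshold < 0.4
        assert sim.trace.firing_events == []
        sim.schedule_charge(41.0, 1, 0.01)
        sim.run_until(42.0)
        assert sim.trace.firing_events == [(41.0, 1)]


class TestMeasuredRate:
    @pytest.mark.parametrize(
        "firings, t, w, expected",
        [
            ([1.0, 2.0, 3.0], 10.0, 10.0, 3),
            ([1.0, 2.0, 3.0], 12.0, 10.0, 1),  # half-open window (2, 12] holds {3}
            ([], 10.0, 10.0, 0),
        ],
    )
    def test_window_counts(self, firings, t, w, expected):
        trace = SimulationTrace(firing_events=[(x, 0) for x in firings])
        assert measured_firing_rate(trace, t, w) == expected

    def test_window_before_start_rejected(self):
        with pytest.raises(ValueError):
            measured_firing_rate(SimulationTrace(), 5.0, 10.0)

    def test_matches_brute_force_count(self):
        import numpy as np

        rng = np.random.default_rng(3)
        times = sorted(rng.uniform(0, 100, size=200))
        trace = SimulationTrace(firing_events=[(t, 0) for t in times])
        for t in (10.0, 33.3, 99.9):
            brute = sum(1 for x in times if t - 10.0 < x <= t)
            assert measured_firing_rate(trace, t, 10.0) == brute
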