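"""Neuron/synapse primitives: charge accumulation, firing, geometry."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from affectnet.network import (
    GridSpec,
    add_charge,
    fire_neuron,
    neuron_distance,
)

from conftest import build_network


class TestAddCharge:
    def test_threshold_crossing_fires_and_resets_charge(self, chain):
        chain.neurons[0].charge = 0.3
        out = add_charge(chain, 0, 0.3, time=5.0)
        assert out.fired
        assert out.new_charge == 0.0
        assert chain.neurons[0].charge == 0.0
        assert chain.neurons[0].last_fire_time == 5.0

    def test_refractory_neuron_accumulates_but_does_not_fire(self, chain):
        n = chain.neurons[0]
        n.charge = 0.3
        n.last_fire_time = 4.5  # refractory period 1 covers t=5.0
        out = add_charge(chain, 0, 0.3, time=5.0)
        assert not out.fired
        assert out.new_charge == pytest.approx(0.6)
        assert n.charge == pytest.approx(0.6)

    def test_charge_clamps_at_unit_bound(self, chain):
        n = chain.neurons[0]
        n.charge = 0.9
        n.last_fire_time = 4.5  # refractory, so the clamped charge is retained
        out = add_charge(chain, 0, 0.5, time=5.0)
        assert out.new_charge == 1.0
        n.charge = -0.9
        out = add_charge(chain, 0, -0.5, time=5.1)
        assert out.new_charge == -1.0

    def test_exact_threshold_equality_fires(self, chain):
        chain.neurons[0].charge = 0.2
        out = add_charge(chain, 0, 0.3, time=0.0)
        assert out.fired

    def test_unknown_neuron_rejected(self, chain):
        with pytest.raises(KeyError):
            add_charge(chain, 99, 0.1, 0.0)

    def test_non_finite_amount_rejected(self, chain):
        with pytest.raises(ValueError):
            add_charge(chain, 0, float("nan"), 0.0)

    def test_refiring_allowed_at_exactly_one_refractory_period(self, chain):
        add_charge(chain, 0, 0.6, time=2.0)
        out = add_charge(chain, 0, 0.6, time=3.0)
        assert out.fired


class TestFireNeuron:
    def test_arrival_times_and_amounts_follow_synapses(self):
        net = build_network(
            [(0, 0, 0), (0, 0, 1), (0, 3, 0)],
            [(0, 1, 0.2), (0, 2, -0.4)],
        )
        arrivals = fire_neuron(net, 0, time=10.0)
        by_post = {a.post: a for a in arrivals}
        assert by_post[1].time == pytest.approx(11.0)
        assert by_post[1].amount == pytest.approx(0.2)
        assert by_post[2].time == pytest.approx(13.0)
        assert by_post[2].amount == pytest.approx(-0.4)

    def test_no_outgoing_synapses_yields_empty(self, chain):
        assert fire_neuron(chain, 1, time=0.0) == []

    def test_equal_distances_give_equal_arrival_times(self):
        net = build_network(
            [(0, 0, 0), (0, 0, 2), (0, 2, 0)],
            [(0, 1, 0.5), (0, 2, 0.5)],
        )
        arrivals = fire_neuron(net, 0, time=1.0)
        assert arrivals[0].time == arrivals[1].time == pytest.approx(3.0)

    def test_firing_inside_refractory_is_contract_violation(self, chain):
        chain.neurons[0].last_fire_time = 9.5
        with pytest.raises(RuntimeError):
            fire_neuron(chain, 0, time=10.0)


class TestGeometry:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((0, 0, 0), (0, 0, 1), 1.0),
            ((0, 0, 0), (0, 0, 0), 0.0),
            ((0, 0, 0), (3, 4, 0), 5.0),
        ],
    )
    def test_distance_examples(self, a, b, expected):
        assert neuron_distance(a, b) == pytest.approx(expected)

    @given(
        st.tuples(*[st.integers(-10, 9)] * 3),
        st.tuples(*[st.integers(-10, 9)] * 3),
        st.tuples(*[st.integers(-10, 9)] * 3),
    )
    @settings(deadline=None, max_examples=50)
    def test_distance_is_a_metric(self, a, b, c):
        assert neuron_distance(a, b) == pytest.approx(neuron_distance(b, a))
        assert (neuron_distance(a, b) == 0) == (a == b)
        assert neuron_distance(a, c) <= neuron_distance(a, b) + neuron_distance(b, c) + 1e-9

    def test_grid_membership(self):
        grid = GridSpec(100.0, 100.0, 100.0, 1.0)
        assert grid.contains((-100, 0, 99))
        assert not grid.contains((100, 0, 0))  # right edge is open
        assert not grid.contains((0.5, 0, 0))  # not a multiple of g
        assert grid.sites_per_axis() == 200


class TestValidation:
    def test_duplicate_positions_rejected(self):
        net = build_network([(0, 0, 0), (1, 0, 0)])
        net.neurons[1].position = (0.0, 0.0, 0.0)
        with pytest.raises(ValueError, match="share position"):
            net.validate()

    def test_synapse_distance_must_match_geometry(self):
        net = build_network([(0, 0, 0), (0, 0, 2)], [(0, 1, 0.5)])
        net.synapses[0].distance = 1.0
        with pytest.raises(ValueError, match="distance"):
            net.validate()

    def test_dangling_synapse_rejected(self):
        net = build_network([(0, 0, 0), (0, 0, 2)], [(0, 1, 0.5)])
        net.synapses[0].post = 7
        with pytest.raises(ValueError, match="missing neuron"):
            net.validate()

    def test_hand_built_network_is_valid(self, chain):
        chain.validate()


@given(
    st.lists(
        st.tuples(
            st.floats(-1, 1, allow_nan=False),  # amount
            st.floats(0, 10, allow_nan=False),  # time gap
        ),
        min_size=1,
        max_size=40,
    )
)
@settings(deadline=None, max_examples=100)
def test_firing_history_respects_refractory_and_bounds(events):
    """Random charge sequences never violate charge bounds, the zero-reset
    rule, or the minimum spacing between firings."""
    net = build_network([(0, 0, 0)], threshold=0.3)
    n = net.neurons[0]
    t = 0.0
    fire_times = []
    for amount, gap in events:
        t += gap
        out = add_charge(net, 0, amount, t)
        assert -1.0 <= n.charge <= 1.0
        if out.fired:
            assert n.charge == 0.0
            fire_times.append(t)
    for t0, t1 in zip(fire_times, fire_times[1:]):
        assert t1 - t0 >= n.refractory_period
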