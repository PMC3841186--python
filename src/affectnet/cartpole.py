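"""Bang-bang cart-pole balancing driven by a spiking network.

A cart on a finite track carries an inverted pole; the controller chooses
one of three actions — push left (-10 N), push right (+10 N), or coast
(0 N) — every 0.02 s.  The four-dimensional state (x, x_dot, theta,
theta_dot) is discretized into three ranges per variable and presented to
the network as pulses on 4 of 12 input neurons; after 200 units of network
time the output neuron (of two) with the most firings in that window picks
the force.  An episode ends when the cart leaves the track or the pole
falls past the failure angle.

Physics: the standard single-pole equations of motion (frictionless track,
massless link), integrated with explicit Euler at 0.02 s:

    temp       = (F + m_p * l * theta_dot^2 * sin(theta)) / (m_c + m_p)
    theta_ddot = (g * sin(theta) - cos(theta) * temp)
                 / (l * (4/3 - m_p * cos^2(theta) / (m_c + m_p)))
    x_ddot     = temp - m_p * l * theta_ddot * cos(theta) / (m_c + m_p)
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .affective import AffectiveState
from .events import Simulator
from .evolution import Genome

__all__ = [
    "CartPoleState",
    "PolePhysics",
    "EncodingRanges",
    "step_dynamics",
    "encode_state",
    "decode_action",
    "run_episode",
    "fitness_six",
    "generalization_grid",
    "SIX_START_STATES",
]


@dataclass(slots=True)
class CartPoleState:
    x: float = 0.0  # cart position, m
    x_dot: float = 0.0  # cart velocity, m/s
    theta: float = 0.0  # pole angle from vertical, rad
    theta_dot: float = 0.0  # pole angular velocity, rad/s


@dataclass(slots=True)
class PolePhysics:
    cart_mass: float = 1.0  # kg
    pole_mass: float = 0.1  # kg
    half_length: float = 0.5  # m
    gravity: float = 9.8  # m/s^2
    force_mag: float = 10.0  # N
    dt: float = 0.02  # s, Euler step and decision period
    track_limit: float = 2.4  # m, |x| beyond this is failure
    angle_limit: float = 0.209  # rad (~12 degrees), |theta| beyond this is failure

    def failed(self, state: CartPoleState) -> bool:
        return abs(state.x) > self.track_limit or abs(state.theta) > self.angle_limit


@dataclass(slots=True)
class EncodingRanges:
    """Two cutpoints per state variable define three left-closed ranges.

    Range index is 0 for v < lo, 1 for lo <= v < hi, 2 for v >= hi; the
    active input neuron for variable k with range r is ``3*k + r``.
    """

    x: Tuple[float, float] = (-0.8, 0.8)
    x_dot: Tuple[float, float] = (-0.5, 0.5)
    theta: Tuple[float, float] = (-0.05, 0.05)
    theta_dot: Tuple[float, float] = (-0.2, 0.2)

    def cutpoints(self) -> List[Tuple[float, float]]:
        return [self.x, self.x_dot, self.theta, self.theta_dot]


# Six (x, theta) fitness starting conditions; velocities are zero.
SIX_START_STATES: Tuple[Tuple[float, float], ...] = (
    (-1.5, 0.0),
    (1.5, 0.0),
    (0.0, -0.1),
    (0.0, 0.1),
    (-1.0, 0.05),
    (1.0, -0.05),
)

NETWORK_TIME_PER_DECISION = 200.0  # units of simulation time per control step
EPISODE_CAP = 300.0  # s, the fully-trained criterion per start state


def step_dynamics(
    state: CartPoleState, force: float, physics: PolePhysics = PolePhysics()
) -> CartPoleState:
    """One Euler step of the cart-pole equations under a bang-bang force."""
    if force not in (-physics.force_mag, 0.0, physics.force_mag):
        raise ValueError(f"force must be one of +/-{physics.force_mag} or 0, got {force}")
    m_total = physics.cart_mass + physics.pole_mass
    ml = physics.pole_mass * physics.half_length
    sin_t, cos_t = math.sin(state.theta), math.cos(state.theta)
    temp = (force + ml * state.theta_dot**2 * sin_t) / m_total
    theta_ddot = (physics.gravity * sin_t - cos_t * temp) / (
        physics.half_length * (4.0 / 3.0 - physics.pole_mass * cos_t**2 / m_total)
    )
    x_ddot = temp - ml * theta_ddot * cos_t / m_total
    dt = physics.dt
    return CartPoleState(
        x=state.x + dt * state.x_dot,
        x_dot=state.x_dot + dt * x_ddot,
        theta=state.theta + dt * state.theta_dot,
        theta_dot=state.theta_dot + dt * theta_ddot,
    )


def encode_state(
    state: CartPoleState, ranges: EncodingRanges = EncodingRanges()
) -> List[int]:
    """Active input-neuron indices (exactly 4 of 12), one per state variable."""
    values = (state.x, state.x_dot, state.theta, state.theta_dot)
    active = []
    for k, (v, (lo, hi)) in enumerate(zip(values, ranges.cutpoints())):
        r = 0 if v < lo else 1 if v < hi else 2
        active.append(3 * k + r)
    return active


def decode_action(count_neg: int, count_pos: int, force_mag: float = 10.0) -> float:
    """Majority vote of the two output neurons; ties and silence coast (0 N)."""
    if count_neg < 0 or count_pos < 0:
        raise ValueError("firing counts must be nonnegative")
    if count_neg > count_pos:
        return -force_mag
    if count_pos > count_neg:
        return force_mag
    return 0.0


def _count_window_firings(
    firing_events: Sequence[Tuple[float, int]], start_idx: int, neuron_ids: Sequence[int]
) -> Dict[int, int]:
    counts = {nid: 0 for nid in neuron_ids}
    for _, nid in firing_events[start_idx:]:
        if nid in counts:
            counts[nid] += 1
    return counts


def run_episode(
    genome: Genome,
    affective_on: bool = True,
    initial: CartPoleState = CartPoleState(),
    max_time: float = EPISODE_CAP,
    *,
    physics: PolePhysics = PolePhysics(),
    ranges: EncodingRanges = EncodingRanges(),
    controller: Optional[AffectiveState] = None,
) -> float:
    """Balance time (s) achieved by a genome's network from one start state.

    The network carries its charges and queued events across decision
    windows within the episode, and is reset (fresh copy of the genome's
    network) at episode start.  With ``affective_on`` the controller tracks
    the genome's evolved desired firing rate; otherwise thresholds stay
    frozen at their trained values.
    """
    net = copy.deepcopy(genome.network)
    net.reset_dynamic_state()
    if len(net.input_neuron_ids) != 12 or len(net.output_neuron_ids) != 2:
        raise ValueError("cart-pole networks need 12 input and 2 output neurons")
    aff = None
    if affective_on:
        aff = replace(controller) if controller is not None else AffectiveState()
        aff.d = genome.desired_rate
    sim = Simulator(net, aff)
    out_neg, out_pos = net.output_neuron_ids

    state = replace(initial)
    balanced = 0.0
    net_time = 0.0
    while balanced < max_time and not physics.failed(state):
        for idx in encode_state(state, ranges):
            sim.schedule_pulse(net_time, net.input_neuron_ids[idx])
        window_start = len(sim.trace.firing_events)
        net_time += NETWORK_TIME_PER_DECISION
        sim.run_until(net_time)
        counts = _count_window_firings(
            sim.trace.firing_events, window_start, (out_neg, out_pos)
        )
        force = decode_action(counts[out_neg], counts[out_pos], physics.force_mag)
        state = step_dynamics(state, force, physics)
        balanced += physics.dt
    return min(balanced, max_time)


def fitness_six(
    genome: Genome,
    affective_on: bool = True,
    *,
    start_states: Sequence[Tuple[float, float]] = SIX_START_STATES,
    cap: float = EPISODE_CAP,
    physics: PolePhysics = PolePhysics(),
    ranges: EncodingRanges = EncodingRanges(),
) -> float:
    """Mean balance time over the six standard (x, theta) starting conditions."""
    times = [
        run_episode(
            genome,
            affective_on,
            CartPoleState(x=x, theta=theta),
            max_time=cap,
            physics=physics,
            ranges=ranges,
        )
        for x, theta in start_states
    ]
    return float(np.mean(times))


def generalization_grid(
    genome: Genome,
    seed: int = 0,
    affective_on: bool = True,
    *,
    x_start: float = -2.2,
    x_step: float = 0.2,
    n_x: int = 21,
    theta_start: float = -0.15,
    theta_step: float = 0.05,
    n_theta: int = 6,
    starts_per_cell: int = 10,
    cap: float = EPISODE_CAP,
    physics: PolePhysics = PolePhysics(),
) -> "np.ndarray":
    """Per-cell mean balance time over a 21 x 6 grid of (x, theta) ranges.

    Each cell [x, x+0.2) x [theta, theta+0.05) receives ``starts_per_cell``
    uniform random starting states (velocities zero); with the defaults that
    is 126 cells and 1260 episodes.  Returns an (n_x, n_theta) array.
    """
    rng = np.random.default_rng(seed)
    result = np.zeros((n_x, n_theta))
    for i in range(n_x):
        for j in range(n_theta):
            x_lo = x_start + i * x_step
            th_lo = theta_start + j * theta_step
            times = []
            for _ in range(starts_per_cell):
                init = CartPoleState(
                    x=float(rng.uniform(x_lo, x_lo + x_step)),
                    theta=float(rng.uniform(th_lo, th_lo + theta_step)),
                )
                times.append(
                    run_episode(genome, affective_on, init, max_time=cap, physics=physics)
                )
            result[i, j] = np.mean(times)
    return result
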