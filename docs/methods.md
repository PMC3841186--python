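# Methods

This note documents the model implemented by `affectnet`, the defaults and
the reasoning behind them, what the synthetic inputs do and do not emulate,
and the numerical choices a user should know before trusting or extending
the results.

## Network model

Neurons occupy distinct sites of a 3-D grid whose coordinates are integral
multiples of the granularity `g` in `[-M, M)` per axis (defaults M = 100,
g = 1: 200 values per axis, 8×10⁶ sites). Each neuron carries a charge and
a threshold, both clamped to [−1, 1], and a refractory period of 1 time
unit. Synapses are directed, weighted (clamped to [−1, 1]) edges whose
propagation delay equals the Euclidean distance between their endpoints:
one unit of simulation time is defined as the time charge takes to travel
one grid unit, and there is no myelination, so equal distances always give
equal delays. The model is deliberately minimal — no charge decay (none is
part of the model), no conductances, no axonal branching — trading neuron
complexity for network complexity.

Firing is evaluated **only at charge-arrival times**. When a packet lands,
the target's charge is incremented (then clamped); if the result reaches
the threshold (ties fire) and the neuron is outside its refractory period,
it fires: charge resets to zero and one packet per outgoing synapse is
scheduled. Inside the refractory period charge accumulates but the neuron
cannot fire. A consequence worth emphasizing: a network-wide threshold
drop never fires anyone by itself — each neuron must receive its next
packet first.

## Discrete-event engine

Events (charge additions, firings, threshold adjustments, input pulses,
desired-rate changes, and application-level output observations) live in a
priority queue ordered by (time, insertion sequence). Equal-time events
process in insertion order, which makes every run a pure function of the
network and the seeds; the test suite asserts bit-identical replay. Event
times are continuous reals — distances, and hence delays, need not be
integral. Internally the simulator keeps heap entries as plain tuples; the
charge-arrival handler is the hot path (the headline run processes ~3×10⁷
events) and is inlined, with the object-level operations
(`add_charge`, `fire_neuron`, `apply_ltp`, `apply_ltd`) kept as the
reference semantics and exercised against the engine in tests.

Input pulses deliver +1.0 charge (clamped) to the designated input neuron,
which fires it whenever it is outside its refractory period, since
thresholds never exceed 1.

## Affective controller

Every `w = 10` time units the controller reads the firing count of the
last window, converts it to a rate `f` in **firings per unit time**
(count/w), and broadcasts

    e = f − d,   ē ← λ·ē + (1−λ)·e,   Δθ = α·ē

to every neuron, skipping any neuron the change would push outside [−1, 1].
The per-unit-time convention matters: with a refractory period of 1 the
rate is bounded by the neuron count (1000 by default), so the error
magnitude is bounded by 1000 and α = 0.001 bounds a single threshold
change to magnitude 1. The sign convention (excess firing raises
thresholds) is what produces the observed monotone relation between the
setpoint and the settled threshold. λ = 0 reduces the smoothed update to
the simple proportional law exactly — both controllers are one code path —
and the suite verifies the recorded trajectory against an independently
reconstructed proportional update. ē starts at 0; the per-neuron (rather
than global) bound skip is equivalent in the homogeneous-threshold
experiments and remains well defined when evolution makes thresholds
heterogeneous.

## Plasticity

LTP credits exactly the synapse whose packet pushed the target over
threshold (earlier contributing packets get nothing — the rule is
event-local and unambiguous); LTD hits a synapse whose packet lands during
the target's refractory period, regardless of packet sign. Both move the
weight by the fixed step 0.001 (clamped at ±1) and share a single
per-synapse refractory clock (default 10 time units): any accepted event —
including one where clamping leaves the weight numerically unchanged —
starts the dead time for both processes. With plasticity disabled all
weights are provably constant.

## Synthetic inputs (what they emulate, what they don't)

The generator draws the study conditions directly: 1000 neurons at distinct
uniform grid sites, 10000 distinct directed synapse pairs, initial
thresholds 0.5, weights i.i.d. uniform on [−1, 1], a single uniformly
chosen input neuron, and exponential input-pulse intervals with mean rate
0.1 per unit time. Spatial proximity bias is implemented as
P(i→j) ∝ exp(−dist(i,j)/τ) with τ = 20 grid units (sampled without
replacement via Gumbel top-k), τ chosen as the typical nearest-neighbour
spacing at this density so that "nearby neurons are more likely to be
connected" without making the graph near-local. The true connectivity
kernel of the original study is not published; quantitative steady-state
properties (oscillation amplitude, settled threshold values) are somewhat
sensitive to it, and τ is exposed as a parameter for exactly that reason.
Passing tests therefore demonstrate the behavior of *this* family of
random recurrent networks, not of any particular biological connectome.

## Rate-control experiments and metrics

`run_rate_control` splits the run seed into independent network and pulse
streams, injects the desired-rate schedule as events, and scores each
schedule segment:

- **settling time** — earliest window-end time from which every later
  window in the segment stays within ±50 firings per unit time of d
  (evaluated on the window-level measurements);
- **percent overshoot** — max excess above d as a percent of d, floored
  at 0;
- **oscillation period** — mean spacing of upward crossings of d before
  settling (undefined below two crossings).

Weight histograms use 20 left-closed bins of width 0.1 on [−1, 1], the
last bin closed.

## Problem sizes used by the test suite

The flagship tracking run uses the full default conditions (1000 neurons,
10000 synapses, d = 300, 10000 time units — a few minutes of CPU). The
qualitative trend checks (threshold-vs-setpoint monotonicity, weight
pile-up into the extreme bins at high rate, settling under slow vs fast
plasticity) run on one-fifth-scale networks: 200 neurons, 1500 synapses on
an M = 50 grid with setpoints scaled by the same factor, horizons
1500–10000 units. These reproduce the full-scale trends (verified against
full-scale spot runs during development) at a fraction of the cost; the
weight-pile-up check keeps the full 10000-unit horizon because the
phenomenon needs total drift capacity t·step/refractory ≈ 1 to move
weights across the [−1, 1] range.

## Observed steady-state behavior and a known limitation

With the default plasticity (step 0.001, refractory 10 — the same time
scale as the controller) the closed loop settles at d = 300 within a few
hundred time units but retains a small limit-cycle: across seeds the
maximum window deviation over the final 2000 units is ≈ 50–60 firings per
unit time, i.e. the ±50 settling band is held only marginally and an
occasional window exceeds it. Slowing plasticity (refractory 50) or
disabling it tightens the band substantially — consistent with the
separation-of-time-scales picture in which learning must run slower than
control. Users who need strict band-keeping at refractory 10 should treat
the band as ≈ ±60 for this kernel, or lower the plasticity step.

## Evolutionary algorithm

The published operator details and parameter tables for the trainer are
not available; the implementation uses documented stand-ins: population
50, tournament 5, crossover 0.9, mutation 0.9, one elite, uniform
mutation-type weights, all configurable. Crossover splits both parents by
a random axis-aligned plane and exchanges sides; designated input/output
neurons are always inherited from the same parent (preserving the 12/2
interface of the cart-pole task), position collisions resolve
first-writer-wins, and a synapse with one surviving endpoint is reattached
to the nearest surviving neuron. The desired-rate gene behaviors are as
specified: children take the parents' average d; one mutation resamples d
uniformly on [0, n_neurons]. Elitism makes best-ever fitness nondecreasing
(asserted on a deterministic toy fitness).

## Cart-pole benchmark

Physics uses the standard single-pole equations (cart 1.0 kg, pole 0.1 kg,
half-length 0.5 m, g = 9.8 m/s², force ±10 N, Euler at 0.02 s, failure at
|x| > 2.4 m or |θ| > 0.209 rad), as the original appendix is unavailable;
all constants are configurable. Encoding cutpoints default to x: ±0.8 m,
ẋ: ±0.5 m/s, θ: ±0.05 rad, θ̇: ±0.2 rad/s with left-closed intervals; the
six fitness starts default to (±1.5, 0), (0, ±0.1), (±1.0, ∓0.05) with
zero velocities; the generalization grid spans 21 x-cells of width 0.2
from −2.2 and 6 θ-cells of width 0.05 from −0.15 (126 cells × 10 random
starts). Ties between the two output neurons, and silence, coast (0 N).
Network charges and queued events persist across the 200-unit decision
windows within an episode and reset between episodes. Full evolutionary
training to the 300 s × six-condition criterion is an overnight job and is
exposed through `affectnet evolve`, not exercised by the default suite;
the suite validates the physics, coding rules, episode loop and the EA
machinery at desk scale.

## Numerical notes

- Tie at charge == threshold fires; boundary encoding intervals are
  left-closed; decode ties coast — all chosen once and documented.
- Threshold adjustments occur at exact multiples of w; a firing at exactly
  a window boundary is counted in the earlier window only if its event
  was inserted before the adjustment event (in practice, window-boundary
  firings have measure zero under continuous delays).
- Seeds: every public entry point takes one integer seed, split via
  `numpy.random.SeedSequence` into independent streams (network, pulses);
  derived seeds stay below 2³¹.
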