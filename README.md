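# affectnet

Discrete-event simulation of spiking artificial neural networks coupled to a
simple *affective system*: a feedback controller, analogous to limbic
neuromodulation, that steers the ensemble firing rate of the network by
broadcasting threshold changes to every neuron. The package also provides
LTP/LTD synaptic plasticity with plasticity refractory periods, an
evolutionary trainer that evolves network topology together with the
desired-firing-rate trait, and a bang-bang cart-pole benchmark driven by the
evolved networks.

It is intended for computational-neuroscience and neuroevolution
experiments on firing-rate homeostasis: how a proportional neuromodulatory
controller interacts with a recurrent spiking substrate and with synaptic
learning rules operating on a similar time scale.

## Model

Neurons sit on a 3-D integer grid and accumulate charge; charge and
thresholds are bounded to [-1, 1]. A neuron whose clamped charge reaches
its threshold outside its refractory period (1 time unit) fires, resets its
charge to zero, and sends one packet per outgoing synapse; the packet
carries the synapse weight and arrives after a delay equal to the Euclidean
distance between the endpoints (charge travels one grid unit per unit of
simulation time). If the packet that arrives makes the target fire, that
synapse is potentiated by a fixed step (LTP, +0.001); if it arrives during
the target's refractory period the synapse is depressed (LTD, −0.001); a
per-synapse refractory period (default 10) limits how often either can act.

Every `w` time units (default 10) the affective system measures the firing
rate f(t) — spikes in the last window divided by `w`, in firings per unit
time — and updates all thresholds:

    e(t)  = f(t) − d(t)
    ē(t)  = λ·ē(t−w) + (1−λ)·e(t)
    Δθ(t) = α·ē(t)            (λ = 0 gives the simple proportional system)

with gain α = 0.001 and decay λ ∈ [0, 1). The change is skipped for any
neuron it would push outside [−1, 1]. Excess firing raises thresholds and
suppresses activity; insufficient firing lowers them.

For training, genomes (a network plus its desired rate d) evolve under
tournament selection, spatial-plane crossover (children receive the
parents' average d) and a mutation menu that includes resampling d
uniformly on [0, n_neurons]. The cart-pole task encodes (x, ẋ, θ, θ̇) into
12 input neurons (3 ranges each), runs the network 200 time units per
0.02 s physics step, and applies −10 N / 0 / +10 N by majority vote of two
output neurons.

## Worked example

```python
from affectnet.affective import AffectiveState
from affectnet.experiments import run_rate_control

result = run_rate_control(
    controller=AffectiveState(d=300.0, alpha=0.001, lambda_=0.0, w=10.0),
    d_schedule=[(0.0, 300.0)],
    t_end=3000.0,
    seed=1,
)
seg = result.segments[0]
print(f"settling time      : {seg.settling_time}")
print(f"percent overshoot  : {seg.percent_overshoot:.1f}")
print(f"final threshold    : {result.final_threshold:.3f}")
print(f"last window rates  : {[r for _, r in result.trace.rate_series[-5:]]}")
```

Output:

```
settling time      : 330.0
percent overshoot  : 74.8
final threshold    : 0.236
last window rates  : [301.0, 298.0, 293.1, 297.5, 299.7]
```

A freshly generated 1000-neuron, 10000-synapse network starts silent, the
controller drops the shared threshold until recurrent firing ignites,
overshoots (peak ≈ 525 firings per unit time, 74.8% above the setpoint),
and settles at t = 330 onto the desired 300 firings per unit time, which
the window measurements then track within a few units. The settled
threshold (0.236) is the level at which the recurrent dynamics
self-sustain exactly that rate; higher setpoints settle at lower
thresholds.

The same experiment is available from a shell:

```sh
affectnet rate-control --seed 1 --config cfg.yaml --out out/
```

which writes firing/rate/threshold CSVs, a metrics summary JSON, and a
replay manifest. Further subcommands: `generate`, `simulate`, `sweep`,
`evolve`, `cartpole-eval`, `generalize`.

## Layout

- `affectnet.network` — neuron/synapse state, grid geometry, firing rules
- `affectnet.events` — event queue and the discrete-event simulation loop
- `affectnet.plasticity` — LTP/LTD updates and their refractory gate
- `affectnet.affective` — the threshold controller
- `affectnet.netgen` — seeded random networks and pulse trains
- `affectnet.experiments` — rate-control harness and control metrics
- `affectnet.evolution` — tournament EA over network genomes
- `affectnet.cartpole` — physics, encoding/decoding, episodes, fitness
- `affectnet.io` / `affectnet.cli` — JSON/CSV serialization and the CLI

See `docs/methods.md` for modeling assumptions, parameter defaults, and
known limitations.
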