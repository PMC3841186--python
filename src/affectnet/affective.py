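"""The affective system: a proportional firing-rate controller.

Every ``w`` units of simulation time the controller compares the network's
measured firing rate f(t) with the desired rate d(t) supplied by the
environment and broadcasts a uniform threshold change to every neuron:

    e(t)      = f(t) - d(t)                       (firing-rate error)
    e_bar(t)  = lambda * e_bar(t-w) + (1 - lambda) * e(t)
    d_theta(t) = alpha * e(t)        (simple system,  lambda = 0)
    d_theta(t) = alpha * e_bar(t)    (complex system, lambda > 0)

Sign convention: excess firing (f > d) yields a positive error and hence a
threshold increase, which suppresses firing.  The two systems coincide when
lambda = 0, so both are implemented as the single update above.

Units: f and d are firings per unit of simulation time; f is the firing
count over the last window divided by w.  Since the refractory period is 1,
f is bounded by the neuron count (1000 in the default network), so with
alpha = 0.001 the error bound of 1000 bounds any single threshold change
to magnitude one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .network import CHARGE_MAX, CHARGE_MIN, NetworkModel

__all__ = [
    "AffectiveState",
    "firing_rate_error",
    "smoothed_error",
    "threshold_delta",
    "apply_threshold_change",
]


@dataclass(slots=True)
class AffectiveState:
    """Controller parameters plus its one piece of memory, the smoothed error."""

    d: float = 300.0  # desired firing rate, firings per unit time
    alpha: float = 0.001  # proportional gain
    lambda_: float = 0.0  # error decay rate; 0 = simple system
    w: float = 10.0  # window length / update period, simulation-time units
    smoothed_error: float = 0.0
    last_update_time: Optional[float] = None

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError(f"window length must be positive, got {self.w}")
        if not (0.0 <= self.lambda_ < 1.0):
            raise ValueError(f"decay rate must be in [0, 1), got {self.lambda_}")

    def update(self, measured_rate: float, time: float) -> float:
        """Consume one window's measured rate; return the threshold change."""
        e = firing_rate_error(measured_rate, self.d)
        self.smoothed_error = smoothed_error(self.smoothed_error, e, self.lambda_)
        self.last_update_time = time
        return threshold_delta(self.smoothed_error, self.alpha)


def firing_rate_error(f: float, d: float) -> float:
    """e = f - d: positive when the network fires above the desired rate."""
    if f < 0:
        raise ValueError(f"measured rate must be nonnegative, got {f}")
    return f - d


def smoothed_error(prev: float, e: float, lambda_: float) -> float:
    """Geometrically averaged error: e_bar' = lambda*e_bar + (1-lambda)*e."""
    if not (0.0 <= lambda_ < 1.0):
        raise ValueError(f"decay rate must be in [0, 1), got {lambda_}")
    return lambda_ * prev + (1.0 - lambda_) * e


def threshold_delta(err: float, alpha: float) -> float:
    """Proportional control law: d_theta = alpha * err."""
    return alpha * err


def apply_threshold_change(network: NetworkModel, delta: float) -> NetworkModel:
    """Shift every neuron's threshold by `delta`.

    The change is skipped for any neuron whose shifted threshold would leave
    [-1, 1]; that neuron's threshold is left unchanged.  With homogeneous
    initial thresholds this keeps all thresholds identical throughout.
    """
    if delta == 0.0:
        return network
    for n in network.neurons.values():
        nt = n.threshold + delta
        if CHARGE_MIN <= nt <= CHARGE_MAX:
            n.threshold = nt
    return network
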