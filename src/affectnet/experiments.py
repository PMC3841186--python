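"""Rate-control experiments and their control-performance metrics.

``run_rate_control`` wires a generated network, the exogenous pulse train,
the affective controller and plasticity into one simulation driven by a
desired-rate schedule, and summarizes each schedule segment with settling
time, percent overshoot and oscillation period.  A segment is *settled*
from the earliest window measurement after which the rate never again
leaves the +/-50 band around the desired rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .affective import AffectiveState
from .events import SimulationTrace, Simulator
from .netgen import GenerationParams, generate_network, input_pulse_times
from .network import NetworkModel

__all__ = [
    "SETTLING_TOLERANCE",
    "RateControlResult",
    "SegmentMetrics",
    "run_rate_control",
    "settling_time",
    "percent_overshoot",
    "oscillation_period",
    "weight_histogram",
    "HISTOGRAM_EDGES",
]

SETTLING_TOLERANCE = 50.0  # firings per unit time; the +/- band defining "settled"
DEFAULT_PULSE_RATE = 0.1  # pulses per unit time

# 20 bins of width 0.1 on [-1, 1]; all left-closed, the last bin closed on both ends
HISTOGRAM_EDGES = np.linspace(-1.0, 1.0, 21)


def weight_histogram(weights: Sequence[float]) -> np.ndarray:
    """20-bin histogram of synapse weights over [-1, 1]."""
    arr = np.asarray(weights, dtype=float)
    if arr.size and (arr.min() < -1.0 or arr.max() > 1.0):
        raise ValueError("weights outside [-1, 1]")
    counts, _ = np.histogram(arr, bins=HISTOGRAM_EDGES)
    return counts


def _series_in_window(
    rate_series: Sequence[Tuple[float, float]], t_start: float, t_stop: float
) -> List[Tuple[float, float]]:
    return [(t, r) for t, r in rate_series if t_start < t <= t_stop]


def settling_time(
    trace_or_series, d: float, tol: float = SETTLING_TOLERANCE
) -> Optional[float]:
    """Earliest window-end time from which |rate - d| <= tol holds to the end.

    Returns None ("unsettled") when the final measurement itself violates
    the band.  Accepts either a SimulationTrace or a raw (time, rate) series.
    """
    series = _coerce_series(trace_or_series)
    if not series:
        raise ValueError("empty rate series")
    settle: Optional[float] = None
    for t, r in series:
        if abs(r - d) > tol:
            settle = None
        elif settle is None:
            settle = t
    return settle


def percent_overshoot(trace_or_series, d: float) -> float:
    """Maximum excess of the measured rate above d, as a percent of d (>= 0)."""
    series = _coerce_series(trace_or_series)
    if not series:
        raise ValueError("empty rate series")
    peak = max(r for _, r in series)
    return max(0.0, 100.0 * (peak - d) / d)


def oscillation_period(trace_or_series, d: float) -> Optional[float]:
    """Mean spacing of successive upward crossings of d before settling.

    None when there are fewer than two upward crossings ("no oscillation",
    e.g. a monotone approach).
    """
    series = _coerce_series(trace_or_series)
    settle = settling_time(series, d, SETTLING_TOLERANCE)
    pre = [(t, r) for t, r in series if settle is None or t <= settle]
    crossings = [
        t
        for (t0, r0), (t, r) in zip(pre, pre[1:])
        if r0 < d <= r
    ]
    if len(crossings) < 2:
        return None
    gaps = np.diff(crossings)
    return float(np.mean(gaps))


def _coerce_series(trace_or_series) -> List[Tuple[float, float]]:
    if isinstance(trace_or_series, SimulationTrace):
        return list(trace_or_series.rate_series)
    return list(trace_or_series)


@dataclass(slots=True)
class SegmentMetrics:
    t_start: float
    t_stop: float
    desired_rate: float
    settling_time: Optional[float]  # absolute time; None = unsettled
    percent_overshoot: float
    oscillation_period: Optional[float]

    @property
    def settled(self) -> bool:
        return self.settling_time is not None


@dataclass
class RateControlResult:
    trace: SimulationTrace
    network: NetworkModel
    segments: List[SegmentMetrics] = field(default_factory=list)
    final_threshold: float = 0.0
    final_histogram: Optional[np.ndarray] = None

    @property
    def settled_fraction(self) -> float:
        return sum(s.settled for s in self.segments) / len(self.segments)


def run_rate_control(
    genparams: Optional[GenerationParams] = None,
    controller: Optional[AffectiveState] = None,
    d_schedule: Sequence[Tuple[float, float]] = ((0.0, 300.0),),
    t_end: float = 10000.0,
    seed: int = 0,
    *,
    network: Optional[NetworkModel] = None,
    pulse_rate: float = DEFAULT_PULSE_RATE,
    weight_snapshot_every: Optional[float] = None,
) -> RateControlResult:
    """Run one rate-controlled simulation and score each schedule segment.

    `seed` is split deterministically into independent streams for the
    network realization and the pulse train.  Pass ``controller=None`` for
    the no-affective control run (thresholds stay fixed).  A pre-built
    `network` overrides `genparams`.
    """
    schedule = sorted(d_schedule)
    if schedule and schedule[-1][0] >= t_end:
        raise ValueError("schedule change times must precede t_end")
    net_seed, pulse_seed = _split_seed(seed)
    if network is None:
        net = generate_network(genparams or GenerationParams(), net_seed)
    else:
        net = network

    aff = replace(controller) if controller is not None else None
    if aff is not None and schedule:
        aff.d = schedule[0][1]

    sim = Simulator(
        net,
        aff,
        weight_snapshot_every=weight_snapshot_every,
        histogram_fn=lambda w: weight_histogram(w).tolist(),
    )
    sim.schedule_pulses(input_pulse_times(pulse_rate, t_end, pulse_seed))
    for t, d in schedule[1:]:
        sim.schedule_desired_rate(t, d)
    if aff is None and schedule:
        sim.trace.desired_series.append((0.0, schedule[0][1]))
    trace = sim.run_until(t_end)

    result = RateControlResult(
        trace=trace,
        network=net,
        final_threshold=net.mean_threshold(),
        final_histogram=weight_histogram(net.weights()),
    )
    if aff is not None:
        bounds = [t for t, _ in schedule] + [t_end]
        for (t0, d), t1 in zip(schedule, bounds[1:]):
            seg = _series_in_window(trace.rate_series, t0, t1)
            if not seg:
                continue
            result.segments.append(
                SegmentMetrics(
                    t_start=t0,
                    t_stop=t1,
                    desired_rate=d,
                    settling_time=settling_time(seg, d),
                    percent_overshoot=percent_overshoot(seg, d),
                    oscillation_period=oscillation_period(seg, d),
                )
            )
    return result


def _split_seed(seed: int) -> Tuple[int, int]:
    state = np.random.SeedSequence(seed).generate_state(2, dtype=np.uint32)
    return int(state[0] % 2**31), int(state[1] % 2**31)
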