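"""LTP/LTD weight updates with a per-synapse plasticity refractory period.

Long-term potentiation raises a synapse's weight by a fixed step when the
charge it delivered made the postsynaptic neuron fire; long-term depression
lowers it by the same step when the charge arrived during the postsynaptic
neuron's refractory period.  Both share a single per-synapse refractory
clock that rejects any change arriving sooner than ``refractory`` time
units after the previous accepted change, which keeps weight dynamics on a
slower time scale than the firing dynamics.  Weights clamp at +/-1.
"""

from __future__ import annotations

from .network import CHARGE_MAX, CHARGE_MIN, PlasticityParams, SynapseState

__all__ = ["PlasticityParams", "apply_ltp", "apply_ltd"]


def _eligible(synapse: SynapseState, time: float, params: PlasticityParams) -> bool:
    last = synapse.last_plasticity_time
    return last is None or (time - last) >= params.refractory


def apply_ltp(synapse: SynapseState, time: float, params: PlasticityParams) -> float:
    """Potentiate: weight += step (clamped at +1), gated by the refractory clock."""
    if _eligible(synapse, time, params):
        synapse.weight = min(synapse.weight + params.step, CHARGE_MAX)
        synapse.last_plasticity_time = time
    return synapse.weight


def apply_ltd(synapse: SynapseState, time: float, params: PlasticityParams) -> float:
    """Depress: weight -= step (clamped at -1), gated by the refractory clock."""
    if _eligible(synapse, time, params):
        synapse.weight = max(synapse.weight - params.step, CHARGE_MIN)
        synapse.last_plasticity_time = time
    return synapse.weight
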