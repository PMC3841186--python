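import pytest

from affectnet.network import (
    GridSpec,
    NetworkModel,
    NeuronState,
    PlasticityParams,
    SynapseState,
    neuron_distance,
)


def build_network(
    positions,
    synapses=(),
    threshold=0.5,
    grid=None,
    plasticity=None,
    input_ids=(),
    output_ids=(),
):
    """Hand-build a small network: positions is a list of (x, y, z),
    synapses a list of (pre, post, weight)."""
    grid = grid or GridSpec(10.0, 10.0, 10.0, 1.0)
    neurons = {
        i: NeuronState(
            id=i,
            position=tuple(float(c) for c in pos),
            threshold=threshold,
            is_input=i in input_ids,
            is_output=i in output_ids,
        )
        for i, pos in enumerate(positions)
    }
    syn = [
        SynapseState(
            pre=a,
            post=b,
            weight=float(w),
            distance=neuron_distance(neurons[a].position, neurons[b].position),
        )
        for a, b, w in synapses
    ]
    net = NetworkModel(
        neurons=neurons,
        synapses=syn,
        grid=grid,
        plasticity=plasticity or PlasticityParams(),
        input_neuron_ids=list(input_ids),
        output_neuron_ids=list(output_ids),
    )
    net.rebuild_index()
    return net


@pytest.fixture
def chain():
    """Two neurons one unit apart, A -> B with weight 1.0, A is the input."""
    return build_network(
        [(0, 0, 0), (0, 0, 1)],
        [(0, 1, 1.0)],
        input_ids=(0,),
    )
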