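"""Network serialization (JSON), trace export (CSV) and run configuration.

The network JSON schema is flat and lossless: floating-point fields
round-trip exactly through Python's repr-based JSON encoding.

.. code-block:: json

    {
      "grid": {"mx": 100.0, "my": 100.0, "mz": 100.0, "g": 1.0},
      "plasticity": {"step": 0.001, "refractory": 10.0, "enabled": true},
      "neurons": [{"id": 0, "position": [x, y, z], "threshold": 0.5,
                   "charge": 0.0, "refractory_period": 1.0,
                   "is_input": false, "is_output": false}],
      "synapses": [{"pre": 0, "post": 1, "weight": 0.25, "distance": 3.0}],
      "input_neuron_ids": [17],
      "output_neuron_ids": []
    }
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional, Tuple, Union

import yaml

from .events import SimulationTrace
from .network import (
    GridSpec,
    NetworkModel,
    NeuronState,
    PlasticityParams,
    SynapseState,
)

__all__ = [
    "save_network",
    "load_network",
    "network_to_dict",
    "network_from_dict",
    "write_trace",
    "RunConfig",
    "load_config",
]

PathLike = Union[str, Path]


class SchemaError(ValueError):
    """A parse failure that names the offending JSON path."""


def network_to_dict(network: NetworkModel) -> Dict[str, Any]:
    return {
        "grid": {
            "mx": network.grid.mx,
            "my": network.grid.my,
            "mz": network.grid.mz,
            "g": network.grid.g,
        },
        "plasticity": {
            "step": network.plasticity.step,
            "refractory": network.plasticity.refractory,
            "enabled": network.plasticity.enabled,
        },
        "neurons": [
            {
                "id": n.id,
                "position": list(n.position),
                "threshold": n.threshold,
                "charge": n.charge,
                "refractory_period": n.refractory_period,
                "is_input": n.is_input,
                "is_output": n.is_output,
            }
            for n in network.neurons.values()
        ],
        "synapses": [
            {"pre": s.pre, "post": s.post, "weight": s.weight, "distance": s.distance}
            for s in network.synapses
        ],
        "input_neuron_ids": list(network.input_neuron_ids),
        "output_neuron_ids": list(network.output_neuron_ids),
    }


def _need(obj: Dict[str, Any], key: str, where: str) -> Any:
    if key not in obj:
        raise SchemaError(f"missing key '{key}' at {where}")
    return obj[key]


def network_from_dict(data: Dict[str, Any]) -> NetworkModel:
    if not isinstance(data, dict):
        raise SchemaError("top-level document is not an object")
    g = _need(data, "grid", "$")
    grid = GridSpec(
        mx=float(_need(g, "mx", "$.grid")),
        my=float(_need(g, "my", "$.grid")),
        mz=float(_need(g, "mz", "$.grid")),
        g=float(_need(g, "g", "$.grid")),
    )
    p = _need(data, "plasticity", "$")
    plasticity = PlasticityParams(
        step=float(_need(p, "step", "$.plasticity")),
        refractory=float(_need(p, "refractory", "$.plasticity")),
        enabled=bool(p.get("enabled", True)),
    )
    neurons: Dict[int, NeuronState] = {}
    for i, nd in enumerate(_need(data, "neurons", "$")):
        where = f"$.neurons[{i}]"
        nid = int(_need(nd, "id", where))
        pos = _need(nd, "position", where)
        if len(pos) != 3:
            raise SchemaError(f"position at {where} must have 3 coordinates")
        neurons[nid] = NeuronState(
            id=nid,
            position=(float(pos[0]), float(pos[1]), float(pos[2])),
            threshold=float(_need(nd, "threshold", where)),
            charge=float(nd.get("charge", 0.0)),
            refractory_period=float(nd.get("refractory_period", 1.0)),
            is_input=bool(nd.get("is_input", False)),
            is_output=bool(nd.get("is_output", False)),
        )
    synapses = []
    for i, sd in enumerate(_need(data, "synapses", "$")):
        where = f"$.synapses[{i}]"
        synapses.append(
            SynapseState(
                pre=int(_need(sd, "pre", where)),
                post=int(_need(sd, "post", where)),
                weight=float(_need(sd, "weight", where)),
                distance=float(_need(sd, "distance", where)),
            )
        )
    net = NetworkModel(
        neurons=neurons,
        synapses=synapses,
        grid=grid,
        plasticity=plasticity,
        input_neuron_ids=[int(i) for i in data.get("input_neuron_ids", [])],
        output_neuron_ids=[int(i) for i in data.get("output_neuron_ids", [])],
    )
    net.rebuild_index()
    return net


def save_network(network: NetworkModel, path: PathLike) -> None:
    Path(path).write_text(json.dumps(network_to_dict(network)))


def load_network(path: PathLike) -> NetworkModel:
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path} is not valid JSON: {exc}") from exc
    return network_from_dict(data)


# ----------------------------------------------------------------------
# trace export


def write_trace(trace: SimulationTrace, out_dir: PathLike) -> Dict[str, Path]:
    """Write a trace to three CSV files with fixed headers and sorted rows."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "firings": out / "firing_events.csv",
        "rates": out / "rates.csv",
        "histograms": out / "weight_histograms.csv",
    }
    with paths["firings"].open("w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["time", "neuron"])
        wr.writerows(trace.firing_events)

    desired = dict(trace.desired_series)
    thresholds = dict(trace.threshold_series)
    current_d = trace.desired_series[0][1] if trace.desired_series else ""
    with paths["rates"].open("w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["time", "rate", "desired", "threshold"])
        for t, r in trace.rate_series:
            current_d = desired.get(t, current_d)
            wr.writerow([t, r, current_d, thresholds.get(t, "")])

    with paths["histograms"].open("w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["time", "bin_lo", "count"])
        for t, counts in trace.weight_snapshots:
            for k, c in enumerate(counts):
                wr.writerow([t, round(-1.0 + 0.1 * k, 1), c])
    return paths


# ----------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Serializable description of a rate-control run; unknown keys rejected."""

    n_neurons: int = 1000
    n_synapses: int = 10000
    grid_m: float = 100.0
    granularity: float = 1.0
    initial_threshold: float = 0.5
    tau: float = 20.0
    alpha: float = 0.001
    lambda_: float = 0.0
    window: float = 10.0
    d_schedule: List[Tuple[float, float]] = field(default_factory=lambda: [(0.0, 300.0)])
    t_end: float = 10000.0
    pulse_rate: float = 0.1
    plasticity_enabled: bool = True
    plasticity_step: float = 0.001
    plasticity_refractory: float = 10.0
    weight_snapshot_every: Optional[float] = None
    seed: int = 0

    @classmethod
    def from_dict(cls, data: Dict[str, Any]) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.d_schedule = [(float(t), float(d)) for t, d in cfg.d_schedule]
        return cfg

    def to_dict(self) -> Dict[str, Any]:
        d = asdict(self)
        d["d_schedule"] = [list(pair) for pair in self.d_schedule]
        return d

    def generation_params(self):
        from .netgen import GenerationParams

        return GenerationParams(
            n_neurons=self.n_neurons,
            n_synapses=self.n_synapses,
            grid=GridSpec(self.grid_m, self.grid_m, self.grid_m, self.granularity),
            initial_threshold=self.initial_threshold,
            tau=self.tau,
            plasticity=PlasticityParams(
                self.plasticity_step, self.plasticity_refractory, self.plasticity_enabled
            ),
        )

    def controller(self):
        from .affective import AffectiveState

        return AffectiveState(
            d=self.d_schedule[0][1], alpha=self.alpha, lambda_=self.lambda_, w=self.window
        )


def load_config(path: PathLike) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return RunConfig.from_dict(data or {})
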