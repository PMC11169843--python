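"""Operation, weight, and membrane-storage accounting for (DT-)SCNNs.

A convolutional layer with output maps of size ``h' x w'``, ``c_in`` input
channels and ``k x k`` kernels performs ``h' * w' * c_in * k * k * c_out``
synaptic operations per timestep.  The coding (first) layer consumes
real-valued pixels and therefore needs multiply-accumulate (MAC) operations;
every later layer consumes binary spikes and needs accumulate-only (ACC)
operations.  A dual-threshold convolutional layer emits ``c_out`` spike maps
from only ``c_out / 2`` membrane maps, halving its operations, kernel
weights, and membrane storage.

Conventions (validated against published network tables):

* "weights" counts convolutional kernel parameters only;
* "Vms" counts the membranes of all spiking layers plus the output
  accumulators;
* operations count conv + fc synaptic events for one forward pass,
  multiplied by the number of timesteps; pooling, threshold comparisons and
  resets are free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .network import ArchSpec, LayerSpec

__all__ = [
    "LayerCount",
    "ComplexityReport",
    "count_layer",
    "profile_network",
    "efficiency_ratio",
    "format_si",
]


@dataclass
class LayerCount:
    label: str
    kind: str
    op_kind: str  # "MAC" | "ACC" | "none"
    ops: int
    weights: int
    vms: int


@dataclass
class ComplexityReport:
    layers: list[LayerCount]
    timesteps: int
    arch_text: str = ""

    @property
    def totals(self) -> dict[str, int]:
        acc = sum(l.ops for l in self.layers if l.op_kind == "ACC") * self.timesteps
        mac = sum(l.ops for l in self.layers if l.op_kind == "MAC") * self.timesteps
        return {
            "ACC": acc,
            "MAC": mac,
            "conv_weights": sum(l.weights for l in self.layers),
            "vms": sum(l.vms for l in self.layers),
        }

    @property
    def conv_vms(self) -> int:
        """Membrane count of the convolutional (conv/dtc) layers only."""
        return sum(l.vms for l in self.layers if l.kind in ("conv", "dtc"))

    def to_dict(self) -> dict:
        return {
            "layers": [
                {
                    "label": l.label,
                    "kind": l.kind,
                    "ops": l.ops,
                    "op_kind": l.op_kind,
                    "weights": l.weights,
                    "vms": l.vms,
                }
                for l in self.layers
            ],
            "totals": self.totals,
            "timesteps": self.timesteps,
        }

    def render(self) -> str:
        """Plain-text table with K/M-suffixed totals."""
        rows = [f"{'layer':<12}{'kind':<6}{'ops':>12}{'op':>5}{'weights':>10}{'Vms':>10}"]
        for l in self.layers:
            rows.append(
                f"{l.label:<12}{l.kind:<6}{l.ops * self.timesteps:>12}"
                f"{(l.op_kind if l.op_kind != 'none' else '-'):>5}"
                f"{l.weights:>10}{l.vms:>10}"
            )
        t = self.totals
        rows.append("-" * len(rows[0]))
        rows.append(
            f"totals (T={self.timesteps}): "
            f"{format_si(t['ACC'])}(ACC) + {format_si(t['MAC'])}(MAC), "
            f"weights {format_si(t['conv_weights'])}, Vms {format_si(t['vms'])}"
        )
        return "\n".join(rows)


def count_layer(layer: LayerSpec, coding: bool = False) -> LayerCount:
    """Per-layer synaptic-operation, weight, and membrane counts.

    ``coding`` marks the first layer, whose real-valued input makes its
    operations MACs.  Shapes must have been propagated by ``parse_arch``.
    """
    if not layer.in_shape or not layer.out_shape:
        raise ValueError("layer shapes not propagated; parse the architecture first")
    label = f"{layer.size}{ {'conv': 'c', 'dtc': 'dtc', 'pool': 'p', 'fc': 'fc', 'fc_out': 'fc'}[layer.kind] }"
    if layer.kind in ("conv", "dtc"):
        c_in, _, _ = layer.in_shape
        _, ho, wo = layer.out_shape
        m = layer.size  # membrane maps: c_out for conv, c_out/2 for dtc
        ops = ho * wo * c_in * layer.kernel * layer.kernel * m
        weights = c_in * layer.kernel * layer.kernel * m
        vms = ho * wo * m
        return LayerCount(label, layer.kind, "MAC" if coding else "ACC", ops, weights, vms)
    if layer.kind in ("fc", "fc_out"):
        n_in = 1
        for d in layer.in_shape:
            n_in *= d
        ops = n_in * layer.size
        return LayerCount(label, layer.kind, "MAC" if coding else "ACC", ops, 0, layer.size)
    # pooling contributes nothing under the stated convention
    return LayerCount(f"p{layer.size}", "pool", "none", 0, 0, 0)


def profile_network(arch: ArchSpec, timesteps: int = 1) -> ComplexityReport:
    """Aggregate per-layer counts; operation totals scale with timesteps."""
    if timesteps < 1:
        raise ValueError(f"timesteps must be >= 1, got {timesteps}")
    counts = [count_layer(l, coding=(i == 0)) for i, l in enumerate(arch.layers)]
    return ComplexityReport(layers=counts, timesteps=timesteps, arch_text=arch.text)


def efficiency_ratio(accuracy_percent: float, total_ops_millions: float) -> float:
    """Accuracy-per-operation figure of merit R = accuracy (%) / ops (M)."""
    if total_ops_millions <= 0:
        raise ValueError("operation count must be positive")
    return float(accuracy_percent) / float(total_ops_millions)


def format_si(n: int | float, decimals: int | None = None,
              unit: str | None = None) -> str:
    """Render a count with a K (10^3) or M (10^6) suffix, half-up rounding.

    ``unit`` forces the suffix (published tables keep "M" even for counts
    below one million, e.g. 313,600 -> "0.31M"); by default the largest
    suffix not exceeding the value is used.  ``decimals=None`` picks 0/1/2
    decimals for scaled values >= 100, >= 10, and < 10 respectively.
    """
    n = float(n)
    scales = {"M": 1e6, "K": 1e3}
    if unit is None:
        for suffix, u in scales.items():
            if abs(n) >= u:
                unit = suffix
                break
        else:
            return f"{n:g}"
    x = Decimal(repr(n)) / Decimal(repr(scales[unit]))
    if decimals is None:
        decimals = 0 if abs(x) >= 100 else (1 if abs(x) >= 10 else 2)
    q = Decimal(1).scaleb(-decimals)
    return f"{x.quantize(q, rounding=ROUND_HALF_UP):f}{unit}"
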