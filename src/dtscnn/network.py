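"""Network architecture: parsing, parameters, and the multi-timestep forward pass.

Architectures are written as compact strings, e.g. ``"16c5-p2-40c5-p2-256fc-10fc"``
for a plain spiking CNN or ``"8dtc5-p2-20dtc5-p2-256fc-10fc"`` for its
dual-threshold counterpart.  Token grammar (``-`` separated, case sensitive):

    <n>c<k>    spiking convolutional layer, n output channels, k x k kernel
    <n>dtc<k>  dual-threshold convolutional layer with n membrane maps,
               emitting 2n spike maps (primary block then secondary block)
    p<s>       pooling over s x s windows with stride s
    <n>fc      fully connected layer with n units; the last fc token is the
               non-spiking output accumulator (one unit per class)

Convolutions use same padding and stride 1; the first layer is the coding
layer and receives the real-valued image directly at every timestep (direct
encoding).  The network output is the vector of output-layer membrane
potentials at the final timestep, and the predicted class is its argmax.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .neuron import NeuronConfig, dtlif_step, lif_step

__all__ = [
    "LayerSpec",
    "ArchSpec",
    "NetworkParams",
    "ForwardTrace",
    "parse_arch",
    "init_params",
    "synaptic_current",
    "dtc_forward",
    "network_forward",
    "predict",
    "ArchError",
]


class ArchError(ValueError):
    """Raised for malformed architecture strings or impossible shapes."""


# ---------------------------------------------------------------------------
# architecture parsing
# ---------------------------------------------------------------------------

@dataclass
class LayerSpec:
    """One parsed layer.

    ``size`` is the number of output channels (conv), membrane maps (dtc —
    half the emitted spike-map count), units (fc / fc_out), or the pooling
    window (pool).  ``in_shape`` / ``out_shape`` are channel-first
    ``(c, h, w)`` for spatial layers and ``(n,)`` after flattening; they are
    filled in by shape propagation during parsing.
    """

    kind: str  # conv | dtc | pool | fc | fc_out
    size: int
    kernel: int | None = None
    spiking: bool = True
    in_shape: tuple[int, ...] = field(default=())
    out_shape: tuple[int, ...] = field(default=())

    @property
    def emitted_channels(self) -> int:
        if self.kind == "dtc":
            return 2 * self.size
        if self.kind == "conv":
            return self.size
        raise ValueError(f"layer kind {self.kind!r} has no channel count")


@dataclass
class ArchSpec:
    text: str
    input_shape: tuple[int, int, int]  # (h, w, c)
    layers: list[LayerSpec] = field(default_factory=list)

    @property
    def n_classes(self) -> int:
        return self.layers[-1].size

    def spiking_layers(self):
        return [(i, l) for i, l in enumerate(self.layers) if l.spiking]


_CONV_RE = re.compile(r"(\d+)c(\d+)")
_DTC_RE = re.compile(r"(\d+)dtc(\d+)")
_POOL_RE = re.compile(r"p(\d+)")
_FC_RE = re.compile(r"(\d+)fc")


def _parse_token(tok: str, pos: int) -> LayerSpec:
    if m := _DTC_RE.fullmatch(tok):
        n, k = int(m.group(1)), int(m.group(2))
        if n < 1 or k < 1:
            raise ArchError(f"token {pos}: {tok!r} has zero size")
        if k % 2 == 0:
            raise ArchError(f"token {pos}: even kernel {k} unsupported (same padding)")
        return LayerSpec("dtc", n, kernel=k)
    if m := _CONV_RE.fullmatch(tok):
        n, k = int(m.group(1)), int(m.group(2))
        if n < 1 or k < 1:
            raise ArchError(f"token {pos}: {tok!r} has zero size")
        if k % 2 == 0:
            raise ArchError(f"token {pos}: even kernel {k} unsupported (same padding)")
        return LayerSpec("conv", n, kernel=k)
    if m := _POOL_RE.fullmatch(tok):
        s = int(m.group(1))
        if s < 1:
            raise ArchError(f"token {pos}: pooling window must be >= 1")
        return LayerSpec("pool", s, spiking=False)
    if m := _FC_RE.fullmatch(tok):
        n = int(m.group(1))
        if n < 1:
            raise ArchError(f"token {pos}: {tok!r} has zero size")
        return LayerSpec("fc", n)
    raise ArchError(f"token {pos}: unrecognised token {tok!r}")


def parse_arch(text: str, input_shape: tuple[int, int, int]) -> ArchSpec:
    """Parse an architecture string and propagate layer shapes.

    ``input_shape`` is ``(height, width, channels)`` of the input image.
    The final ``fc`` token becomes the non-spiking output accumulator.
    """
    if not text or not text.strip():
        raise ArchError("empty architecture string")
    h, w, c = input_shape
    if h < 1 or w < 1 or c < 1:
        raise ArchError(f"invalid input shape {input_shape}")
    tokens = text.strip().split("-")
    layers = [_parse_token(tok, i) for i, tok in enumerate(tokens)]
    if layers[0].kind not in ("conv", "dtc"):
        raise ArchError("first layer must be convolutional (the coding layer)")
    if layers[-1].kind != "fc":
        raise ArchError("last layer must be fully connected (the classifier)")
    layers[-1] = LayerSpec("fc_out", layers[-1].size, spiking=False)

    # shape propagation, channel-first
    shape: tuple[int, ...] = (c, h, w)
    for i, layer in enumerate(layers):
        layer.in_shape = shape
        if layer.kind in ("conv", "dtc"):
            if len(shape) != 3:
                raise ArchError(f"layer {i}: convolution after flattening")
            shape = (layer.emitted_channels, shape[1], shape[2])
        elif layer.kind == "pool":
            if len(shape) != 3:
                raise ArchError(f"layer {i}: pooling after flattening")
            s = layer.size
            nh, nw = shape[1] // s, shape[2] // s
            if nh < 1 or nw < 1:
                raise ArchError(
                    f"layer {i}: pooling {s}x{s} collapses {shape[1]}x{shape[2]} below 1x1"
                )
            shape = (shape[0], nh, nw)
        else:  # fc / fc_out
            shape = (layer.size,)
        layer.out_shape = shape
    return ArchSpec(text=text.strip(), input_shape=(h, w, c), layers=layers)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class NetworkParams:
    """Synaptic weights and per-layer learnable thresholds.

    ``weights[i]`` is ``None`` for pooling layers, a ``(m, c_in, k, k)``
    kernel stack for conv/dtc layers (``m`` membrane maps), and a
    ``(n_out, n_in)`` matrix for fc layers.  ``thresholds[i]`` is a length-1
    array for spiking conv/fc layers, length-2 ``[vth0, vth1]`` for dtc
    layers, and ``None`` for non-spiking layers.
    """

    weights: list[np.ndarray | None]
    thresholds: list[np.ndarray | None]
    leak: float

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            weights=[None if w is None else w.copy() for w in self.weights],
            thresholds=[None if t is None else t.copy() for t in self.thresholds],
            leak=self.leak,
        )


def init_params(arch: ArchSpec, seed: int = 0, leak: float = 0.5,
                threshold_init: float = 0.5, weight_gain: float = 1.0) -> NetworkParams:
    """Fan-in-scaled uniform weight initialisation with a recorded seed.

    Weights are drawn from ``U(-g*sqrt(3/fan_in), g*sqrt(3/fan_in))`` (unit
    variance of the summed current for unit-variance inputs at ``g = 1``).
    All thresholds start at the same value (default 0.5), as do both members
    of each dual-threshold pair.
    """
    rng = np.random.default_rng(seed)
    weights: list[np.ndarray | None] = []
    thresholds: list[np.ndarray | None] = []
    for layer in arch.layers:
        if layer.kind in ("conv", "dtc"):
            c_in = layer.in_shape[0]
            k = layer.kernel
            fan_in = c_in * k * k
            bound = weight_gain * np.sqrt(3.0 / fan_in)
            weights.append(rng.uniform(-bound, bound, size=(layer.size, c_in, k, k)))
            n_th = 2 if layer.kind == "dtc" else 1
            thresholds.append(np.full(n_th, float(threshold_init)))
        elif layer.kind in ("fc", "fc_out"):
            n_in = int(np.prod(layer.in_shape))
            bound = weight_gain * np.sqrt(3.0 / n_in)
            weights.append(rng.uniform(-bound, bound, size=(layer.size, n_in)))
            thresholds.append(
                np.full(1, float(threshold_init)) if layer.kind == "fc" else None
            )
        else:
            weights.append(None)
            thresholds.append(None)
    return NetworkParams(weights=weights, thresholds=thresholds, leak=float(leak))


# ---------------------------------------------------------------------------
# convolution / pooling primitives (same padding, stride 1; im2col based)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B, C*k*k, H*W) patch matrix with same padding."""
    b, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (B, C, H, W, k, k) -> (B, C, k, k, H*W)
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(b, c * k * k, h * w)
    return np.ascontiguousarray(cols)


def _conv2d(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Same-padding stride-1 cross-correlation; x (B,C,H,W), weights (M,C,k,k)."""
    m, c, k, _ = weights.shape
    b, cx, h, w = x.shape
    if cx != c:
        raise ValueError(f"input has {cx} channels, kernels expect {c}")
    cols = _im2col(x, k)
    out = np.matmul(weights.reshape(m, c * k * k), cols)  # (B, M, H*W)
    return out.reshape(b, m, h, w)


def _conv2d_grad_w(x: np.ndarray, g_out: np.ndarray, k: int) -> np.ndarray:
    """Gradient of the conv output w.r.t. the kernels, summed over the batch."""
    b, c, h, w = x.shape
    m = g_out.shape[1]
    cols = _im2col(x, k)  # (B, C*k*k, H*W)
    g = np.matmul(g_out.reshape(b, m, h * w), cols.transpose(0, 2, 1))  # (B, M, C*k*k)
    return g.sum(axis=0).reshape(m, c, k, k)


def _conv2d_grad_x(g_out: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Gradient routed back to the conv input (transpose convolution)."""
    m, c, k, _ = weights.shape
    b, _, h, w = g_out.shape
    g_cols = np.matmul(
        weights.reshape(m, c * k * k).T, g_out.reshape(b, m, h * w)
    )  # (B, C*k*k, H*W)
    g_cols = g_cols.reshape(b, c, k, k, h, w)
    p = k // 2
    canvas = np.zeros((b, c, h + 2 * p, w + 2 * p))
    for di in range(k):
        for dj in range(k):
            canvas[:, :, di:di + h, dj:dj + w] += g_cols[:, :, di, dj]
    return canvas[:, :, p:p + h, p:p + w]


def _pool_forward(x: np.ndarray, s: int, mode: str) -> np.ndarray:
    b, c, h, w = x.shape
    nh, nw = h // s, w // s
    xw = x[:, :, : nh * s, : nw * s].reshape(b, c, nh, s, nw, s)
    if mode == "avg":
        return xw.mean(axis=(3, 5))
    if mode == "max":
        return xw.max(axis=(3, 5))
    raise ValueError(f"unknown pooling mode {mode!r}")


def _pool_backward(g_out: np.ndarray, x: np.ndarray, s: int, mode: str) -> np.ndarray:
    b, c, h, w = x.shape
    nh, nw = h // s, w // s
    g_in = np.zeros_like(x)
    if mode == "avg":
        g = np.repeat(np.repeat(g_out, s, axis=2), s, axis=3) / (s * s)
        g_in[:, :, : nh * s, : nw * s] = g
    else:  # max: route to the first maximal element of each window
        xw = x[:, :, : nh * s, : nw * s].reshape(b, c, nh, s, nw, s)
        flat = xw.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, nh, nw, s * s)
        idx = flat.argmax(axis=-1)
        mask = np.zeros_like(flat)
        np.put_along_axis(mask, idx[..., None], 1.0, axis=-1)
        mask = mask.reshape(b, c, nh, nw, s, s).transpose(0, 1, 2, 4, 3, 5)
        g_in[:, :, : nh * s, : nw * s] = (
            mask * g_out[:, :, :, None, :, None]
        ).reshape(b, c, nh * s, nw * s)
    return g_in


# ---------------------------------------------------------------------------
# layer-level operations
# ---------------------------------------------------------------------------

def synaptic_current(x: np.ndarray, weights: np.ndarray, layer: LayerSpec) -> np.ndarray:
    """Weighted sum of presynaptic activity: convolution or matrix product.

    ``x`` is real-valued only at the coding layer (direct pixel input);
    elsewhere it holds binary spikes (or pooled spike fractions).
    """
    x = np.asarray(x, dtype=np.float64)
    if layer.kind in ("conv", "dtc"):
        return _conv2d(x, weights)
    if layer.kind in ("fc", "fc_out"):
        flat = x.reshape(x.shape[0], -1)
        if flat.shape[1] != weights.shape[1]:
            raise ValueError(
                f"fc input size {flat.shape[1]} != weight fan-in {weights.shape[1]}"
            )
        return flat @ weights.T
    raise ValueError(f"layer kind {layer.kind!r} carries no synapses")


def dtc_forward(x: np.ndarray, weights: np.ndarray, thresholds, state_prev,
                leak: float, layer: LayerSpec | None = None):
    """One timestep of a dual-threshold convolutional layer.

    Returns the new :class:`NeuronState` and the concatenated spike maps —
    the primary-threshold block followed by the secondary block along the
    channel axis, so ``m`` membrane maps emit ``2m`` spike maps.
    """
    if layer is None:
        m = weights.shape[0]
        layer = LayerSpec("dtc", m, kernel=weights.shape[2])
    current = synaptic_current(x, weights, layer)
    cfg = NeuronConfig(leak=leak, thresholds=(float(thresholds[0]), float(thresholds[1])))
    state = dtlif_step(state_prev.membrane, state_prev.spikes[0], current, cfg,
                       time_index=state_prev.time_index + 1)
    out = np.concatenate(state.spikes, axis=1)
    return state, out


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------

class ForwardTrace:
    """Per-layer, per-timestep record of a forward pass.

    Stored (indexed ``[layer][t-1]``): the array each layer consumed
    (``inputs``), synaptic currents, membranes, per-pathway spike tuples and
    emitted outputs, plus one dropout mask per fc layer (shared across
    timesteps) and the final output membrane potentials.
    """

    def __init__(self, n_layers: int, timesteps: int):
        self.timesteps = timesteps
        self.inputs = [[] for _ in range(n_layers)]
        self.currents = [[] for _ in range(n_layers)]
        self.membranes = [[] for _ in range(n_layers)]
        self.spikes = [[] for _ in range(n_layers)]
        self.outputs = [[] for _ in range(n_layers)]
        self.dropout_masks: dict[int, np.ndarray] = {}
        self.output_vms: np.ndarray | None = None

    def export(self) -> dict[str, np.ndarray]:
        """Flatten to a key-value archive keyed ``layer{L}/t{T}/{field}``."""
        out = {}
        for li in range(len(self.inputs)):
            for t in range(len(self.membranes[li])):
                key = f"layer{li}/t{t + 1}"
                if self.currents[li]:
                    out[f"{key}/current"] = self.currents[li][t]
                if self.membranes[li]:
                    out[f"{key}/membrane"] = self.membranes[li][t]
                if self.spikes[li] and self.spikes[li][t] is not None:
                    out[f"{key}/spikes"] = np.stack(self.spikes[li][t])
        if self.output_vms is not None:
            out["output_vms"] = self.output_vms
        return out


def _coerce_batch(batch: np.ndarray, arch: ArchSpec) -> np.ndarray:
    """Accept (B,h,w), (B,h,w,c) or (B,c,h,w) and return channel-first."""
    h, w, c = arch.input_shape
    batch = np.asarray(batch, dtype=np.float64)
    if batch.ndim == 3 and c == 1 and batch.shape[1:] == (h, w):
        return batch[:, None, :, :]
    if batch.ndim == 4 and batch.shape[1:] == (h, w, c):
        return np.moveaxis(batch, 3, 1)
    if batch.ndim == 4 and batch.shape[1:] == (c, h, w):
        return batch
    raise ValueError(
        f"batch shape {batch.shape} incompatible with input shape {(h, w, c)}"
    )


def network_forward(arch: ArchSpec, params: NetworkParams, batch: np.ndarray,
                    timesteps: int, trace: bool = False, training: bool = False,
                    dropout_p: float = 0.0, rng: np.random.Generator | None = None,
                    pooling: str = "avg"):
    """Run the network for ``timesteps`` ticks and return the output Vms.

    The same real-valued image batch is presented at every timestep (direct
    encoding).  All membranes and spikes start at zero.  The output layer
    accumulates current into its membrane with leak but never spikes or
    resets; its membrane at the last timestep is the network output, one
    value per class.  With ``training=True`` and ``dropout_p > 0``, dropout
    masks (one per spiking fc layer, shared across timesteps) are applied to
    fc spike outputs with inverted scaling.

    Returns ``(output_vms, trace_or_None)``.
    """
    if timesteps < 1:
        raise ValueError(f"timesteps must be >= 1, got {timesteps}")
    x0 = _coerce_batch(batch, arch)
    b = x0.shape[0]
    n_layers = len(arch.layers)
    leak = params.leak

    # mutable per-layer state
    membrane: list[np.ndarray | None] = [None] * n_layers
    spike0: list[np.ndarray | None] = [None] * n_layers
    for li, layer in enumerate(arch.layers):
        if layer.kind in ("conv", "dtc"):
            membrane[li] = np.zeros((b, layer.size, *layer.in_shape[1:]))
            spike0[li] = np.zeros_like(membrane[li])
        elif layer.kind in ("fc", "fc_out"):
            membrane[li] = np.zeros((b, layer.size))
            spike0[li] = np.zeros_like(membrane[li])

    rec = ForwardTrace(n_layers, timesteps) if (trace or training) else None
    use_dropout = training and dropout_p > 0.0
    masks: dict[int, np.ndarray] = {}
    if use_dropout:
        if rng is None:
            raise ValueError("dropout requires an explicit rng")
        for li, layer in enumerate(arch.layers):
            if layer.kind == "fc":
                masks[li] = (rng.random((b, layer.size)) >= dropout_p).astype(np.float64)
        if rec is not None:
            rec.dropout_masks = masks

    for t in range(1, timesteps + 1):
        x = x0
        for li, layer in enumerate(arch.layers):
            if rec is not None:
                rec.inputs[li].append(x)
            if layer.kind == "pool":
                x = _pool_forward(x, layer.size, pooling)
                if rec is not None:
                    rec.currents[li].append(None)
                    rec.membranes[li].append(None)
                    rec.spikes[li].append(None)
                    rec.outputs[li].append(x)
                continue
            w = params.weights[li]
            i_t = synaptic_current(x, w, layer)
            if layer.kind == "fc_out":
                v = leak * membrane[li] + i_t
                membrane[li] = v
                x = v
                s_tuple = None
            else:
                v = leak * membrane[li] * (1.0 - spike0[li]) + i_t
                th = params.thresholds[li]
                if layer.kind == "dtc":
                    s0 = (v >= th[0]).astype(np.float64)
                    s1 = (v >= th[1]).astype(np.float64)
                    s_tuple = (s0, s1)
                    x = np.concatenate([s0, s1], axis=1)
                else:
                    s0 = (v >= th[0]).astype(np.float64)
                    s_tuple = (s0,)
                    x = s0
                membrane[li] = v
                spike0[li] = s0
                if layer.kind == "fc" and use_dropout:
                    x = x * masks[li] / (1.0 - dropout_p)
            if rec is not None:
                rec.currents[li].append(i_t)
                rec.membranes[li].append(v)
                rec.spikes[li].append(s_tuple)
                rec.outputs[li].append(x)

    out_vms = membrane[n_layers - 1]
    if rec is not None:
        rec.output_vms = out_vms
    return out_vms, (rec if (trace or training) else None)


def predict(output_vms: np.ndarray) -> np.ndarray:
    """Predicted class per sample: the label of the largest output membrane.

    Ties break toward the lowest class index.
    """
    vms = np.asarray(output_vms, dtype=np.float64)
    if vms.size == 0 or vms.shape[-1] == 0:
        raise ValueError("empty output")
    return np.argmax(vms, axis=-1)
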