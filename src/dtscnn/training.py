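"""Variant spatio-temporal backpropagation (STBP) for dual-threshold SCNNs.

Spikes are non-differentiable, so the backward pass substitutes the
rectangular surrogate ``h(u)`` for the derivative of each threshold
comparison, with ``u = v / vth``.  For a dual-threshold layer the loss
gradient reaching each spike pathway is routed back through the next
layer's linear connectivity, the two pathway gradients converge onto the
single shared membrane,

    dL/dv(t) = sum_k dL/dx_k(t) * h(v(t)/vth_k) / vth_k  (+ temporal terms),

and the thresholds themselves are learnable with

    dL/dvth_k = sum_i dL/dx_ik(t) * h(v(t)/vth_k) * (-v(t) / vth_k^2).

Temporal credit assignment follows the layer's own recursion: the primary
spike at ``t`` gates the reset term of ``v(t+1)``, and the membrane at ``t``
leaks into ``t+1`` wherever no reset occurred.  Two backward modes exist:

* ``variant`` (default): future influence on the membrane is counted only
  through the next step's spikes, i.e. ``dL/dv(t)`` adds
  ``lam * (1 - s0(t)) * sum_k dL/dx_k(t+1) * h(v(t+1)/vth_k)/vth_k``, and the
  primary-pathway spike gradient adds
  ``dL/dx_0(t+1) * h(v(t+1)/vth_0)/vth_0 * (-lam * v(t))``.
* ``standard`` (``temporal_membrane_path=True``): full STBP, carrying the
  direct membrane-to-membrane path ``lam * (1 - s0(t)) * dL/dv(t+1)`` and
  routing the reset-path spike gradient through ``dL/dv(t+1)``.

At a single timestep the two modes coincide, and all headline single-step
networks are trained at ``T = 1`` in the re-train stage.

The two-stage strategy pre-trains from random weights at five timesteps,
then continues from the pre-trained parameters at one timestep, retaining
accuracy while cutting inference latency and operation counts fivefold.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .network import (
    ArchSpec,
    NetworkParams,
    ForwardTrace,
    _conv2d_grad_w,
    _conv2d_grad_x,
    _pool_backward,
    network_forward,
    predict,
)
from .neuron import surrogate_gradient

__all__ = [
    "TrainConfig",
    "GradientSet",
    "compute_loss",
    "backward_spike",
    "backward_membrane",
    "threshold_gradient",
    "backprop",
    "train_stage",
    "two_stage_train",
    "evaluate",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Hyperparameters of one training stage.

    The learning rate is multiplied by ``lr_decay`` every
    ``decay_interval`` epochs ("dropped by 10%" read as a factor of 0.9).
    Dropout applies to spiking fully connected activations only, during
    training only.  ``temporal_membrane_path`` selects the standard-STBP
    temporal recursion instead of the default variant form (moot at T=1).
    """

    timesteps: int = 1
    lr: float = 0.05
    lr_decay: float = 0.9
    decay_interval: int = 25
    epochs: int = 100
    batch_size: int = 64
    dropout: float = 0.5
    leak: float = 0.5
    seed: int = 0
    stage: str = "pretrain"  # "pretrain" | "retrain"
    loss: str = "cross_entropy"
    optimizer: str = "sgd"  # "sgd" | "momentum"
    momentum: float = 0.9
    pooling: str = "avg"  # "avg" | "max"
    temporal_membrane_path: bool = False
    threshold_floor: float = 0.01
    threshold_init: float = 0.5
    weight_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.timesteps < 1:
            raise ValueError("timesteps must be >= 1")
        if self.lr <= 0 or self.lr_decay <= 0 or self.decay_interval < 1:
            raise ValueError("learning-rate schedule parameters must be positive")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if not 0.0 <= self.leak <= 1.0:
            raise ValueError("leak must be in [0, 1]")
        if self.stage not in ("pretrain", "retrain"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.loss != "cross_entropy":
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.optimizer not in ("sgd", "momentum"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.pooling not in ("avg", "max"):
            raise ValueError(f"unknown pooling {self.pooling!r}")
        if self.threshold_floor <= 0:
            raise ValueError("threshold_floor must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "TrainConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config file must hold a mapping")
        return cls.from_dict(raw)


@dataclass
class GradientSet:
    """Loss value plus gradients mirroring :class:`NetworkParams`."""

    weight_grads: list[np.ndarray | None]
    threshold_grads: list[np.ndarray | None]
    loss: float


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def compute_loss(output_vms: np.ndarray, labels) -> float:
    """Mean softmax cross-entropy of the output membrane potentials."""
    return _loss_and_grad(output_vms, labels)[0]


def _loss_and_grad(output_vms: np.ndarray, labels):
    vms = np.asarray(output_vms, dtype=np.float64)
    labels = np.asarray(labels)
    if vms.ndim != 2:
        raise ValueError("output_vms must be (batch, classes)")
    b, c = vms.shape
    if labels.shape != (b,):
        raise ValueError(f"need one label per sample, got {labels.shape} for batch {b}")
    if labels.min() < 0 or labels.max() >= c:
        raise ValueError(f"label out of range [0, {c})")
    p = _softmax(vms)
    loss = float(-np.mean(np.log(np.maximum(p[np.arange(b), labels], 1e-300))))
    grad = p.copy()
    grad[np.arange(b), labels] -= 1.0
    return loss, grad / b


# ---------------------------------------------------------------------------
# backward primitives
# ---------------------------------------------------------------------------

def backward_spike(grad_up_path0, grad_up_path1=None, grad_future=None) -> np.ndarray:
    """Total loss gradient at one spike map.

    Elementwise sum of the next layer's routed pathway contributions (the
    linear synaptic connectivity has already summed over its fan-out) and
    the temporal contribution from the next timestep; absent terms pass
    ``None``.  At the final timestep there is no temporal term.
    """
    g = np.asarray(grad_up_path0, dtype=np.float64)
    for extra in (grad_up_path1, grad_future):
        if extra is not None:
            extra = np.asarray(extra, dtype=np.float64)
            if extra.shape != g.shape:
                raise ValueError(f"shape mismatch: {g.shape} vs {extra.shape}")
            g = g + extra
    return g


def _pathway_to_membrane(grad_spikes, v, thresholds) -> np.ndarray:
    """sum_k dL/dx_k * h(v/vth_k) / vth_k — spike grads folded onto the Vm."""
    total = np.zeros_like(np.asarray(v, dtype=np.float64))
    for g_k, vth_k in zip(grad_spikes, thresholds):
        if g_k is not None:
            total = total + np.asarray(g_k) * surrogate_gradient(v / vth_k) / vth_k
    return total


def backward_membrane(grad_spike_path0_t, grad_spike_path1_t, v_t, thresholds,
                      grad_spike_t1=None, v_t1=None, spike0_t=None,
                      leak: float = 0.5) -> np.ndarray:
    """Loss gradient at the membrane from its spike pathways (variant form).

    Sums both pathway contributions at ``t`` through the surrogate, plus —
    when the next step's spike gradients are supplied — the printed temporal
    bracket ``lam * (1 - s0(t)) * sum_k dL/dx_k(t+1) * h(v(t+1)/vth_k)/vth_k``.
    For a single-threshold layer pass ``grad_spike_path1_t=None`` and a
    1-tuple of thresholds.
    """
    g_v = _pathway_to_membrane((grad_spike_path0_t, grad_spike_path1_t), v_t, thresholds)
    if grad_spike_t1 is not None:
        if v_t1 is None or spike0_t is None:
            raise ValueError("temporal term needs v_t1 and spike0_t")
        g_v = g_v + leak * (1.0 - np.asarray(spike0_t)) * _pathway_to_membrane(
            grad_spike_t1, v_t1, thresholds
        )
    return g_v


def threshold_gradient(grad_spikes_pathk, v, vth_k: float) -> float:
    """dL/dvth_k summed over neurons (and timesteps folded in by the caller).

    Each neuron contributes ``dL/dx_k * h(v/vth_k) * (-v / vth_k^2)``; the
    surrogate window zeroes neurons whose membrane sits far from the
    threshold.  The gradient-descent update is ``vth_k -= lr * gradient``.
    """
    if vth_k <= 0:
        raise ValueError(f"threshold must be positive, got {vth_k}")
    g = np.asarray(grad_spikes_pathk, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    return float(np.sum(g * surrogate_gradient(v / vth_k) * (-v / vth_k**2)))


# ---------------------------------------------------------------------------
# full backward pass
# ---------------------------------------------------------------------------

def backprop(arch: ArchSpec, params: NetworkParams, trace: ForwardTrace,
             labels, cfg: TrainConfig) -> GradientSet:
    """Backpropagate through space and time over a recorded forward pass.

    Layers are processed last to first; within each spiking layer, time runs
    backward so the temporal recursion can consume the already-computed
    gradients of step ``t + 1``.  Weight gradients are summed over the batch
    (the loss carries the 1/batch factor); threshold gradients are summed
    over neurons and timesteps.
    """
    T = trace.timesteps
    leak = params.leak
    standard = cfg.temporal_membrane_path
    loss, g_out = _loss_and_grad(trace.output_vms, labels)

    n_layers = len(arch.layers)
    g_w: list[np.ndarray | None] = [None] * n_layers
    g_th: list[np.ndarray | None] = [None] * n_layers

    # gradient w.r.t. the current layer's output, one slot per timestep
    g_stack: list[np.ndarray | None] = [None] * T

    for li in range(n_layers - 1, -1, -1):
        layer = arch.layers[li]
        w = params.weights[li]
        inputs = trace.inputs[li]

        if layer.kind == "pool":
            g_stack = [
                _pool_backward(g_stack[t], inputs[t], layer.size, cfg.pooling)
                for t in range(T)
            ]
            continue

        if layer.kind == "fc_out":
            # leaky accumulator, no spikes, no reset: v(t) = lam v(t-1) + i(t)
            g_v = [None] * T
            g_v[T - 1] = g_out
            for t in range(T - 2, -1, -1):
                g_v[t] = leak * g_v[t + 1]
            g_w[li] = sum(
                g_v[t].T @ inputs[t].reshape(inputs[t].shape[0], -1) for t in range(T)
            )
            g_stack = [(g_v[t] @ w).reshape(inputs[t].shape) for t in range(T)]
            continue

        # spiking layer (conv, dtc, or fc)
        th = params.thresholds[li]
        dual = layer.kind == "dtc"
        membranes = trace.membranes[li]
        spikes = trace.spikes[li]
        mask = trace.dropout_masks.get(li)

        # spatial upstream per pathway
        spatial: list[tuple[np.ndarray, ...]] = []
        for t in range(T):
            g_o = g_stack[t]
            if layer.kind == "fc" and mask is not None:
                g_o = g_o * mask / (1.0 - cfg.dropout)
            if dual:
                m = layer.size
                spatial.append((g_o[:, :m], g_o[:, m:]))
            else:
                spatial.append((g_o,))

        g_x: list[tuple[np.ndarray, ...] | None] = [None] * T
        g_v = [None] * T
        for t in range(T - 1, -1, -1):
            v_t = membranes[t]
            s0_t = spikes[t][0]
            if t == T - 1:
                g_x[t] = spatial[t]
                g_v[t] = _pathway_to_membrane(g_x[t], v_t, th)
            else:
                v_t1 = membranes[t + 1]
                if standard:
                    reset_path = -leak * v_t * g_v[t + 1]
                else:
                    reset_path = (
                        -leak * v_t
                        * np.asarray(g_x[t + 1][0])
                        * surrogate_gradient(v_t1 / th[0]) / th[0]
                    )
                if dual:
                    g_x[t] = (
                        backward_spike(spatial[t][0], grad_future=reset_path),
                        spatial[t][1],
                    )
                else:
                    g_x[t] = (backward_spike(spatial[t][0], grad_future=reset_path),)
                if standard:
                    g_v[t] = (
                        _pathway_to_membrane(g_x[t], v_t, th)
                        + leak * (1.0 - s0_t) * g_v[t + 1]
                    )
                else:
                    g_v[t] = backward_membrane(
                        g_x[t][0], g_x[t][1] if dual else None, v_t, th,
                        grad_spike_t1=g_x[t + 1], v_t1=v_t1, spike0_t=s0_t,
                        leak=leak,
                    )

        # parameter gradients
        g_th[li] = np.array([
            sum(threshold_gradient(g_x[t][k], membranes[t], th[k]) for t in range(T))
            for k in range(len(th))
        ])
        if layer.kind == "fc":
            g_w[li] = sum(
                g_v[t].T @ inputs[t].reshape(inputs[t].shape[0], -1) for t in range(T)
            )
            g_stack = [(g_v[t] @ w).reshape(inputs[t].shape) for t in range(T)]
        else:
            g_w[li] = sum(
                _conv2d_grad_w(inputs[t], g_v[t], layer.kernel) for t in range(T)
            )
            if li > 0:
                g_stack = [_conv2d_grad_x(g_v[t], w) for t in range(T)]

    return GradientSet(weight_grads=g_w, threshold_grads=g_th, loss=loss)


# ---------------------------------------------------------------------------
# training loops
# ---------------------------------------------------------------------------

def evaluate(arch: ArchSpec, params: NetworkParams, images, labels,
             timesteps: int, batch_size: int = 256, pooling: str = "avg") -> float:
    """Classification accuracy of a clean (no-dropout) forward pass."""
    labels = np.asarray(labels)
    n = len(labels)
    correct = 0
    for start in range(0, n, batch_size):
        xb = images[start:start + batch_size]
        out, _ = network_forward(arch, params, xb, timesteps, pooling=pooling)
        correct += int(np.sum(predict(out) == labels[start:start + batch_size]))
    return correct / n


def train_stage(arch: ArchSpec, params: NetworkParams, data, cfg: TrainConfig):
    """Run one training stage of mini-batch gradient descent.

    ``data`` is an ``(images, labels)`` pair.  Weights and both thresholds of
    every spiking layer are updated each mini-batch; thresholds are clipped
    to a small positive floor so the ``1/vth`` surrogate scaling stays
    defined.  Returns the updated parameters (the input is not mutated) and
    a per-epoch metrics list of dicts ``{epoch, stage, loss, accuracy, lr}``.
    """
    images, labels = data
    images = np.asarray(images, dtype=np.float64)
    labels = np.asarray(labels)
    n = len(labels)
    if n == 0:
        raise ValueError("empty training set")
    params = params.copy()
    rng = np.random.default_rng(cfg.seed)
    velocity_w = [None if wgt is None else np.zeros_like(wgt) for wgt in params.weights]
    velocity_t = [None if th is None else np.zeros_like(th) for th in params.thresholds]
    metrics: list[dict] = []

    for epoch in range(cfg.epochs):
        lr = cfg.lr * cfg.lr_decay ** (epoch // cfg.decay_interval)
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            _, tr = network_forward(
                arch, params, images[idx], cfg.timesteps, training=True,
                dropout_p=cfg.dropout, rng=rng, pooling=cfg.pooling,
            )
            grads = backprop(arch, params, tr, labels[idx], cfg)
            batch_losses.append(grads.loss)
            for li in range(len(arch.layers)):
                gw = grads.weight_grads[li]
                if gw is not None:
                    if cfg.optimizer == "momentum":
                        velocity_w[li] = cfg.momentum * velocity_w[li] - lr * gw
                        params.weights[li] = params.weights[li] + velocity_w[li]
                    else:
                        params.weights[li] = params.weights[li] - lr * gw
                gt = grads.threshold_grads[li]
                if gt is not None:
                    if cfg.optimizer == "momentum":
                        velocity_t[li] = cfg.momentum * velocity_t[li] - lr * gt
                        new_th = params.thresholds[li] + velocity_t[li]
                    else:
                        new_th = params.thresholds[li] - lr * gt
                    params.thresholds[li] = np.maximum(new_th, cfg.threshold_floor)
        acc = evaluate(arch, params, images, labels, cfg.timesteps,
                       batch_size=max(cfg.batch_size, 256), pooling=cfg.pooling)
        metrics.append({
            "epoch": epoch,
            "stage": cfg.stage,
            "loss": float(np.mean(batch_losses)),
            "accuracy": acc,
            "lr": lr,
        })
    return params, metrics


def two_stage_train(arch: ArchSpec, params_init: NetworkParams, data,
                    cfg_pretrain: TrainConfig, cfg_retrain: TrainConfig):
    """Pre-train at several timesteps, then re-train the result at one.

    Stage one starts from the supplied (random) initialisation, by default at
    five timesteps; stage two continues from the stage-one parameters with
    the timestep set to one, so the final network infers in a single tick.
    Returns the final parameters and both stage histories.
    """
    p1, m1 = train_stage(arch, params_init, data, cfg_pretrain)
    p2, m2 = train_stage(arch, p1, data, cfg_retrain)
    return p2, {"pretrain": m1, "retrain": m2}
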