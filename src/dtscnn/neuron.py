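"""Leaky integrate-and-fire dynamics with one or two firing thresholds.

The membrane potential of a (DT-)LIF neuron evolves in discrete time as

    v(t) = lam * v(t-1) * (1 - s0(t-1)) + i(t)

where ``lam`` is the leakage factor and ``s0`` the spike of the *primary*
threshold pathway: crossing the primary threshold resets the membrane, while
a dual-threshold neuron compares the same membrane against a second threshold
to emit a second spike map *without* resetting.  The surrogate gradient used
during training is a rectangular window of width 1 centred on
``u = v / threshold = 1``.

Everything in this module is pure array computation; layers and networks are
built on top of it in :mod:`dtscnn.network`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NeuronConfig",
    "NeuronState",
    "lif_step",
    "dtlif_step",
    "surrogate_gradient",
]


@dataclass(frozen=True)
class NeuronConfig:
    """Static neuron parameters shared by all neurons of a layer.

    Parameters
    ----------
    leak
        Leakage factor ``lam`` in ``[0, 1]``; the fraction of the membrane
        potential carried over to the next timestep when no reset occurred.
    thresholds
        Firing threshold(s) in membrane-potential units.  A 1-tuple
        ``(vth,)`` describes a plain LIF neuron; a 2-tuple ``(vth0, vth1)``
        a dual-threshold neuron.  ``vth0`` is the resetting (primary)
        threshold.  No ordering between ``vth0`` and ``vth1`` is imposed:
        training is free to push the secondary threshold above or below the
        primary one.
    """

    leak: float
    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.leak <= 1.0:
            raise ValueError(f"leak must be in [0, 1], got {self.leak}")
        if len(self.thresholds) not in (1, 2):
            raise ValueError("thresholds must be a 1- or 2-tuple")
        if any(th <= 0 for th in self.thresholds):
            raise ValueError(f"thresholds must be positive, got {self.thresholds}")

    @property
    def dual(self) -> bool:
        return len(self.thresholds) == 2


@dataclass
class NeuronState:
    """Membrane potentials and spikes of one layer at one timestep.

    ``spikes`` holds one binary array per threshold pathway: a single array
    for plain LIF neurons, two (primary, secondary) for dual-threshold
    neurons.  Spike arrays are float arrays containing exactly 0.0 or 1.0 so
    they can enter synaptic sums directly.
    """

    membrane: np.ndarray
    spikes: tuple[np.ndarray, ...]
    time_index: int = 1


def _as_float(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def _check_binary(a: np.ndarray, name: str) -> None:
    if not np.all((a == 0.0) | (a == 1.0)):
        raise ValueError(f"{name} must be binary (0/1)")


def _integrate(v_prev, spike_prev, current, cfg: NeuronConfig) -> np.ndarray:
    """Shared membrane update: reset mask, leak, then current injection."""
    v_prev = _as_float(v_prev, "v_prev")
    spike_prev = _as_float(spike_prev, "spike_prev")
    current = _as_float(current, "current")
    if not (v_prev.shape == spike_prev.shape == current.shape):
        raise ValueError(
            "shape mismatch: "
            f"v_prev {v_prev.shape}, spike_prev {spike_prev.shape}, "
            f"current {current.shape}"
        )
    _check_binary(spike_prev, "spike_prev")
    return cfg.leak * v_prev * (1.0 - spike_prev) + current


def lif_step(v_prev, spike_prev, current, cfg: NeuronConfig,
             time_index: int = 1) -> NeuronState:
    """Advance plain LIF neurons by one timestep.

    ``spike_prev`` is the previous step's spike (which triggers the reset of
    the carried membrane); the returned state holds the new membrane and the
    spike it emits against the single threshold (fired when ``v >= vth``).
    """
    if cfg.dual:
        raise ValueError("lif_step requires a single-threshold NeuronConfig")
    v = _integrate(v_prev, spike_prev, current, cfg)
    spike = (v >= cfg.thresholds[0]).astype(np.float64)
    return NeuronState(membrane=v, spikes=(spike,), time_index=time_index)


def dtlif_step(v_prev, spike0_prev, current, cfg: NeuronConfig,
               time_index: int = 1) -> NeuronState:
    """Advance dual-threshold LIF neurons by one timestep.

    Only the *primary* pathway's previous spike ``spike0_prev`` enters the
    reset term; secondary spikes read the membrane without resetting it, so a
    neuron that only ever crosses the secondary threshold integrates exactly
    like a threshold-free leaky integrator.
    """
    if not cfg.dual:
        raise ValueError("dtlif_step requires a dual-threshold NeuronConfig")
    v = _integrate(v_prev, spike0_prev, current, cfg)
    vth0, vth1 = cfg.thresholds
    spike0 = (v >= vth0).astype(np.float64)
    spike1 = (v >= vth1).astype(np.float64)
    return NeuronState(membrane=v, spikes=(spike0, spike1), time_index=time_index)


def surrogate_gradient(u) -> np.ndarray:
    """Rectangular surrogate derivative of the spike step function.

    ``u`` is the membrane normalised by the threshold; the stand-in
    derivative is 1 where ``|u - 1| < 1/2`` (strict inequality, so the
    window boundary itself carries zero gradient) and 0 elsewhere.
    """
    u = _as_float(u, "u")
    return np.where(np.abs(u - 1.0) < 0.5, 1.0, 0.0)
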