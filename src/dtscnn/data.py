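"""Synthetic datasets, IDX-format image/label files, and checkpoints.

The synthetic generator produces small grayscale classification sets in the
same regime the networks are designed for: pixel values in ``[0, 1]``,
presented identically at every timestep (direct encoding).  Each class owns
a disjoint cell of the image and draws its pattern there — an oriented bar
segment or a Gaussian blob — so the noise-free class means have
non-overlapping (bars: exactly orthogonal) supports and the task is
separable by construction.

IDX is the simple big-endian binary container used to distribute the MNIST
dataset (magic ``0x00 0x00 <dtype> <ndim>`` followed by ``ndim`` uint32
dimension sizes and raw data); reader and writer here cover the
unsigned-byte tensors used for images and labels.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass

import numpy as np

from .network import ArchSpec, NetworkParams, parse_arch

__all__ = [
    "SyntheticSpec",
    "generate_synthetic_dataset",
    "class_patterns",
    "read_idx",
    "write_idx",
    "save_checkpoint",
    "load_checkpoint",
    "FormatError",
    "CHECKPOINT_VERSION",
]


class FormatError(ValueError):
    """Raised for malformed IDX files or checkpoint archives."""


# ---------------------------------------------------------------------------
# synthetic data
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Defaults describe the desk-scale regime used throughout the test suite:
    four classes of oriented bars on 16x16 grayscale images with mild
    additive Gaussian noise.
    """

    n_classes: int = 4
    samples_per_class: int = 50
    image_size: tuple[int, int] = (16, 16)
    family: str = "bars"  # "bars" | "blobs"
    noise_std: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.samples_per_class < 1:
            raise ValueError("need at least one sample per class")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")
        if self.family not in ("bars", "blobs"):
            raise ValueError(f"unknown pattern family {self.family!r}")


def _class_cells(n_classes: int, h: int, w: int):
    """Disjoint grid cells, one per class; error if cells get too small."""
    gcols = int(np.ceil(np.sqrt(n_classes)))
    grows = int(np.ceil(n_classes / gcols))
    ch, cw = h // grows, w // gcols
    if min(ch, cw) < 5:
        raise ValueError(
            f"image {h}x{w} too small for {n_classes} class patterns "
            f"(cells {ch}x{cw}, need >= 5x5)"
        )
    cells = []
    for k in range(n_classes):
        r, c = divmod(k, gcols)
        cells.append((r * ch, c * cw, ch, cw))
    return cells


def class_patterns(spec: SyntheticSpec) -> np.ndarray:
    """Noise-free class mean images, shape ``(n_classes, h, w)``.

    Bar patterns of different classes have exactly disjoint supports (each
    lives in its own grid cell), so the mean images are orthogonal.
    """
    h, w = spec.image_size
    cells = _class_cells(spec.n_classes, h, w)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    patterns = np.zeros((spec.n_classes, h, w))
    for k, (r0, c0, ch, cw) in enumerate(cells):
        cy, cx = r0 + (ch - 1) / 2.0, c0 + (cw - 1) / 2.0
        in_cell = (yy >= r0) & (yy < r0 + ch) & (xx >= c0) & (xx < c0 + cw)
        if spec.family == "bars":
            theta = np.pi * k / spec.n_classes
            dy, dx = np.sin(theta), np.cos(theta)
            along = (yy - cy) * dy + (xx - cx) * dx
            perp = -(yy - cy) * dx + (xx - cx) * dy
            half_len = (min(ch, cw) - 2) / 2.0
            patterns[k] = np.where(
                in_cell & (np.abs(perp) <= 0.7) & (np.abs(along) <= half_len), 1.0, 0.0
            )
        else:  # blobs
            sigma = min(ch, cw) / 5.0
            r2 = (yy - cy) ** 2 + (xx - cx) ** 2
            patterns[k] = np.where(in_cell, np.exp(-r2 / (2.0 * sigma**2)), 0.0)
    return patterns


def generate_synthetic_dataset(spec: SyntheticSpec):
    """Balanced labelled image set, deterministic for a given seed.

    Each sample is its class pattern plus i.i.d. Gaussian pixel noise,
    clipped to ``[0, 1]``.  Returns ``(images, labels)`` with images of
    shape ``(n, h, w)`` in a seed-determined shuffled order.
    """
    patterns = class_patterns(spec)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_classes * spec.samples_per_class
    h, w = spec.image_size
    images = np.repeat(patterns, spec.samples_per_class, axis=0)
    labels = np.repeat(np.arange(spec.n_classes), spec.samples_per_class)
    if spec.noise_std > 0:
        images = images + rng.normal(0.0, spec.noise_std, size=(n, h, w))
        images = np.clip(images, 0.0, 1.0)
    else:
        images = images.copy()
    order = rng.permutation(n)
    return images[order], labels[order]


# ---------------------------------------------------------------------------
# IDX container
# ---------------------------------------------------------------------------

_IDX_UBYTE = 0x08


def write_idx(array: np.ndarray, path) -> None:
    """Write an unsigned-byte tensor in IDX format (big-endian header)."""
    arr = np.asarray(array)
    if arr.dtype != np.uint8:
        if not np.issubdtype(arr.dtype, np.integer) or arr.min() < 0 or arr.max() > 255:
            raise ValueError("IDX writer supports unsigned-byte data (0..255)")
        arr = arr.astype(np.uint8)
    if arr.ndim < 1 or arr.ndim > 255:
        raise ValueError(f"unsupported dimensionality {arr.ndim}")
    with open(path, "wb") as fh:
        fh.write(struct.pack(">BBBB", 0, 0, _IDX_UBYTE, arr.ndim))
        for d in arr.shape:
            fh.write(struct.pack(">I", d))
        fh.write(arr.tobytes())


def read_idx(path) -> np.ndarray:
    """Read an IDX file; errors name the byte offset of the problem."""
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < 4:
        raise FormatError(f"{path}: truncated header at offset {len(data)} (need 4 bytes)")
    zero0, zero1, dtype_code, ndim = struct.unpack(">BBBB", data[:4])
    if zero0 != 0 or zero1 != 0:
        raise FormatError(f"{path}: bad magic at offset 0: {data[:4].hex()}")
    if dtype_code != _IDX_UBYTE:
        raise FormatError(
            f"{path}: unsupported element type 0x{dtype_code:02x} at offset 2"
        )
    header_len = 4 + 4 * ndim
    if len(data) < header_len:
        raise FormatError(
            f"{path}: truncated dimension table at offset {len(data)} "
            f"(need {header_len} bytes)"
        )
    dims = struct.unpack(f">{ndim}I", data[4:header_len])
    n_items = int(np.prod(dims, dtype=np.int64)) if dims else 1
    if len(data) < header_len + n_items:
        raise FormatError(
            f"{path}: file ends at offset {len(data)} but header promises "
            f"{header_len + n_items} bytes"
        )
    return np.frombuffer(
        data, dtype=np.uint8, count=n_items, offset=header_len
    ).reshape(dims).copy()


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(params: NetworkParams, arch: ArchSpec, cfg, path,
                    stage: str = "pretrain", epoch: int = 0, seed: int = 0) -> None:
    """Persist weights, thresholds, and run metadata to a ``.npz`` archive.

    ``cfg`` may be a dict or any object with a ``to_dict`` method; it is
    stored as JSON so the archive is self-describing.
    """
    if hasattr(cfg, "to_dict"):
        cfg = cfg.to_dict()
    payload = {
        "version": np.array(CHECKPOINT_VERSION),
        "arch": np.array(arch.text),
        "input_shape": np.array(arch.input_shape),
        "leak": np.array(params.leak),
        "stage": np.array(stage),
        "epoch": np.array(int(epoch)),
        "seed": np.array(int(seed)),
        "config": np.array(json.dumps(cfg if cfg is not None else {})),
    }
    for i, wgt in enumerate(params.weights):
        if wgt is not None:
            payload[f"w{i}"] = wgt
    for i, th in enumerate(params.thresholds):
        if th is not None:
            payload[f"th{i}"] = th
    np.savez(path, **payload)


def load_checkpoint(path):
    """Load a checkpoint; returns ``(params, arch, meta)``.

    ``meta`` holds ``stage``, ``epoch``, ``seed``, and the stored ``config``
    dict.  Round-tripping through ``save_checkpoint`` reproduces weights and
    thresholds bit for bit.
    """
    try:
        with np.load(path, allow_pickle=False) as archive:
            files = dict(archive)
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt zip / bad npz
        raise FormatError(f"{path}: unreadable checkpoint archive ({exc})") from exc
    if "version" not in files:
        raise FormatError(f"{path}: not a checkpoint archive (no version field)")
    version = int(files["version"])
    if version != CHECKPOINT_VERSION:
        raise FormatError(
            f"{path}: checkpoint version {version} != supported {CHECKPOINT_VERSION}"
        )
    arch = parse_arch(str(files["arch"]), tuple(int(d) for d in files["input_shape"]))
    weights = [files.get(f"w{i}") for i in range(len(arch.layers))]
    thresholds = [files.get(f"th{i}") for i in range(len(arch.layers))]
    params = NetworkParams(weights=weights, thresholds=thresholds,
                           leak=float(files["leak"]))
    meta = {
        "stage": str(files["stage"]),
        "epoch": int(files["epoch"]),
        "seed": int(files["seed"]),
        "config": json.loads(str(files["config"])),
    }
    return params, arch, meta
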