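"""Similarity analysis of binary spiking feature maps (SFmaps).

A dual-threshold convolutional layer derives two spike maps from each
membrane map; the maps differ only where the membrane falls between the two
thresholds, so each primary/secondary pair is highly similar.  This module
quantifies that similarity (Hamming agreement by default), extracts the
signed difference maps, and rescales trained threshold pairs so the primary
threshold reads 1 for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimilarityReport",
    "sfmap_similarity",
    "delta_sfmap",
    "normalize_thresholds",
    "save_map_grid",
]


@dataclass
class SimilarityReport:
    """Pairwise channel similarities of one spike-map stack.

    ``matrix[a, b]`` is the fraction of positions where channels ``a`` and
    ``b`` agree (symmetric, unit diagonal).  ``similar_pairs`` lists channel
    pairs at or above the cutoff, in descending similarity (ties broken by
    channel indices).
    """

    matrix: np.ndarray
    cutoff: float
    similar_pairs: list[tuple[int, int, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "matrix": self.matrix.tolist(),
            "similar_pairs": [
                {"a": a, "b": b, "similarity": s} for a, b, s in self.similar_pairs
            ],
        }


def _check_binary_stack(maps: np.ndarray) -> np.ndarray:
    maps = np.asarray(maps, dtype=np.float64)
    if maps.ndim < 2:
        raise ValueError("expected a (channels, ...) stack of maps")
    if not np.all((maps == 0.0) | (maps == 1.0)):
        raise ValueError("maps must be binary (0/1)")
    return maps.reshape(maps.shape[0], -1)


def sfmap_similarity(maps: np.ndarray, cutoff: float = 0.9,
                     metric: str = "hamming") -> SimilarityReport:
    """Pairwise similarity between the channels of a binary map stack.

    ``hamming`` similarity is the fraction of agreeing positions; it is
    defined for all-zero maps (common early in training), unlike ``jaccard``
    (intersection over union of the spiking positions), which is also
    available and treats two empty maps as identical.
    """
    flat = _check_binary_stack(maps)
    c = flat.shape[0]
    if c < 2:
        raise ValueError("need at least two channels")
    if metric == "hamming":
        # agreement = 1 - mean |a - b|
        diff = np.abs(flat[:, None, :] - flat[None, :, :]).mean(axis=2)
        mat = 1.0 - diff
    elif metric == "jaccard":
        inter = np.minimum(flat[:, None, :], flat[None, :, :]).sum(axis=2)
        union = np.maximum(flat[:, None, :], flat[None, :, :]).sum(axis=2)
        with np.errstate(invalid="ignore"):
            mat = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    pairs = [
        (a, b, float(mat[a, b]))
        for a in range(c)
        for b in range(a + 1, c)
        if mat[a, b] >= cutoff
    ]
    pairs.sort(key=lambda p: (-p[2], p[0], p[1]))
    return SimilarityReport(matrix=mat, cutoff=cutoff, similar_pairs=pairs)


def delta_sfmap(map_a: np.ndarray, map_b: np.ndarray) -> np.ndarray:
    """Signed elementwise difference of two binary maps (values -1, 0, +1)."""
    a = np.asarray(map_a, dtype=np.float64)
    b = np.asarray(map_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    for m, name in ((a, "map_a"), (b, "map_b")):
        if not np.all((m == 0.0) | (m == 1.0)):
            raise ValueError(f"{name} must be binary (0/1)")
    return a - b


def normalize_thresholds(pairs) -> list[tuple[float, float]]:
    """Rescale each (vth0, vth1) pair so the resetting threshold reads 1.

    Dividing both members by vth0 leaves the spike maps of the pair invariant
    up to this common scale and makes trained pairs comparable across layers.
    Ratios above 1 are legal: training can push the secondary threshold
    either side of the primary one.
    """
    out = []
    for vth0, vth1 in pairs:
        if vth0 <= 0:
            raise ValueError(f"primary threshold must be positive, got {vth0}")
        out.append((1.0, float(vth1) / float(vth0)))
    return out


def save_map_grid(maps: np.ndarray, path, ncols: int = 8, titles=None) -> None:
    """Write a grid of spike maps as an image file for visual inspection."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    maps = np.asarray(maps, dtype=np.float64)
    n = maps.shape[0]
    ncols = min(ncols, n)
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(1.2 * ncols, 1.2 * nrows),
                             squeeze=False)
    for i in range(nrows * ncols):
        ax = axes[i // ncols][i % ncols]
        ax.axis("off")
        if i < n:
            ax.imshow(maps[i], cmap="gray", vmin=min(0.0, maps[i].min()), vmax=1.0)
            if titles is not None:
                ax.set_title(str(titles[i]), fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
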