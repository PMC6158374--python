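"""Interpretability: capsule-dimension perturbation sweeps and
gradient-based voxel-to-feature attribution.

A sweep decodes a capsule with one dimension offset over a range of deltas,
showing which image property that dimension controls. Attribution is the
Jacobian of the mapper's predicted capsule dimensions with respect to its
voxel inputs, reported as magnitudes (voxels x 32).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .capsnet import CapsNetModel
from .mapper import MapperModel

__all__ = ["PerturbationSweep", "AttributionMap", "perturb_dimension", "attribute_voxels"]


@dataclass
class PerturbationSweep:
    dimension: int
    deltas: np.ndarray
    images: np.ndarray           # (len(deltas), 28, 28), in delta order
    label: str = ""              # free-text name, e.g. "orientation"


def perturb_dimension(
    capsule: np.ndarray,
    dim: int,
    capsnet: CapsNetModel,
    deltas=None,
    label: str = "",
) -> PerturbationSweep:
    """Decode `capsule` with `capsule[dim] + delta` for each delta.

    Default deltas run from -0.5 to +0.5 in steps of 0.1. The input capsule
    is left untouched; a zero delta reproduces the plain reconstruction
    exactly.
    """
    c = np.asarray(capsule, dtype=np.float64)
    if c.shape != (capsnet.config.digit_dim,):
        raise ValueError(f"expected a {capsnet.config.digit_dim}-D capsule, got {c.shape}")
    if not 0 <= dim < c.size:
        raise ValueError(f"dimension {dim} out of range [0, {c.size})")
    d = np.arange(-0.5, 0.5001, 0.1) if deltas is None else np.asarray(deltas, dtype=np.float64)
    batch = np.repeat(c[None], d.size, axis=0)
    batch[:, dim] += d
    images = capsnet.decode(batch).data
    return PerturbationSweep(dimension=dim, deltas=d, images=images, label=label)


@dataclass
class AttributionMap:
    values: np.ndarray           # (n_voxels, 32) gradient magnitudes
    raw: np.ndarray              # signed Jacobian, same shape
    normalization: str = "none"

    def normalized(self) -> np.ndarray:
        """Per-dimension max scaling for display; raw values are retained."""
        peak = self.values.max(axis=0, keepdims=True)
        return self.values / np.where(peak == 0.0, 1.0, peak)


def _mapper_jacobian(mapper: MapperModel, x: np.ndarray,
                     activations: str, presquash: bool) -> np.ndarray:
    """Jacobian d(output 32-vector)/d(input voxels), analytic."""
    w1, b1 = mapper.w1.data, mapper.b1.data
    w2, b2 = mapper.w2.data, mapper.b2.data
    w3, b3 = mapper.w3.data, mapper.b3.data
    a1 = x @ w1 + b1
    h1 = np.maximum(a1, 0.0) if activations == "relu" else a1
    a2 = h1 @ w2 + b2
    h2 = np.maximum(a2, 0.0) if activations == "relu" else a2
    out = h2 @ w3 + b3                                   # (32,)

    J = w1.copy()                                        # (n_in, h1)
    if activations == "relu":
        J = J * (a1 > 0.0)
    J = J @ (w2 * (a2 > 0.0) if activations == "relu" else w2)
    J = J @ w3                                           # (n_in, 32)

    if presquash:
        return J
    # chain through the per-half squash: v = s * n/(1+n^2), n = |s|
    for h in range(2):
        s = out[16 * h: 16 * (h + 1)]
        n2 = float(s @ s)
        n = np.sqrt(n2)
        if n < 1e-12:
            S = np.zeros((16, 16))
        else:
            alpha = n / (1.0 + n2)
            dalpha = (1.0 - n2) / (1.0 + n2) ** 2
            S = alpha * np.eye(16) + (dalpha / n) * np.outer(s, s)
        J[:, 16 * h: 16 * (h + 1)] = J[:, 16 * h: 16 * (h + 1)] @ S.T
    return J


def attribute_voxels(
    mapper: MapperModel,
    voxel_input: np.ndarray,
    average_over: np.ndarray | None = None,
    activations: str = "relu",
    presquash: bool = False,
) -> AttributionMap:
    """Gradient of each predicted capsule dimension w.r.t. each voxel.

    `voxel_input` is the linearisation point (e.g. the training-set mean
    voxel vector); pass `average_over` (n, voxels) to average magnitudes
    over many inputs instead. `activations="identity"` bypasses the
    rectifiers and, together with `presquash=True`, makes the map the exact
    product of the three weight matrices.
    """
    if average_over is not None:
        maps = [
            _mapper_jacobian(mapper, np.asarray(x, dtype=np.float64),
                             activations, presquash)
            for x in np.atleast_2d(average_over)
        ]
        raw = np.mean(maps, axis=0)
        values = np.mean([np.abs(m) for m in maps], axis=0)
    else:
        x = np.asarray(voxel_input, dtype=np.float64).ravel()
        if x.size != mapper.n_inputs:
            raise ValueError(f"expected {mapper.n_inputs} voxels, got {x.size}")
        raw = _mapper_jacobian(mapper, x, activations, presquash)
        values = np.abs(raw)
    return AttributionMap(values=values, raw=raw)


def save_sweep_strip(path, sweep: PerturbationSweep):
    """PNG strip of a sweep's reconstructions, left (-) to right (+)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = len(sweep.deltas)
    fig, axes = plt.subplots(1, m, figsize=(1.0 * m, 1.3))
    for ax, img, d in zip(np.atleast_1d(axes), sweep.images, sweep.deltas):
        ax.imshow(img, cmap="gray", vmin=0, vmax=1)
        ax.set_xticks([])
        ax.set_yticks([])
        ax.set_title(f"{d:+.1f}", fontsize=6)
    name = sweep.label or f"dim {sweep.dimension}"
    fig.suptitle(name, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_attribution_heatmap(path, amap: AttributionMap):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 8))
    im = ax.imshow(amap.normalized(), aspect="auto", cmap="viridis")
    ax.set_xlabel("capsule dimension")
    ax.set_ylabel("selected voxel")
    fig.colorbar(im, ax=ax, label="|gradient| (per-dimension scaled)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
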