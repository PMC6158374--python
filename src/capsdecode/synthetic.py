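"""Synthetic stimuli and fMRI-like voxel responses.

Generates digit-like 28x28 glyphs ('6' = circle with an upward tail, '9' =
the same shape rotated half a turn, giving a downward tail) and voxel
response matrices that are a noisy linear function of 16-dimensional capsule
features on a known subset of voxels. Ground truth (encoding weights,
informative indices, per-voxel noise scale) is carried along so downstream
stages can be validated by parameter recovery.

Also provides an IDX-format reader/writer for real digit archives and a
stratified k-fold splitter.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field

import numpy as np

IMAGE_SIZE = 28
N_FEATURES = 16

_IDX_MAGIC_IMAGES = 0x00000803
_IDX_MAGIC_LABELS = 0x00000801


# ---------------------------------------------------------------------------
# Glyph rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlyphParams:
    """Pose parameters of one rendered glyph."""

    label: int                      # 6 or 9
    orientation: float = 0.0        # radians, about the glyph centre
    scale: float = 1.0
    stroke_width: float = 2.0       # pixels
    circle_radius: float = 6.0      # pixels, before scaling
    translation: tuple[float, float] = (0.0, 0.0)
    tail_length: float = 9.0        # pixels, before scaling

    def __post_init__(self):
        if self.label not in (6, 9):
            raise ValueError(f"label must be 6 or 9, got {self.label}")


DEFAULT_PARAM_RANGES: dict[str, tuple[float, float]] = {
    "orientation": (-0.3, 0.3),
    "scale": (0.75, 1.0),
    "stroke_width": (1.6, 2.4),
    "circle_radius": (4.5, 5.5),
    "translation": (-1.0, 1.0),
    "tail_length": (6.5, 8.5),
}

_AA = 0.8      # anti-aliasing falloff width, pixels
_CIRCLE_Y = 3.0  # circle centre offset below the glyph origin, canonical pose


def _glyph_geometry(p: GlyphParams):
    """Circle centre and tail segment endpoints in glyph coordinates."""
    a = np.array([p.circle_radius * np.cos(-0.9),
                  _CIRCLE_Y + p.circle_radius * np.sin(-0.9)])
    b = a + np.array([1.2, -(p.tail_length - 1.0)])
    return np.array([0.0, _CIRCLE_Y]), a, b


def _glyph_extent(p: GlyphParams) -> float:
    """Radius of the smallest centred disc containing the rendered glyph."""
    centre, a, b = _glyph_geometry(p)
    reach = max(np.hypot(*centre) + p.circle_radius, np.hypot(*a), np.hypot(*b))
    return reach * p.scale + p.stroke_width / 2.0 + _AA


def _check_in_frame(p: GlyphParams):
    cx = (IMAGE_SIZE - 1) / 2.0 + p.translation[0]
    cy = (IMAGE_SIZE - 1) / 2.0 + p.translation[1]
    r = _glyph_extent(p)
    if cx - r < 0 or cy - r < 0 or cx + r > IMAGE_SIZE - 1 or cy + r > IMAGE_SIZE - 1:
        raise ValueError(
            f"glyph with scale={p.scale:.3g}, circle_radius={p.circle_radius:.3g}, "
            f"tail_length={p.tail_length:.3g}, stroke_width={p.stroke_width:.3g}, "
            f"translation={p.translation} extends outside the 28x28 frame "
            f"(required half-extent {r:.2f})"
        )


def _segment_distance(px, py, ax, ay, bx, by):
    """Distance from points (px, py) to segment (a, b), vectorised."""
    vx, vy = bx - ax, by - ay
    L2 = vx * vx + vy * vy
    t = np.clip(((px - ax) * vx + (py - ay) * vy) / L2, 0.0, 1.0)
    dx = px - (ax + t * vx)
    dy = py - (ay + t * vy)
    return np.hypot(dx, dy)


def render_glyph(params: GlyphParams) -> np.ndarray:
    """Render one glyph to a 28x28 array of intensities in [0, 1].

    The canonical shape (before rotation) is a '6': a circular ring in the
    lower half with a tail rising from its upper-right. Class 9 adds a half
    turn so the tail points down-left.
    """
    _check_in_frame(params)
    p = params
    cx = (IMAGE_SIZE - 1) / 2.0 + p.translation[0]
    cy = (IMAGE_SIZE - 1) / 2.0 + p.translation[1]

    yy, xx = np.mgrid[0:IMAGE_SIZE, 0:IMAGE_SIZE].astype(np.float64)
    # rotate pixel grid into glyph coordinates (inverse rotation)
    theta = p.orientation + (np.pi if p.label == 9 else 0.0)
    ct, st = np.cos(-theta), np.sin(-theta)
    gx = (xx - cx) * ct - (yy - cy) * st
    gy = (xx - cx) * st + (yy - cy) * ct
    gx /= p.scale
    gy /= p.scale

    # circle centred below origin (y axis points down on screen); the tail
    # rises from the circle's upper-right rim
    centre, a, b = _glyph_geometry(p)
    ring = np.abs(np.hypot(gx - centre[0], gy - centre[1]) - p.circle_radius)
    tail = _segment_distance(gx, gy, a[0], a[1], b[0], b[1])

    dist = np.minimum(ring, tail) * p.scale
    half = p.stroke_width / 2.0
    img = np.clip((half + _AA - dist) / _AA, 0.0, 1.0)
    return img


# ---------------------------------------------------------------------------
# Stimulus sets
# ---------------------------------------------------------------------------

@dataclass
class StimulusImage:
    """A 28x28 grayscale stimulus with its class label."""

    pixels: np.ndarray
    label: int

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.shape != (IMAGE_SIZE, IMAGE_SIZE):
            raise ValueError(f"expected 28x28 pixels, got {self.pixels.shape}")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("pixel intensities must lie in [0, 1]")


def generate_digits(
    n: int,
    class_mix: float = 0.5,
    param_ranges: dict[str, tuple[float, float]] | None = None,
    seed: int | None = None,
) -> list[StimulusImage]:
    """Generate `n` glyph stimuli; `class_mix` is the fraction of class 6.

    Deterministic for a fixed seed. Class counts are exact:
    round(n * class_mix) images of class 6, the rest class 9.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= class_mix <= 1.0:
        raise ValueError("class_mix must lie in [0, 1]")
    ranges = dict(DEFAULT_PARAM_RANGES)
    if param_ranges:
        ranges.update(param_ranges)
    rng = np.random.default_rng(seed)
    n6 = int(round(n * class_mix))
    labels = np.array([6] * n6 + [9] * (n - n6))
    rng.shuffle(labels)
    out = []
    for lab in labels:
        p = GlyphParams(
            label=int(lab),
            orientation=rng.uniform(*ranges["orientation"]),
            scale=rng.uniform(*ranges["scale"]),
            stroke_width=rng.uniform(*ranges["stroke_width"]),
            circle_radius=rng.uniform(*ranges["circle_radius"]),
            translation=(rng.uniform(*ranges["translation"]),
                         rng.uniform(*ranges["translation"])),
            tail_length=rng.uniform(*ranges["tail_length"]),
        )
        out.append(StimulusImage(render_glyph(p), int(lab)))
    return out


def images_to_array(images: list[StimulusImage]) -> tuple[np.ndarray, np.ndarray]:
    """Stack stimuli into (n, 28, 28) pixels and (n,) labels."""
    px = np.stack([im.pixels for im in images])
    lab = np.array([im.label for im in images])
    return px, lab


# ---------------------------------------------------------------------------
# Voxel response simulation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    """A generated stimulus/voxel dataset with its ground truth."""

    images: list[StimulusImage]
    voxels: np.ndarray               # (n_stimuli, n_voxels)
    true_capsules: np.ndarray        # (n_stimuli, 16) features that drove voxels
    encoding_weights: np.ndarray     # (16, n_voxels); zero columns = uninformative
    intercepts: np.ndarray           # (n_voxels,)
    informative_idx: np.ndarray      # sorted indices of informative voxels
    noise_sd: np.ndarray             # (n_voxels,)
    seed: int | None
    labels: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.labels is None and self.images:
            self.labels = np.array([im.label for im in self.images])

    @property
    def n_stimuli(self) -> int:
        return self.voxels.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.voxels.shape[1]


def generate_fmri(
    true_capsules: np.ndarray,
    n_voxels: int,
    n_informative: int,
    snr_r2: float,
    seed: int | None = None,
    images: list[StimulusImage] | None = None,
    encoding_weights: np.ndarray | None = None,
    uninformative_sd: float = 1.0,
    calibration: str = "population",
) -> SyntheticStudy:
    """Simulate voxel responses linear in 16 capsule features.

    Informative voxels get per-voxel Gaussian noise calibrated so their
    population R^2 against the features equals `snr_r2`; the remaining
    voxels are pure noise with zero encoding weights. `snr_r2 = 1` yields
    exact linear responses. Pass `encoding_weights` (16 x n_voxels, zero
    outside the informative set) to plant a specific structure.

    An in-sample OLS R^2 overshoots the population value by roughly
    (1 - R^2) * 16 / (n - 1); `calibration="insample"` lowers the noise
    target so the *expected in-sample* R^2 at this n equals `snr_r2`.
    """
    C = np.asarray(true_capsules, dtype=np.float64)
    n, f = C.shape
    if f != N_FEATURES:
        raise ValueError(f"true_capsules must have {N_FEATURES} columns, got {f}")
    if n < 17:
        raise ValueError(
            f"need at least 17 stimuli to keep the downstream intercept "
            f"regression determined, got {n}"
        )
    if not 0.0 < snr_r2 <= 1.0:
        raise ValueError("snr_r2 must lie in (0, 1]")
    if n_informative > n_voxels:
        raise ValueError("n_informative cannot exceed n_voxels")
    if np.any(C.std(axis=0) < 1e-12):
        warnings.warn(
            "true_capsules has a zero-variance feature; its encoding weight "
            "is unidentifiable", RuntimeWarning, stacklevel=2,
        )
    rng = np.random.default_rng(seed)

    if encoding_weights is not None:
        W = np.asarray(encoding_weights, dtype=np.float64).copy()
        if W.shape != (N_FEATURES, n_voxels):
            raise ValueError(f"encoding_weights must be {N_FEATURES}x{n_voxels}")
        informative = np.flatnonzero(np.any(W != 0.0, axis=0))
        if n_informative != informative.size:
            raise ValueError(
                "n_informative disagrees with the nonzero columns of "
                "encoding_weights"
            )
    else:
        informative = np.sort(rng.choice(n_voxels, size=n_informative, replace=False))
        W = np.zeros((N_FEATURES, n_voxels))
        W[:, informative] = rng.normal(size=(N_FEATURES, n_informative))

    intercepts = rng.normal(scale=0.5, size=n_voxels)
    signal = C @ W + intercepts

    if calibration not in ("population", "insample"):
        raise ValueError("calibration must be 'population' or 'insample'")
    target = snr_r2
    if calibration == "insample" and snr_r2 < 1.0:
        optimism = N_FEATURES / (n - 1)
        target = max(1e-6, (snr_r2 - optimism) / (1.0 - optimism))
    noise_sd = np.full(n_voxels, float(uninformative_sd))
    sig_var = signal[:, informative].var(axis=0)
    if snr_r2 >= 1.0:
        noise_sd[informative] = 0.0
    else:
        noise_sd[informative] = np.sqrt(sig_var * (1.0 - target) / target)
    voxels = signal + rng.normal(size=(n, n_voxels)) * noise_sd

    return SyntheticStudy(
        images=images or [],
        voxels=voxels,
        true_capsules=C,
        encoding_weights=W,
        intercepts=intercepts,
        informative_idx=np.asarray(informative),
        noise_sd=noise_sd,
        seed=seed,
    )


def pseudo_capsule_features(n: int, seed: int | None = None) -> np.ndarray:
    """Random squashed-looking 16-D feature vectors (norms in (0, 1))."""
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, N_FEATURES))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * rng.uniform(0.3, 0.9, size=(n, 1))


def make_study(
    n_stimuli: int = 100,
    n_voxels: int = 3092,
    n_informative: int = 50,
    snr_r2: float = 0.9,
    seed: int | None = None,
    capsule_features: np.ndarray | None = None,
    calibration: str = "population",
) -> SyntheticStudy:
    """Convenience: glyph stimuli plus simulated voxels in one call.

    If `capsule_features` is not given, surrogate 16-D features are drawn at
    random; pass features from a trained capsule network for end-to-end runs.
    """
    images = generate_digits(n_stimuli, class_mix=0.5, seed=seed)
    feats = (
        pseudo_capsule_features(n_stimuli, seed=seed)
        if capsule_features is None
        else np.asarray(capsule_features, dtype=np.float64)
    )
    return generate_fmri(
        feats, n_voxels, n_informative, snr_r2, seed=seed, images=images,
        calibration=calibration,
    )


# ---------------------------------------------------------------------------
# IDX archive format
# ---------------------------------------------------------------------------

def read_idx(path) -> list[StimulusImage]:
    """Read an IDX image archive (unsigned byte, 3 dimensions)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 4:
        raise ValueError(f"{path}: truncated IDX header at offset 0")
    (magic,) = struct.unpack(">I", raw[:4])
    if magic != _IDX_MAGIC_IMAGES:
        raise ValueError(
            f"{path}: bad magic number 0x{magic:08x} at offset 0 "
            f"(expected 0x{_IDX_MAGIC_IMAGES:08x})"
        )
    if len(raw) < 16:
        raise ValueError(f"{path}: truncated dimension header at offset 4")
    n, rows, cols = struct.unpack(">III", raw[4:16])
    expected = 16 + n * rows * cols
    if len(raw) < expected:
        raise ValueError(
            f"{path}: payload short at offset {len(raw)} "
            f"(header promises {expected} bytes)"
        )
    data = np.frombuffer(raw[16:expected], dtype=np.uint8)
    data = data.reshape(n, rows, cols).astype(np.float64) / 255.0
    if (rows, cols) != (IMAGE_SIZE, IMAGE_SIZE):
        raise ValueError(f"{path}: expected 28x28 images, got {rows}x{cols}")
    return [StimulusImage(img, label=6) for img in data]


def write_idx(path, images: list[StimulusImage]):
    """Write stimuli as an IDX archive with 8-bit quantisation."""
    px, _ = images_to_array(images)
    quant = np.round(px * 255.0).astype(np.uint8)
    n, rows, cols = quant.shape
    with open(path, "wb") as fh:
        fh.write(struct.pack(">IIII", _IDX_MAGIC_IMAGES, n, rows, cols))
        fh.write(quant.tobytes())


def read_idx_labels(path) -> np.ndarray:
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 8:
        raise ValueError(f"{path}: truncated IDX label header")
    magic, n = struct.unpack(">II", raw[:8])
    if magic != _IDX_MAGIC_LABELS:
        raise ValueError(f"{path}: bad magic number 0x{magic:08x} at offset 0")
    if len(raw) < 8 + n:
        raise ValueError(f"{path}: label payload short at offset {len(raw)}")
    return np.frombuffer(raw[8:8 + n], dtype=np.uint8).astype(int)


def write_idx_labels(path, labels):
    labels = np.asarray(labels, dtype=np.uint8)
    with open(path, "wb") as fh:
        fh.write(struct.pack(">II", _IDX_MAGIC_LABELS, labels.size))
        fh.write(labels.tobytes())


# ---------------------------------------------------------------------------
# Cross-validation folds
# ---------------------------------------------------------------------------

def split_folds(
    n: int,
    k: int,
    labels: np.ndarray | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Assign each of `n` items to one of `k` folds (stratified if labelled).

    Returns an integer array of fold ids in [0, k). Folds are disjoint and
    exhaustive; with labels, each class is dealt round-robin so per-fold
    class counts differ by at most one.
    """
    if k > n:
        raise ValueError(f"cannot split {n} items into {k} folds")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    if labels is None:
        order = rng.permutation(n)
        assignment[order] = np.arange(n) % k
    else:
        labels = np.asarray(labels)
        offset = 0
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            idx = rng.permutation(idx)
            assignment[idx] = (np.arange(idx.size) + offset) % k
            offset += idx.size
    return assignment
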