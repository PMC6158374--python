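"""Capsule network: convolutional features, primary capsules, dynamic
routing by agreement to two 16-D class capsules, margin loss, and a
fully connected reconstruction decoder trained jointly.

Shapes at the reference configuration (28x28 input): Conv1 gives 256 maps
of 20x20, the primary convolution 32 maps x 8 channels at 6x6, i.e. 1152
8-D capsules, routed to one 16-D capsule per class.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Adam, Tensor, conv2d, softmax, squash

__all__ = [
    "CapsNetConfig",
    "CapsNetModel",
    "MarginLossConfig",
    "dynamic_routing",
    "margin_loss",
    "overall_loss",
    "train_capsnet",
    "scaled_config",
]


@dataclass(frozen=True)
class MarginLossConfig:
    m_plus: float = 0.9
    m_minus: float = 0.1
    lambda_down: float = 0.5

    def __post_init__(self):
        if not 0.0 < self.m_minus < self.m_plus < 1.0:
            raise ValueError("require 0 < m_minus < m_plus < 1")


@dataclass(frozen=True)
class CapsNetConfig:
    image_size: int = 28
    conv1_channels: int = 256
    conv1_kernel: int = 9
    conv1_stride: int = 1
    primary_maps: int = 32
    primary_dim: int = 8
    primary_kernel: int = 9
    primary_stride: int = 2
    n_classes: int = 2
    digit_dim: int = 16
    routing_iters: int = 3
    decoder_hidden: tuple[int, int] = (512, 1024)
    recon_weight: float = 4.0         # mu in the overall loss
    margin: MarginLossConfig = field(default_factory=MarginLossConfig)
    w_init_sigma: float = 0.1

    @property
    def conv1_size(self) -> int:
        return (self.image_size - self.conv1_kernel) // self.conv1_stride + 1

    @property
    def primary_size(self) -> int:
        return (self.conv1_size - self.primary_kernel) // self.primary_stride + 1

    @property
    def n_primary(self) -> int:
        return self.primary_maps * self.primary_size ** 2


def scaled_config(**overrides) -> CapsNetConfig:
    """A reduced-width configuration for desk-scale training runs."""
    base = dict(conv1_channels=32, primary_maps=8, decoder_hidden=(256, 512))
    base.update(overrides)
    return CapsNetConfig(**base)


class CapsNetModel:
    """Holds all trainable parameters and implements the forward pass."""

    def __init__(self, config: CapsNetConfig | None = None, seed: int | None = None):
        self.config = cfg = config or CapsNetConfig()
        rng = np.random.default_rng(seed)

        def conv_init(out_c, in_c, k):
            fan_in = in_c * k * k
            return Tensor(rng.normal(scale=np.sqrt(2.0 / fan_in),
                                     size=(out_c, in_c, k, k)), requires_grad=True)

        def dense_init(n_in, n_out):
            w = Tensor(rng.normal(scale=np.sqrt(2.0 / n_in), size=(n_in, n_out)),
                       requires_grad=True)
            b = Tensor(np.zeros(n_out), requires_grad=True)
            return w, b

        self.conv1_w = conv_init(cfg.conv1_channels, 1, cfg.conv1_kernel)
        self.conv1_b = Tensor(np.zeros(cfg.conv1_channels), requires_grad=True)
        pc_out = cfg.primary_maps * cfg.primary_dim
        self.conv2_w = conv_init(pc_out, cfg.conv1_channels, cfg.primary_kernel)
        self.conv2_b = Tensor(np.zeros(pc_out), requires_grad=True)
        # routing transforms W_ij: one (digit_dim x primary_dim) matrix per
        # (lower capsule i, class capsule j) pair
        self.W = Tensor(
            rng.normal(scale=cfg.w_init_sigma,
                       size=(cfg.n_primary, cfg.n_classes, cfg.digit_dim, cfg.primary_dim)),
            requires_grad=True,
        )
        h1, h2 = cfg.decoder_hidden
        n_px = cfg.image_size ** 2
        self.dec1_w, self.dec1_b = dense_init(cfg.digit_dim, h1)
        self.dec2_w, self.dec2_b = dense_init(h1, h2)
        self.dec3_w, self.dec3_b = dense_init(h2, n_px)

    def parameters(self) -> list[Tensor]:
        return [self.conv1_w, self.conv1_b, self.conv2_w, self.conv2_b, self.W,
                self.dec1_w, self.dec1_b, self.dec2_w, self.dec2_b,
                self.dec3_w, self.dec3_b]

    def state_dict(self) -> dict[str, np.ndarray]:
        names = ["conv1_w", "conv1_b", "conv2_w", "conv2_b", "W",
                 "dec1_w", "dec1_b", "dec2_w", "dec2_b", "dec3_w", "dec3_b"]
        return {n: getattr(self, n).data.copy() for n in names}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for name, arr in state.items():
            getattr(self, name).data[...] = arr

    # -- forward pieces -------------------------------------------------------

    def _as_batch(self, images) -> Tensor:
        x = np.asarray(images, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        s = self.config.image_size
        if x.shape[-2:] != (s, s):
            raise ValueError(
                f"expected {s}x{s} input images, got {x.shape[-2]}x{x.shape[-1]}"
            )
        return Tensor(x[:, None, :, :])  # (B, 1, H, W)

    def forward_conv1(self, images) -> Tensor:
        x = self._as_batch(images)
        return conv2d(x, self.conv1_w, self.conv1_b,
                      stride=self.config.conv1_stride).relu()

    def forward_primary(self, images) -> Tensor:
        """Primary capsule grid, squashed: (B, n_primary, primary_dim)."""
        cfg = self.config
        h = self.forward_conv1(images)
        g = conv2d(h, self.conv2_w, self.conv2_b, stride=cfg.primary_stride)
        B = g.shape[0]
        side = cfg.primary_size
        u = (g.reshape(B, cfg.primary_maps, cfg.primary_dim, side, side)
              .transpose(0, 1, 3, 4, 2)
              .reshape(B, cfg.n_primary, cfg.primary_dim))
        return squash(u, axis=-1)

    def predictions(self, u: Tensor) -> Tensor:
        """Prediction vectors u_hat_{j|i} = W_ij u_i: (B, N, J, digit_dim)."""
        cfg = self.config
        B = u.shape[0]
        ue = u.reshape(B, cfg.n_primary, 1, cfg.primary_dim, 1)
        return (self.W @ ue).reshape(B, cfg.n_primary, cfg.n_classes, cfg.digit_dim)

    def route(self, u_hat: Tensor, iterations: int | None = None):
        iters = self.config.routing_iters if iterations is None else iterations
        return dynamic_routing(u_hat, iterations=iters)

    def forward(self, images, iterations: int | None = None):
        """Full pass: images -> (digit capsules v, couplings, primary caps)."""
        u = self.forward_primary(images)
        u_hat = self.predictions(u)
        v, c = self.route(u_hat, iterations)
        return v, c, u

    def decode(self, capsule) -> Tensor:
        """Reconstruct images from 16-D capsules: (B, 16) -> (B, 28, 28)."""
        cfg = self.config
        z = capsule if isinstance(capsule, Tensor) else Tensor(np.atleast_2d(capsule))
        if z.ndim == 1:
            z = z.reshape(1, -1)
        if z.shape[-1] != cfg.digit_dim:
            raise ValueError(
                f"decoder expects {cfg.digit_dim}-D capsules, got {z.shape[-1]}"
            )
        h = (z @ self.dec1_w + self.dec1_b).relu()
        h = (h @ self.dec2_w + self.dec2_b).relu()
        out = (h @ self.dec3_w + self.dec3_b).sigmoid()
        B = z.shape[0]
        return out.reshape(B, cfg.image_size, cfg.image_size)

    # -- inference ------------------------------------------------------------

    def capsule_lengths(self, v: Tensor) -> np.ndarray:
        return np.linalg.norm(v.data, axis=-1)

    def classify(self, images) -> np.ndarray:
        """Predicted class index per image: argmax of capsule norm."""
        v, _, _ = self.forward(images)
        return self.capsule_lengths(v).argmax(axis=1)


# ---------------------------------------------------------------------------
# Routing
# ---------------------------------------------------------------------------

def dynamic_routing(u_hat, iterations: int = 3, trace: list | None = None):
    """Dynamic routing by agreement over prediction vectors.

    `u_hat`: (B, N, J, D) predictions of N lower capsules for J upper
    capsules. Logits start at zero; couplings are the softmax of the logits
    over the upper capsules for each lower capsule; s_j is the coupling-
    weighted sum of predictions and v_j its squash; logits are refined by
    the scalar agreement u_hat . v.

    Returns (v, couplings) with v: (B, J, D) and the final (B, N, J)
    coupling coefficients. Pass a list as `trace` to capture per-iteration
    (logits, couplings, v) snapshots as plain arrays.
    """
    if iterations < 1:
        raise ValueError("routing needs at least one iteration")
    u = u_hat if isinstance(u_hat, Tensor) else Tensor(u_hat)
    if not np.all(np.isfinite(u.data)):
        raise FloatingPointError("non-finite prediction vectors entering routing")
    B, N, J, D = u.shape
    b = Tensor(np.zeros((B, N, J)))
    v = c = None
    for it in range(iterations):
        c = softmax(b, axis=2)
        s = (c.reshape(B, N, J, 1) * u).sum(axis=1)
        v = squash(s, axis=-1)
        if trace is not None:
            trace.append((b.data.copy(), c.data.copy(), v.data.copy()))
        if it < iterations - 1:
            agreement = (u * v.reshape(B, 1, J, D)).sum(axis=-1)
            b = b + agreement
    return v, c


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def margin_loss(v_lengths, targets, config: MarginLossConfig | None = None):
    """Per-class hinge-squared loss on capsule norms.

    sum_c [T_c max(0, m+ - |v_c|)^2 + lambda (1 - T_c) max(0, |v_c| - m-)^2],
    averaged over the batch when given 2-D input.
    """
    cfg = config or MarginLossConfig()
    L = v_lengths if isinstance(v_lengths, Tensor) else Tensor(v_lengths)
    T = np.asarray(targets, dtype=np.float64)
    if T.shape != L.shape:
        raise ValueError(f"targets shape {T.shape} != lengths shape {L.shape}")
    rows = np.atleast_2d(T)
    if not (np.all((rows == 0) | (rows == 1)) and np.all(rows.sum(axis=-1) == 1)):
        raise ValueError("targets must be one-hot over the classes")
    present = Tensor(T) * (Tensor(cfg.m_plus) - L).relu() ** 2
    absent = Tensor(cfg.lambda_down * (1.0 - T)) * (L - cfg.m_minus).relu() ** 2
    per_sample = (present + absent).sum(axis=-1)
    return per_sample.mean() if per_sample.ndim else per_sample


def overall_loss(margin, image, reconstruction, mu: float = 4.0):
    """Classification margin loss plus mu times pixel-mean reconstruction MSE."""
    m = margin if isinstance(margin, Tensor) else Tensor(margin)
    img = image if isinstance(image, Tensor) else Tensor(image)
    rec = reconstruction if isinstance(reconstruction, Tensor) else Tensor(reconstruction)
    if img.shape != rec.shape:
        raise ValueError(f"image shape {img.shape} != reconstruction {rec.shape}")
    mse = ((rec - img) ** 2).mean()
    return m + mu * mse


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainTrace:
    epoch_loss: list[float] = field(default_factory=list)
    epoch_accuracy: list[float] = field(default_factory=list)


def train_capsnet(
    images: np.ndarray,
    labels: np.ndarray,
    config: CapsNetConfig | None = None,
    epochs: int = 20,
    batch_size: int = 10,
    learning_rate: float = 1e-3,
    seed: int | None = None,
    verbose: bool = False,
) -> tuple[CapsNetModel, TrainTrace]:
    """Train the capsule network end to end with Adam.

    The decoder is fed the target-class capsule during training (the joint
    objective of the overall loss); classification accuracy uses the
    longer-capsule rule. Labels are the raw class ids {6, 9}.
    """
    images = np.asarray(images, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("training requires at least two classes")
    cfg = config or CapsNetConfig()
    if classes.size != cfg.n_classes:
        raise ValueError(f"config expects {cfg.n_classes} classes, data has {classes.size}")
    y = np.searchsorted(classes, labels)           # class indices, label-sorted
    onehot = np.eye(cfg.n_classes)[y]

    rng = np.random.default_rng(seed)
    model = CapsNetModel(cfg, seed=rng.integers(2 ** 31))
    opt = Adam(model.parameters(), lr=learning_rate)
    trace = TrainTrace()
    n = images.shape[0]

    for epoch in range(epochs):
        order = rng.permutation(n)
        total = 0.0
        correct = 0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb, tb = images[idx], onehot[idx]
            v, _, _ = model.forward(xb)
            lengths = v.norm(axis=-1, eps=1e-12)
            m = margin_loss(lengths, tb, cfg.margin)
            # decoder sees the target-class capsule
            vk = (v * Tensor(tb[:, :, None])).sum(axis=1)
            rec = model.decode(vk)
            loss = overall_loss(m, Tensor(xb), rec, mu=cfg.recon_weight)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged (non-finite loss) at epoch {epoch}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(idx)
            correct += int((lengths.data.argmax(axis=1) == tb.argmax(axis=1)).sum())
        trace.epoch_loss.append(total / n)
        trace.epoch_accuracy.append(correct / n)
        if verbose:
            print(f"epoch {epoch + 1:3d}: loss={trace.epoch_loss[-1]:.4f} "
                  f"acc={trace.epoch_accuracy[-1]:.3f}")
    return model, trace


def config_to_dict(cfg: CapsNetConfig) -> dict:
    d = asdict(cfg)
    d["decoder_hidden"] = list(cfg.decoder_hidden)
    return d


def config_from_dict(d: dict) -> CapsNetConfig:
    d = dict(d)
    d["decoder_hidden"] = tuple(d["decoder_hidden"])
    d["margin"] = MarginLossConfig(**d["margin"])
    return CapsNetConfig(**d)
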