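"""Three-layer network mapping selected voxels to the two class capsules.

Layer widths 256 / 128 / 32; rectifiers on the first two layers, linear
output split into two 16-D halves that are each squashed. Trained with Adam
against the mean squared error to capsules from a frozen capsule network,
with L2 penalties on the first two weight matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor, squash

__all__ = ["MapperModel", "MapperTrainConfig", "train_mapper"]


@dataclass(frozen=True)
class MapperTrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 10
    iterations: int = 10_000
    l2_strength: float = 1e-3
    seed: int | None = None

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.iterations < 0:
            raise ValueError("learning_rate, batch_size must be positive; iterations >= 0")
        if self.l2_strength < 0:
            raise ValueError("l2_strength must be non-negative")


class MapperModel:
    """100 -> 256 -> 128 -> 32, output split into two squashed 16-D capsules.

    Output ordering is fixed by the capsule network's class order: half 0 is
    the lower class label ('6'), half 1 the higher ('9').
    """

    HIDDEN = (256, 128)
    OUT = 32

    def __init__(self, n_inputs: int = 100, seed: int | None = None,
                 hidden: tuple[int, int] | None = None):
        self.n_inputs = n_inputs
        h1, h2 = hidden or self.HIDDEN
        self.hidden = (h1, h2)
        rng = np.random.default_rng(seed)

        def dense(n_in, n_out):
            w = Tensor(rng.normal(scale=np.sqrt(2.0 / n_in), size=(n_in, n_out)),
                       requires_grad=True)
            b = Tensor(np.zeros(n_out), requires_grad=True)
            return w, b

        self.w1, self.b1 = dense(n_inputs, h1)
        self.w2, self.b2 = dense(h1, h2)
        self.w3, self.b3 = dense(h2, self.OUT)

    def parameters(self) -> list[Tensor]:
        return [self.w1, self.b1, self.w2, self.b2, self.w3, self.b3]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {n: getattr(self, n).data.copy()
                for n in ("w1", "b1", "w2", "b2", "w3", "b3")}

    def load_state_dict(self, state):
        for name, arr in state.items():
            getattr(self, name).data[...] = arr

    def forward(self, voxels) -> Tensor:
        """Predicted capsules as a Tensor of shape (B, 2, 16)."""
        x = voxels if isinstance(voxels, Tensor) else Tensor(np.atleast_2d(voxels))
        if x.ndim == 1:
            x = x.reshape(1, -1)
        if x.shape[-1] != self.n_inputs:
            raise ValueError(
                f"mapper expects {self.n_inputs} voxel inputs, got {x.shape[-1]}"
            )
        h = (x @ self.w1 + self.b1).relu()
        h = (h @ self.w2 + self.b2).relu()
        out = h @ self.w3 + self.b3
        caps = out.reshape(out.shape[0], 2, 16)
        return squash(caps, axis=-1)

    def predict_capsules(self, voxels: np.ndarray) -> np.ndarray:
        """Numpy convenience wrapper around `forward`."""
        return self.forward(voxels).data


@dataclass
class MapperTrace:
    iteration: list[int] = field(default_factory=list)
    train_mse: list[float] = field(default_factory=list)
    test_mse: list[float] = field(default_factory=list)


def _mse_objective(model: MapperModel, xb, yb, l2: float) -> Tensor:
    pred = model.forward(Tensor(xb))
    mse = ((pred - Tensor(yb)) ** 2).mean()
    if l2 > 0:
        mse = mse + l2 * ((model.w1 ** 2).sum() + (model.w2 ** 2).sum())
    return mse


def train_mapper(
    voxels: np.ndarray,
    true_capsules: np.ndarray,
    config: MapperTrainConfig | None = None,
    test_voxels: np.ndarray | None = None,
    test_capsules: np.ndarray | None = None,
    eval_every: int = 100,
) -> tuple[MapperModel, MapperTrace]:
    """Minimise MSE(predicted, true capsules) + L2 penalty with Adam.

    `voxels`: (n, k) selected voxel responses; `true_capsules`: (n, 2, 16)
    from the frozen capsule network. With `config.iterations == 0` the
    freshly initialised model is returned untouched.
    """
    cfg = config or MapperTrainConfig()
    X = np.asarray(voxels, dtype=np.float64)
    Y = np.asarray(true_capsules, dtype=np.float64)
    n = X.shape[0]
    if Y.shape != (n, 2, 16):
        raise ValueError(f"true_capsules must be (n, 2, 16), got {Y.shape}")
    if n < cfg.batch_size:
        raise ValueError(f"n={n} smaller than batch size {cfg.batch_size}")
    rng = np.random.default_rng(cfg.seed)
    model = MapperModel(n_inputs=X.shape[1], seed=rng.integers(2 ** 31))
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    trace = MapperTrace()

    for it in range(cfg.iterations):
        idx = rng.choice(n, size=cfg.batch_size, replace=False)
        loss = _mse_objective(model, X[idx], Y[idx], cfg.l2_strength)
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"mapper training diverged at iteration {it}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        if it % eval_every == 0 or it == cfg.iterations - 1:
            trace.iteration.append(it)
            trace.train_mse.append(float(((model.predict_capsules(X) - Y) ** 2).mean()))
            if test_voxels is not None:
                trace.test_mse.append(float(
                    ((model.predict_capsules(test_voxels) - test_capsules) ** 2).mean()
                ))
    return model, trace
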