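"""Per-voxel linear encoding from capsule features and R^2-based selection.

Each voxel is regressed (ordinary least squares with intercept) on the 16
components of the longer class capsule; voxels are ranked by in-sample
coefficient of determination and the top k retained. A separate
cross-validated evaluation reports out-of-fold prediction correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synthetic import split_folds

__all__ = [
    "EncodingFit",
    "VoxelSelection",
    "ZScorer",
    "longer_capsule_features",
    "fit_voxel_encoding",
    "select_top_k",
    "evaluate_encoding",
]


def longer_capsule_features(capsules: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pick the larger-norm capsule of each (2, 16) pair.

    Accepts (2, 16) or (n, 2, 16). Returns (features, chosen_index); exact
    norm ties resolve to index 0 (the lower class label).
    """
    c = np.asarray(capsules, dtype=np.float64)
    single = c.ndim == 2
    if single:
        c = c[None]
    if c.shape[1:] != (2, 16):
        raise ValueError(f"expected (n, 2, 16) capsules, got {c.shape}")
    norms = np.linalg.norm(c, axis=2)
    # strict ">" so a tie keeps index 0
    chosen = (norms[:, 1] > norms[:, 0]).astype(int)
    feats = c[np.arange(c.shape[0]), chosen]
    if single:
        return feats[0], chosen[0]
    return feats, chosen


@dataclass
class EncodingFit:
    """OLS weights (intercept first) and in-sample R^2 for every voxel."""

    weights: np.ndarray      # (17, n_voxels)
    r_squared: np.ndarray    # (n_voxels,)

    @property
    def n_voxels(self) -> int:
        return self.r_squared.size

    def predict(self, features: np.ndarray) -> np.ndarray:
        X = np.column_stack([np.ones(len(features)), features])
        return X @ self.weights


def fit_voxel_encoding(features: np.ndarray, voxels: np.ndarray) -> EncodingFit:
    """OLS with intercept for every voxel at once; R^2 = 1 - SS_res/SS_tot."""
    F = np.asarray(features, dtype=np.float64)
    Y = np.asarray(voxels, dtype=np.float64)
    n, p = F.shape
    if Y.shape[0] != n:
        raise ValueError(f"{n} feature rows but {Y.shape[0]} voxel rows")
    if n <= p + 1:
        raise ValueError(
            f"need more than {p + 1} samples to fit {p} features with "
            f"intercept, got {n}"
        )
    X = np.column_stack([np.ones(n), F])
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); "
            "minimum-norm solution used", RuntimeWarning, stacklevel=2,
        )
    resid = Y - X @ beta
    ss_res = (resid ** 2).sum(axis=0)
    ss_tot = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    const = ss_tot <= 1e-300
    if np.any(const):
        warnings.warn(
            f"{int(const.sum())} constant voxel(s); their R^2 is set to 0",
            RuntimeWarning, stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(const, 0.0, 1.0 - ss_res / np.where(const, 1.0, ss_tot))
    return EncodingFit(weights=beta, r_squared=r2)


@dataclass
class VoxelSelection:
    """Top-k voxels by encoding R^2 (ties broken by ascending index)."""

    ranked_indices: np.ndarray   # all voxels, best first
    k: int

    @property
    def indices(self) -> np.ndarray:
        return self.ranked_indices[: self.k]

    @property
    def mask(self) -> np.ndarray:
        m = np.zeros(self.ranked_indices.size, dtype=bool)
        m[self.indices] = True
        return m

    def apply(self, voxels: np.ndarray) -> np.ndarray:
        return np.asarray(voxels)[..., self.indices]


def select_top_k(fit: EncodingFit, k: int = 100) -> VoxelSelection:
    if k > fit.n_voxels:
        raise ValueError(f"k={k} exceeds the {fit.n_voxels} available voxels")
    order = np.lexsort((np.arange(fit.n_voxels), -fit.r_squared))
    return VoxelSelection(ranked_indices=order, k=k)


@dataclass
class ZScorer:
    """Per-voxel standardisation with statistics frozen on the training fold."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, voxels: np.ndarray) -> "ZScorer":
        v = np.asarray(voxels, dtype=np.float64)
        sd = v.std(axis=0)
        return cls(mean=v.mean(axis=0), sd=np.where(sd == 0.0, 1.0, sd))

    def transform(self, voxels: np.ndarray) -> np.ndarray:
        return (np.asarray(voxels, dtype=np.float64) - self.mean) / self.sd


def evaluate_encoding(
    features: np.ndarray,
    voxels: np.ndarray,
    selection: VoxelSelection | np.ndarray | None = None,
    folds: int = 10,
    seed: int | None = None,
    labels: np.ndarray | None = None,
) -> dict:
    """Out-of-fold prediction correlation per voxel, averaged over a selection.

    Refits the per-voxel OLS on each training fold, predicts the held-out
    fold, and computes one Pearson correlation per voxel from the pooled
    out-of-fold predictions. Voxels whose predictions have zero variance are
    excluded (their count is reported).
    """
    F = np.asarray(features, dtype=np.float64)
    Y = np.asarray(voxels, dtype=np.float64)
    n, V = Y.shape
    if selection is None:
        sel_idx = np.arange(V)
    elif isinstance(selection, VoxelSelection):
        sel_idx = selection.indices
    else:
        sel_idx = np.asarray(selection)
    assign = split_folds(n, folds, labels=labels, seed=seed)
    pred = np.empty_like(Y)
    for f in range(folds):
        test = assign == f
        fit = fit_voxel_encoding(F[~test], Y[~test])
        pred[test] = fit.predict(F[test])

    P, O = pred[:, sel_idx], Y[:, sel_idx]
    pv = P.var(axis=0)
    ov = O.var(axis=0)
    defined = (pv > 1e-300) & (ov > 1e-300)
    Pc = P - P.mean(axis=0)
    Oc = O - O.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (Pc * Oc).sum(axis=0) / np.sqrt((Pc ** 2).sum(axis=0) * (Oc ** 2).sum(axis=0))
    corr = np.where(defined, corr, np.nan)
    return {
        "per_voxel_correlation": corr,
        "mean_correlation": float(np.nanmean(corr)) if defined.any() else float("nan"),
        "n_undefined": int((~defined).sum()),
        "fold_assignment": assign,
    }
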