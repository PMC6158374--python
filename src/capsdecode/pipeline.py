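"""End-to-end reconstruction from voxel responses and its evaluation.

Inference chain: voxel vector -> selection mask -> mapper -> longer-capsule
choice -> decoder. Evaluation runs stratified k-fold cross-validation,
refitting voxel selection and the mapper on each training fold (the capsule
network is trained once on images alone and shared), and reports MSE, PCC
and SSIM per held-out item, alongside the "theoretical" reconstructions
obtained by decoding the true capsules directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from .capsnet import CapsNetModel
from .encoding import (
    VoxelSelection,
    ZScorer,
    fit_voxel_encoding,
    longer_capsule_features,
    select_top_k,
)
from .mapper import MapperModel, MapperTrainConfig, train_mapper
from .synthetic import SyntheticStudy, images_to_array, split_folds

__all__ = [
    "ReconstructionResult",
    "MetricsReport",
    "mse_metric",
    "pcc_metric",
    "ssim_metric",
    "reconstruct_from_fmri",
    "crossvalidate",
]

SSIM_KWARGS = dict(
    win_size=11,
    gaussian_weights=True,
    sigma=1.5,
    K1=0.01,
    K2=0.03,
    use_sample_covariance=False,
    data_range=1.0,
)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _check_pair(a, b):
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    return a, b


def mse_metric(a, b) -> float:
    """Pixel-mean squared error."""
    a, b = _check_pair(a, b)
    return float(((a - b) ** 2).mean())


def pcc_metric(a, b) -> float:
    """Pearson correlation across flattened pixels."""
    a, b = _check_pair(a, b)
    av, bv = a.ravel(), b.ravel()
    if av.std() == 0.0 or bv.std() == 0.0:
        raise ValueError(
            "Pearson correlation is undefined for a constant image; "
            "compare non-constant images or use MSE/SSIM instead"
        )
    return float(np.corrcoef(av, bv)[0, 1])


def ssim_metric(a, b) -> float:
    """Structural similarity with an 11x11 Gaussian window (sigma 1.5),
    K1=0.01, K2=0.03, dynamic range 1."""
    a, b = _check_pair(a, b)
    if min(a.shape) < SSIM_KWARGS["win_size"]:
        raise ValueError(
            f"images smaller than the {SSIM_KWARGS['win_size']}-pixel SSIM window"
        )
    return float(structural_similarity(a, b, **SSIM_KWARGS))


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

@dataclass
class ReconstructionResult:
    predicted_capsules: np.ndarray          # (2, 16)
    chosen_class: int                       # raw label, 6 or 9
    image: np.ndarray                       # (28, 28) in [0, 1]
    tie: bool = False
    theoretical_image: np.ndarray | None = None


CLASS_LABELS = (6, 9)


def reconstruct_from_fmri(
    voxel_vector: np.ndarray,
    selection: VoxelSelection,
    mapper: MapperModel,
    capsnet: CapsNetModel,
    scaler: ZScorer | None = None,
    true_capsule: np.ndarray | None = None,
) -> ReconstructionResult:
    """Full-chain reconstruction for one voxel response vector."""
    v = np.asarray(voxel_vector, dtype=np.float64)
    if v.ndim != 1:
        raise ValueError("reconstruct_from_fmri takes a single voxel vector")
    if selection.ranked_indices.size != v.size:
        raise ValueError(
            f"selection stage: selection covers {selection.ranked_indices.size} "
            f"voxels but the input has {v.size}"
        )
    if scaler is not None:
        v = scaler.transform(v[None])[0]
    x = selection.apply(v)
    if x.size != mapper.n_inputs:
        raise ValueError(
            f"mapper stage: {x.size} selected voxels but the mapper expects "
            f"{mapper.n_inputs}"
        )
    caps = mapper.predict_capsules(x)[0]          # (2, 16)
    feats, chosen = longer_capsule_features(caps)
    norms = np.linalg.norm(caps, axis=1)
    img = capsnet.decode(feats).data[0]
    theo = None
    if true_capsule is not None:
        theo = capsnet.decode(np.asarray(true_capsule)).data[0]
    return ReconstructionResult(
        predicted_capsules=caps,
        chosen_class=CLASS_LABELS[int(chosen)],
        image=img,
        tie=bool(norms[0] == norms[1]),
        theoretical_image=theo,
    )


# ---------------------------------------------------------------------------
# Cross-validated evaluation
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    per_item: pd.DataFrame
    fold_assignment: np.ndarray
    reconstructions: np.ndarray = field(repr=False, default=None)
    theoretical: np.ndarray = field(repr=False, default=None)

    def summary(self) -> pd.DataFrame:
        cols = {"MSE": "mse", "PCC": "pcc", "SSIM": "ssim"}
        return pd.DataFrame(
            {name: [self.per_item[c].mean()] for name, c in cols.items()}
        )

    @property
    def class_accuracy(self) -> float:
        return float((self.per_item.class_pred == self.per_item.class_true).mean())


def crossvalidate(
    study: SyntheticStudy,
    capsnet: CapsNetModel,
    k_folds: int = 10,
    k_voxels: int = 100,
    mapper_config: MapperTrainConfig | None = None,
    seed: int | None = None,
    zscore: bool = True,
    global_selection: bool = False,
) -> MetricsReport:
    """Stratified k-fold evaluation of the full reconstruction chain.

    Per fold: z-score voxels on training statistics, fit the per-voxel
    encoding on the training items only, select the top `k_voxels`, train
    the mapper on the training items, then reconstruct and score the
    held-out items. Set `global_selection=True` to rank voxels once on all
    items instead (mimics a non-leakage-safe protocol).
    """
    pixels, labels = images_to_array(study.images)
    n = study.n_stimuli
    rng = np.random.default_rng(seed)
    assign = split_folds(n, k_folds, labels=labels, seed=rng.integers(2 ** 31))

    v_all, _, _ = capsnet.forward(pixels)
    true_caps = v_all.data                                  # (n, 2, 16)
    feats_all, _ = longer_capsule_features(true_caps)

    global_sel = None
    if global_selection:
        sc = ZScorer.fit(study.voxels) if zscore else None
        vz = sc.transform(study.voxels) if zscore else study.voxels
        global_sel = select_top_k(fit_voxel_encoding(feats_all, vz), k=k_voxels)

    rows = []
    recon_imgs = np.zeros_like(pixels)
    theo_imgs = np.zeros_like(pixels)
    base_cfg = mapper_config or MapperTrainConfig()
    for f in range(k_folds):
        test = assign == f
        train = ~test
        scaler = ZScorer.fit(study.voxels[train]) if zscore else None
        vox = scaler.transform(study.voxels) if zscore else study.voxels

        if global_sel is not None:
            sel = global_sel
        else:
            fit = fit_voxel_encoding(feats_all[train], vox[train])
            sel = select_top_k(fit, k=k_voxels)

        fold_cfg = MapperTrainConfig(
            learning_rate=base_cfg.learning_rate,
            batch_size=base_cfg.batch_size,
            iterations=base_cfg.iterations,
            l2_strength=base_cfg.l2_strength,
            seed=int(rng.integers(2 ** 31)),
        )
        mapper, _ = train_mapper(sel.apply(vox[train]), true_caps[train], fold_cfg)

        for i in np.flatnonzero(test):
            res = reconstruct_from_fmri(
                vox[i], sel, mapper, capsnet,
                true_capsule=feats_all[i],
            )
            recon_imgs[i] = res.image
            theo_imgs[i] = res.theoretical_image
            rows.append({
                "item": int(i),
                "fold": f,
                "class_true": int(labels[i]),
                "class_pred": res.chosen_class,
                "mse": mse_metric(pixels[i], res.image),
                "pcc": pcc_metric(pixels[i], res.image),
                "ssim": ssim_metric(pixels[i], res.image),
                "ssim_theoretical": ssim_metric(pixels[i], res.theoretical_image),
            })

    per_item = pd.DataFrame(rows).sort_values("item").reset_index(drop=True)
    return MetricsReport(
        per_item=per_item,
        fold_assignment=assign,
        reconstructions=recon_imgs,
        theoretical=theo_imgs,
    )


def save_reconstruction_grid(path, stimuli, theoretical, reconstructed,
                             max_items: int = 12):
    """PNG grid with stimulus / theoretical / fMRI-path rows."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = min(max_items, len(stimuli))
    fig, axes = plt.subplots(3, m, figsize=(1.1 * m, 3.6))
    axes = np.atleast_2d(axes)
    row_names = ["stimulus", "theoretical", "from fMRI"]
    for r, imgs in enumerate((stimuli, theoretical, reconstructed)):
        for c in range(m):
            ax = axes[r, c]
            ax.imshow(imgs[c], cmap="gray", vmin=0, vmax=1)
            ax.set_xticks([])
            ax.set_yticks([])
            if c == 0:
                ax.set_ylabel(row_names[r], fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
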