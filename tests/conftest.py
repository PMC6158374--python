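"""Shared fixtures. Training runs are session-scoped so the expensive
models are fit once and reused across the unit and acceptance tests."""

import numpy as np
import pytest

from capsdecode.capsnet import scaled_config, train_capsnet
from capsdecode.encoding import (
    ZScorer,
    fit_voxel_encoding,
    longer_capsule_features,
    select_top_k,
)
from capsdecode.mapper import MapperTrainConfig, train_mapper
from capsdecode.synthetic import generate_digits, generate_fmri, images_to_array

GLYPH_SEED = 11
CAPSNET_SEED = 0
STUDY_SEED = 21
MAPPER_SEED = 5


def finite_difference(f, params, h=1e-5, coords=None, rng=None, n_coords=10):
    """Central finite differences of scalar f() w.r.t. selected coordinates.

    `params` is a list of Tensors mutated in place; returns a list of
    (tensor_index, flat_coord, fd_gradient) triples.
    """
    rng = rng or np.random.default_rng(0)
    out = []
    if coords is None:
        coords = []
        for _ in range(n_coords):
            ti = int(rng.integers(len(params)))
            coords.append((ti, int(rng.integers(params[ti].data.size))))
    for ti, ci in coords:
        flat = params[ti].data.reshape(-1)
        orig = flat[ci]
        flat[ci] = orig + h
        fp = float(f())
        flat[ci] = orig - h
        fm = float(f())
        flat[ci] = orig
        out.append((ti, ci, (fp - fm) / (2 * h)))
    return out


@pytest.fixture(scope="session")
def glyphs500():
    images = generate_digits(500, class_mix=0.5, seed=GLYPH_SEED)
    return images_to_array(images)


@pytest.fixture(scope="session")
def trained_capsnet(glyphs500):
    """Scaled-width capsule net trained for 20 epochs on 500 glyphs."""
    px, lab = glyphs500
    model, trace = train_capsnet(
        px, lab, scaled_config(), epochs=20, batch_size=10,
        learning_rate=1e-3, seed=CAPSNET_SEED,
    )
    return model, trace


@pytest.fixture(scope="session")
def noiseless_study(trained_capsnet):
    """100-item study whose voxels are an exact linear map of the trained
    network's longer-capsule features (snr_r2 = 1)."""
    model, _ = trained_capsnet
    images = generate_digits(100, class_mix=0.5, seed=STUDY_SEED)
    px, _ = images_to_array(images)
    v, _, _ = model.forward(px)
    feats, _ = longer_capsule_features(v.data)
    study = generate_fmri(
        feats, n_voxels=300, n_informative=60, snr_r2=1.0,
        seed=STUDY_SEED, images=images,
    )
    return study, v.data


@pytest.fixture(scope="session")
def selected_voxels(noiseless_study):
    """Z-scored, top-100 selected voxel matrix plus the selection itself."""
    study, true_caps = noiseless_study
    feats, _ = longer_capsule_features(true_caps)
    scaler = ZScorer.fit(study.voxels)
    vz = scaler.transform(study.voxels)
    sel = select_top_k(fit_voxel_encoding(feats, vz), k=100)
    return sel.apply(vz), sel, scaler


@pytest.fixture(scope="session")
def cv_report(noiseless_study, trained_capsnet):
    """Full 10-fold cross-validated evaluation on the noiseless study."""
    from capsdecode.pipeline import crossvalidate

    study, _ = noiseless_study
    capsnet, _ = trained_capsnet
    return crossvalidate(
        study, capsnet, k_folds=10, k_voxels=100,
        mapper_config=MapperTrainConfig(learning_rate=1e-3, iterations=2500),
        seed=7,
    )


@pytest.fixture(scope="session")
def trained_mapper(noiseless_study, selected_voxels):
    """Mapper fit on the first 90 study items (noiseless, z-scored)."""
    study, true_caps = noiseless_study
    X, sel, _ = selected_voxels
    cfg = MapperTrainConfig(learning_rate=1e-3, iterations=8000, seed=MAPPER_SEED)
    model, trace = train_mapper(
        X[:90], true_caps[:90], cfg,
        test_voxels=X[90:], test_capsules=true_caps[90:],
    )
    return model, trace
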