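"""Shared on-disk conventions: the HDF5 study container, model checkpoints
(HDF5 weights + JSON config sidecar), and the run configuration."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np

from . import capsnet as _capsnet
from .capsnet import CapsNetModel
from .mapper import MapperModel
from .synthetic import StimulusImage, SyntheticStudy

__all__ = [
    "DEFAULT_CONFIG",
    "config_hash",
    "load_config",
    "save_config",
    "save_study",
    "load_study",
    "save_capsnet",
    "load_capsnet",
    "save_mapper",
    "load_mapper",
]

# All stage hyperparameters in one overridable place.
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "study": {
        "n_stimuli": 100,
        "n_voxels": 3092,
        "n_informative": 50,
        "snr_r2": 0.9,
    },
    "capsnet": {
        "scaled": True,
        "epochs": 20,
        "batch_size": 10,
        "learning_rate": 1e-3,
        "n_train_images": 500,
        "m_plus": 0.9,
        "m_minus": 0.1,
        "lambda_down": 0.5,
        "recon_weight": 4.0,
        "routing_iters": 3,
    },
    "selection": {"k_voxels": 100, "zscore": True},
    "mapper": {
        "learning_rate": 1e-4,
        "batch_size": 10,
        "iterations": 10000,
        "l2_strength": 1e-3,
    },
    "evaluate": {"folds": 10},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, json.load(fh))
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def save_config(cfg: dict, path):
    with open(path, "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
        fh.write("\n")


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Study container
# ---------------------------------------------------------------------------

def save_study(study: SyntheticStudy, path):
    from .synthetic import images_to_array

    with h5py.File(path, "w") as f:
        if study.images:
            px, lab = images_to_array(study.images)
            f.create_dataset("images", data=px)
            f.create_dataset("labels", data=lab)
        f.create_dataset("voxels", data=study.voxels)
        f.create_dataset("true_capsules", data=study.true_capsules)
        f.create_dataset("encoding_weights", data=study.encoding_weights)
        f.create_dataset("intercepts", data=study.intercepts)
        f.create_dataset("informative_idx", data=study.informative_idx)
        f.create_dataset("noise_sd", data=study.noise_sd)
        f.attrs["seed"] = -1 if study.seed is None else study.seed


def load_study(path) -> SyntheticStudy:
    with h5py.File(path, "r") as f:
        images = []
        if "images" in f:
            px = f["images"][...]
            lab = f["labels"][...]
            images = [StimulusImage(p, int(l)) for p, l in zip(px, lab)]
        seed = int(f.attrs.get("seed", -1))
        return SyntheticStudy(
            images=images,
            voxels=f["voxels"][...],
            true_capsules=f["true_capsules"][...],
            encoding_weights=f["encoding_weights"][...],
            intercepts=f["intercepts"][...],
            informative_idx=f["informative_idx"][...],
            noise_sd=f["noise_sd"][...],
            seed=None if seed < 0 else seed,
        )


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def _save_weights(path, state: dict[str, np.ndarray], meta: dict):
    path = Path(path)
    with h5py.File(path, "w") as f:
        for name, arr in state.items():
            f.create_dataset(name, data=arr)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _load_weights(path) -> tuple[dict[str, np.ndarray], dict]:
    path = Path(path)
    with h5py.File(path, "r") as f:
        state = {name: f[name][...] for name in f}
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    return state, meta


def save_capsnet(model: CapsNetModel, path, extra_meta: dict | None = None):
    meta = {"kind": "capsnet", "config": _capsnet.config_to_dict(model.config)}
    meta.update(extra_meta or {})
    _save_weights(path, model.state_dict(), meta)


def load_capsnet(path) -> CapsNetModel:
    state, meta = _load_weights(path)
    model = CapsNetModel(_capsnet.config_from_dict(meta["config"]))
    model.load_state_dict(state)
    return model


def save_mapper(model: MapperModel, path, extra_meta: dict | None = None):
    meta = {
        "kind": "mapper",
        "n_inputs": model.n_inputs,
        "hidden": list(model.hidden),
    }
    meta.update(extra_meta or {})
    _save_weights(path, model.state_dict(), meta)


def load_mapper(path) -> MapperModel:
    state, meta = _load_weights(path)
    model = MapperModel(n_inputs=meta["n_inputs"], hidden=tuple(meta["hidden"]))
    model.load_state_dict(state)
    return model
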