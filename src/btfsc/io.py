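"""Reading and writing the pipeline's on-disk artifacts.

Viewable images travel as 8-bit PNG (values in [0,1] scaled to 0–255);
float grids, fusion weights and trained classifier models travel as ``.npz``
archives (named flat binary tensors) with a JSON-encoded manifest entry
carrying shapes and configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .classifier import DlpnnModel, build_arch
from .fusion import FusionWeights

__all__ = [
    "load_image",
    "save_image",
    "save_weights",
    "load_weights",
    "save_model",
    "load_model",
]


def load_image(path) -> np.ndarray:
    """Load a PNG/TIFF image as float in [0,1]; RGB stays 3-channel."""
    arr = np.asarray(iio.imread(path))
    if arr.dtype == np.uint8:
        arr = arr / 255.0
    elif arr.dtype == np.uint16:
        arr = arr / 65535.0
    else:
        arr = arr.astype(float)
    if arr.ndim == 3 and arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    return arr


def save_image(path, img: np.ndarray) -> None:
    """Save a [0,1] grid (or RGB) as 8-bit PNG."""
    arr = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    iio.imwrite(path, (arr * 255.0 + 0.5).astype(np.uint8))


def save_weights(path, wts: FusionWeights, manifest: dict | None = None) -> None:
    d = wts.as_dict()
    meta = {"shapes": {k: list(v.shape) for k, v in d.items()}}
    if manifest:
        meta.update(manifest)
    np.savez(path, manifest=json.dumps(meta), **d)


def load_weights(path) -> FusionWeights:
    with np.load(path, allow_pickle=False) as z:
        return FusionWeights(**{k: z[k] for k in ("w1", "b1", "w2", "b2", "w3", "b3")})


def save_model(path, model: DlpnnModel, manifest: dict | None = None) -> None:
    meta = {
        "feature_concat": model.feature_concat,
        "loss_trace": model.loss_trace,
        "acc_trace": model.acc_trace,
    }
    if manifest:
        meta.update(manifest)
    extras = {}
    if model.feature_concat:
        extras["feature_mean"] = model.feature_mean
        extras["feature_std"] = model.feature_std
    np.savez(path, manifest=json.dumps(meta), **model.params, **extras)


def load_model(path) -> DlpnnModel:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["manifest"]))
        params = {k: z[k] for k in ("cw1", "cb1", "cw2", "cb2", "dw1", "db1", "hw", "hb")}
        model = DlpnnModel(
            arch=build_arch(),
            params=params,
            feature_concat=bool(meta["feature_concat"]),
            loss_trace=list(meta.get("loss_trace", [])),
            acc_trace=list(meta.get("acc_trace", [])),
            trained=True,
        )
        if model.feature_concat:
            model.feature_mean = z["feature_mean"]
            model.feature_std = z["feature_std"]
    return model


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
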