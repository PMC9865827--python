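"""Benign/malignant classifier: a small convolutional network with a
softmax posterior, optionally concatenating the 13-entry hybrid feature
vector before the output head.

The layer geometry is fixed and self-checking: a 64x64 grayscale ROI passes
through conv 3x3/32 (valid, to 62), max-pool 2x2 (31), conv 3x3/64 (29),
max-pool 2x2 (14), flatten (14*14*64 = 12544), dense 128 (ReLU), then a
2-way softmax head.  Training is plain seeded SGD on cross-entropy at the
published recipe (batch 90, learning rate 0.02, 300 epochs by default;
scaled-down epoch counts are used for desk-scale runs).  When
``feature_concat`` is on, hybrid feature vectors are z-scored with training
-set statistics and concatenated to the dense-layer output before the head.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from . import _nn
from .errors import ParameterError, ShapeError, StateError

__all__ = ["DlpnnArch", "TrainConfig", "DlpnnModel", "build_arch", "train", "predict", "extract_roi"]

LABELS = ("benign", "malignant")
N_FEATURES = 13


@dataclass(frozen=True)
class DlpnnArch:
    """The layer geometry; construction fails if the shape chain breaks."""

    input_size: int = 64
    conv1: tuple[int, int, int] = (62, 3, 32)  # (out_spatial, kernel, filters)
    pool1: tuple[int, int, int] = (31, 2, 32)
    conv2: tuple[int, int, int] = (29, 3, 64)
    pool2: tuple[int, int, int] = (14, 2, 64)
    flatten: int = 12544
    dense1: int = 128
    head: int = 2

    def __post_init__(self):
        s = self.input_size
        chain = []
        for conv, pool in ((self.conv1, self.pool1), (self.conv2, self.pool2)):
            s = s - conv[1] + 1
            chain.append((s, conv[0]))
            s = (s - pool[1]) // 2 + 1
            chain.append((s, pool[0]))
        for got, declared in chain:
            if got != declared:
                raise ParameterError(f"shape chain broken: computed {got}, declared {declared}")
        if self.pool2[0] ** 2 * self.pool2[2] != self.flatten:
            raise ParameterError("flatten size inconsistent with pool2 output")


def build_arch() -> DlpnnArch:
    """The standard geometry (64 -> 62 -> 31 -> 29 -> 14, flatten 12544)."""
    return DlpnnArch()


@dataclass(frozen=True)
class TrainConfig:
    """Published training recipe; epochs are scaled down for desk-scale runs."""

    batch: int = 90
    epochs: int = 300
    lr: float = 0.02
    seed: int = 0
    feature_concat: bool = True

    def __post_init__(self):
        if self.epochs < 0:
            raise ParameterError("epochs must be >= 0")
        if self.batch < 1:
            raise ParameterError("batch must be >= 1")


@dataclass
class DlpnnModel:
    """Trained network: parameters, architecture, training traces and the
    z-score statistics of the hybrid features (when used)."""

    arch: DlpnnArch
    params: dict[str, np.ndarray]
    feature_concat: bool
    feature_mean: np.ndarray | None = None
    feature_std: np.ndarray | None = None
    loss_trace: list[float] = field(default_factory=list)
    acc_trace: list[float] = field(default_factory=list)
    trained: bool = False


def _init_params(arch: DlpnnArch, feature_concat: bool, seed: int) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)

    def he(shape, fan_in):
        return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)

    f1, f2 = arch.conv1[2], arch.conv2[2]
    head_in = arch.dense1 + (N_FEATURES if feature_concat else 0)
    return {
        "cw1": he((f1, 1, 3, 3), 9),
        "cb1": np.zeros(f1, np.float32),
        "cw2": he((f2, f1, 3, 3), 9 * f1),
        "cb2": np.zeros(f2, np.float32),
        "dw1": he((arch.flatten, arch.dense1), arch.flatten),
        "db1": np.zeros(arch.dense1, np.float32),
        "hw": he((head_in, arch.head), head_in),
        "hb": np.zeros(arch.head, np.float32),
    }


def _forward(params, x, feats, need_cache=True):
    """x: (N,1,64,64) float32; feats: (N,13) z-scored or None."""
    z1, c1 = _nn.conv2d(x, params["cw1"], params["cb1"])
    a1 = _nn.relu(z1)
    p1, pc1 = _nn.maxpool2(a1)
    z2, c2 = _nn.conv2d(p1, params["cw2"], params["cb2"])
    a2 = _nn.relu(z2)
    p2, pc2 = _nn.maxpool2(a2)
    flat = p2.reshape(p2.shape[0], -1)
    zd = flat @ params["dw1"] + params["db1"]
    ad = _nn.relu(zd)
    head_in = ad if feats is None else np.concatenate([ad, feats.astype(np.float32)], axis=1)
    logits = head_in @ params["hw"] + params["hb"]
    cache = (z1, c1, pc1, z2, c2, pc2, flat, zd, ad, head_in) if need_cache else None
    return logits, cache


def _backward(params, dlogits, cache):
    z1, c1, pc1, z2, c2, pc2, flat, zd, ad, head_in = cache
    grads = {}
    grads["hw"] = head_in.T @ dlogits
    grads["hb"] = dlogits.sum(axis=0)
    dhead_in = dlogits @ params["hw"].T
    dad = dhead_in[:, : ad.shape[1]]
    dzd = dad * (zd > 0)
    grads["dw1"] = flat.T @ dzd
    grads["db1"] = dzd.sum(axis=0)
    dflat = dzd @ params["dw1"].T
    dp2 = dflat.reshape(dflat.shape[0], params["cw2"].shape[0], 14, 14)
    da2 = _nn.maxpool2_backward(dp2, pc2)
    dz2 = da2 * (z2 > 0)
    dp1, grads["cw2"], grads["cb2"] = _nn.conv2d_backward(dz2, params["cw2"], c2)
    da1 = _nn.maxpool2_backward(dp1, pc1)
    dz1 = da1 * (z1 > 0)
    _, grads["cw1"], grads["cb1"] = _nn.conv2d_backward(dz1, params["cw1"], c1, need_dx=False)
    return grads


def _as_feature_matrix(features) -> np.ndarray:
    rows = []
    for f in features:
        rows.append(f.as_array() if hasattr(f, "as_array") else np.asarray(f, dtype=float))
    return np.vstack(rows)


def extract_roi(img: np.ndarray, mask: np.ndarray, size: int = 64) -> np.ndarray:
    """Bounding-box crop of the mask region resized to ``size`` x ``size``."""
    from .features import roi_from_mask

    roi = roi_from_mask(img, mask)
    return resize(roi, (size, size), order=1, anti_aliasing=True, preserve_range=True)


def roi_dataset(pairs, *, denoise: bool = True, use_truth_mask: bool = True, k: int = 4):
    """Build (roi, features, label) training triples from phantom pairs.

    The ROI is the tumor bounding box of the (optionally HPWF-denoised) MR
    channel resized to 64x64; features are the hybrid 13-vector of the
    unresized crop.  With ``use_truth_mask=False`` the mask comes from the
    clustering segmenter instead of ground truth.
    """
    from .denoise import hpwf_denoise
    from .features import hybrid_vector, roi_from_mask
    from .segmentation import segment

    triples = []
    for pair in pairs:
        img = hpwf_denoise(pair.mr).output if denoise else np.asarray(pair.mr, dtype=float)
        mask = pair.truth_mask if use_truth_mask else segment(img, k).tumor_mask
        roi = extract_roi(img, mask)
        feats = hybrid_vector(roi_from_mask(img, mask))
        triples.append((roi, feats, pair.label))
    return triples


def train(dataset, cfg: TrainConfig = TrainConfig()) -> DlpnnModel:
    """Train on a sequence of (roi, features, label) triples.

    ``roi`` must be 64x64 in [0,1]; ``features`` a 13-entry vector (ignored
    unless ``cfg.feature_concat``); ``label`` one of {"benign", "malignant"}
    (or 0/1).  Deterministic for a fixed config and dataset.
    """
    rois, feats, labels = [], [], []
    for roi, f, lab in dataset:
        roi = np.asarray(roi, dtype=np.float32)
        if roi.shape != (64, 64):
            raise ShapeError("ROIs must be 64x64 (use extract_roi)")
        rois.append(roi)
        feats.append(f)
        labels.append(LABELS.index(lab) if isinstance(lab, str) else int(lab))
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ParameterError("training set must contain both classes")
    if cfg.batch > len(rois):
        raise ParameterError("batch size exceeds the dataset")
    x = np.stack(rois)[:, None]  # (N,1,64,64)

    arch = build_arch()
    params = _init_params(arch, cfg.feature_concat, cfg.seed)
    model = DlpnnModel(arch=arch, params=params, feature_concat=cfg.feature_concat)
    fmat = None
    if cfg.feature_concat:
        fmat = _as_feature_matrix(feats)
        model.feature_mean = fmat.mean(axis=0)
        model.feature_std = np.where(fmat.std(axis=0) > 1e-12, fmat.std(axis=0), 1.0)
        fmat = (fmat - model.feature_mean) / model.feature_std

    rng = np.random.default_rng(cfg.seed + 1)
    n = x.shape[0]
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses, hits = [], 0
        for start in range(0, n, cfg.batch):
            idx = order[start : start + cfg.batch]
            xb = x[idx]
            fb = fmat[idx] if fmat is not None else None
            logits, cache = _forward(params, xb, fb)
            loss, dlogits = _nn.softmax_cross_entropy(logits, y[idx])
            if cfg.lr != 0.0:
                grads = _backward(params, dlogits.astype(np.float32), cache)
                for k, g in grads.items():
                    params[k] -= cfg.lr * g
            losses.append(loss)
            hits += int((logits.argmax(axis=1) == y[idx]).sum())
        model.loss_trace.append(float(np.mean(losses)))
        model.acc_trace.append(hits / n)
    model.trained = True
    return model


def predict(model: DlpnnModel, roi: np.ndarray, features=None):
    """Posterior class probabilities and the argmax label for one ROI."""
    if not model.trained:
        raise StateError("model has not been trained")
    roi = np.asarray(roi, dtype=np.float32)
    if roi.shape != (64, 64):
        raise ShapeError("ROI must be 64x64")
    fb = None
    if model.feature_concat:
        if features is None:
            raise ParameterError("this model requires the hybrid feature vector")
        f = _as_feature_matrix([features])
        fb = (f - model.feature_mean) / model.feature_std
    logits, _ = _forward(model.params, roi[None, None], fb, need_cache=False)
    probs = _nn.softmax(logits)[0]
    return LABELS[int(probs.argmax())], probs.astype(float)
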