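"""Two-branch convolutional fusion of co-registered modality images.

The network follows a fixed symmetric topology: each branch convolves its
input with a shared 3x3 kernel bank (stage 1, 64 maps, ReLU), the two branch
outputs are summed and convolved with a shared second bank (stage 2, 128
maps, ReLU) — by construction the two stage-2 maps F3 and F4 are identical —
then the concatenated stage-2 maps are projected by a third bank back to a
single fused channel, ReLU'd and clipped to [0, 1].  Same-padding is used
throughout so the fused image has the input resolution.

Training is unsupervised: the loss pulls the fused image toward both sources
with a uniform-window structural-similarity term per source plus a
gradient-preservation term (the fused gradients should match, per pixel and
direction, whichever source gradient is larger in magnitude).  The SSIM
surrogate uses circular boundary handling so its analytic gradient is exact;
evaluation SSIM elsewhere in the package uses the canonical Gaussian-window
form from scikit-image.

A color modality (PET/SPECT-like RGB) is fused on its luma channel only:
convert to YCbCr, fuse Y with the grayscale modality, re-attach Cb/Cr and
convert back.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

from . import _nn
from .errors import ParameterError, ShapeError
from .phantom import ModalityPair

__all__ = [
    "FusionWeights",
    "FusionConfig",
    "FusionTraining",
    "to_ycbcr",
    "from_ycbcr",
    "forward_fuse",
    "train_fusion",
    "fuse_pair",
    "average_fuse",
    "rea_enhance",
]

_C1 = 0.01**2
_C2 = 0.03**2
_SSIM_WIN = 7
#: strength of the optional REA edge enhancement of the second branch input
_REA_GAIN = 0.2


# ---------------------------------------------------------------------------
# color conversion (ITU-R BT.601, offset-0.5 chroma convention)

def to_ycbcr(rgb: np.ndarray):
    """Split an RGB image in [0,1] into (y, cb, cr); gray maps to cb=cr=0.5."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ShapeError("expected an HxWx3 RGB image")
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    y = 0.299 * r + 0.587 * g + 0.114 * b
    cb = (b - y) / 1.772 + 0.5
    cr = (r - y) / 1.402 + 0.5
    return y, cb, cr


def from_ycbcr(y: np.ndarray, cb: np.ndarray, cr: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_ycbcr` (exact up to float rounding)."""
    b = (cb - 0.5) * 1.772 + y
    r = (cr - 0.5) * 1.402 + y
    g = (y - 0.299 * r - 0.114 * b) / 0.587
    return np.stack([r, g, b], axis=-1)


# ---------------------------------------------------------------------------
# weights

@dataclass
class FusionWeights:
    """Kernel banks and biases of the three stages.

    Shapes: ``w1 (s1, 1, 3, 3)``, ``w2 (s2, s1, 3, 3)``, ``w3 (1, 2*s2, 3, 3)``
    with default map counts s1=64, s2=128.  Stage-1 and stage-2 banks are
    shared across the two symmetric branches.
    """

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    w3: np.ndarray
    b3: np.ndarray

    @property
    def map_counts(self) -> dict[str, int]:
        return {"stage1": self.w1.shape[0], "stage2": self.w2.shape[0]}

    def as_dict(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k) for k in ("w1", "b1", "w2", "b2", "w3", "b3")}

    @classmethod
    def initialize(cls, seed: int, stage1: int = 64, stage2: int = 128) -> "FusionWeights":
        """Seeded average-preserving initialization.

        Small He-scaled noise everywhere, plus a deterministic delta-kernel
        path through map 0 of every stage so the untrained network computes
        approximately the pixel average of its two inputs.  Training then
        refines a sensible fusion instead of recovering one from noise.
        """
        rng = np.random.default_rng(seed)

        def noise(shape):
            fan_in = int(np.prod(shape[1:]))
            return (0.05 * np.sqrt(2.0 / fan_in) * rng.standard_normal(shape)).astype(
                np.float32
            )

        w1 = noise((stage1, 1, 3, 3))
        w2 = noise((stage2, stage1, 3, 3))
        w3 = noise((1, 2 * stage2, 3, 3))
        w1[0, 0, 1, 1] += 1.0  # F1[0] ~ a, F2[0] ~ b
        w2[0, 0, 1, 1] += 0.5  # F3[0] ~ (a + b) / 2
        w3[0, 0, 1, 1] += 0.5
        w3[0, stage2, 1, 1] += 0.5  # F_R ~ (F3[0] + F4[0]) / 2
        zeros = lambda k: np.zeros(k, dtype=np.float32)
        return cls(w1=w1, b1=zeros(stage1), w2=w2, b2=zeros(stage2), w3=w3, b3=zeros(1))


@dataclass(frozen=True)
class FusionConfig:
    """Training recipe for the fusion network.

    ``loss_weights`` weights the three loss terms (SSIM to source a, SSIM to
    source b, gradient preservation); they must be nonnegative with at least
    one positive.
    """

    epochs: int = 50
    lr: float = 1e-3
    batch: int = 1
    loss_weights: tuple[float, float, float] = (0.4, 0.4, 0.2)
    seed: int = 0

    def __post_init__(self):
        lw = np.asarray(self.loss_weights, dtype=float)
        if np.any(lw < 0) or not np.any(lw > 0):
            raise ParameterError("loss weights must be >= 0 with at least one > 0")


@dataclass
class FusionTraining:
    """Result of :func:`train_fusion`: the weights plus the per-epoch loss trace."""

    weights: FusionWeights
    loss_trace: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# forward / backward

def _forward(a: np.ndarray, b: np.ndarray, wts: FusionWeights):
    """Full forward pass with caches for backprop.

    Because the two stage-2 maps are provably identical (their defining
    expressions are symmetric in F1 + F2), the stage-3 convolution over the
    concatenation [F3, F4] is computed exactly as a convolution of F3 with
    the sum of the two kernel-bank halves — same arithmetic, half the work.
    """
    xa = a[None].astype(np.float32)
    xb = b[None].astype(np.float32)
    z1a, ca = _nn.sconv2d(xa, wts.w1, wts.b1, padding=1)
    z1b, cb = _nn.sconv2d(xb, wts.w1, wts.b1, padding=1)
    f1, f2 = _nn.relu(z1a), _nn.relu(z1b)
    s = f1 + f2
    z2, c2 = _nn.sconv2d(s, wts.w2, wts.b2, padding=1)
    f3 = _nn.relu(z2)
    f4 = f3  # Eqs for the two stage-2 maps are symmetric in F1 + F2
    s2 = wts.w2.shape[0]
    w3_eff = wts.w3[:, :s2] + wts.w3[:, s2:]
    z3, c3 = _nn.sconv2d(f3, w3_eff, wts.b3, padding=1)
    fused = np.clip(_nn.relu(z3), 0.0, 1.0)
    cache = (z1a, z1b, ca, cb, z2, c2, c3, z3, w3_eff)
    return fused[0], (f1, f2, f3, f4), cache


def _backward(dfused: np.ndarray, wts: FusionWeights, cache):
    z1a, z1b, ca, cb, z2, c2, c3, z3, w3_eff = cache
    dz3 = dfused[None].astype(np.float32) * ((z3 > 0) & (z3 < 1))
    df3, dw3_eff, db3 = _nn.sconv2d_backward(dz3, c3, w3_eff, padding=1)
    # both halves of w3 see the same input (F4 aliases F3), hence equal grads
    dw3 = np.concatenate([dw3_eff, dw3_eff], axis=1)
    dz2 = df3 * (z2 > 0)
    ds, dw2, db2 = _nn.sconv2d_backward(dz2, c2, wts.w2, padding=1)
    dz1a = ds * (z1a > 0)
    dz1b = ds * (z1b > 0)
    _, dw1a, db1a = _nn.sconv2d_backward(dz1a, ca, wts.w1, padding=1, need_dx=False)
    _, dw1b, db1b = _nn.sconv2d_backward(dz1b, cb, wts.w1, padding=1, need_dx=False)
    return {
        "w1": dw1a + dw1b,
        "b1": db1a + db1b,
        "w2": dw2,
        "b2": db2,
        "w3": dw3,
        "b3": db3,
    }


def forward_fuse(a: np.ndarray, b: np.ndarray, wts: FusionWeights, return_maps: bool = False):
    """Fuse two [0,1] grids of equal shape; optionally return (F1..F4)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ShapeError("inputs must be 2-D grids of equal shape")
    fused, maps, _ = _forward(a, b, wts)
    fused = fused.astype(float)
    return (fused, maps) if return_maps else fused


# ---------------------------------------------------------------------------
# loss: uniform-window SSIM (circular boundaries, exact analytic gradient)
# plus gradient preservation

def _ssim_loss_grad(x: np.ndarray, y: np.ndarray):
    """(1 - mean SSIM(x, y), d/dx) with a flat 7x7 window, wrap boundaries."""
    U = lambda z: uniform_filter(z, size=_SSIM_WIN, mode="wrap")
    mu_x, mu_y = U(x), U(y)
    sx2 = U(x * x) - mu_x**2
    sy2 = U(y * y) - mu_y**2
    sxy = U(x * y) - mu_x * mu_y
    a1 = 2 * mu_x * mu_y + _C1
    a2 = 2 * sxy + _C2
    b1 = mu_x**2 + mu_y**2 + _C1
    b2 = sx2 + sy2 + _C2
    s = (a1 * a2) / (b1 * b2)
    n = x.size
    d_mu = 2 * mu_y * a2 / (b1 * b2) - 2 * mu_x * s / b1
    d_sx2 = -s / b2
    d_sxy = 2 * a1 / (b1 * b2)
    dx = (
        U(d_mu)
        + 2 * x * U(d_sx2)
        - 2 * U(d_sx2 * mu_x)
        + y * U(d_sxy)
        - U(d_sxy * mu_y)
    ) / n
    return 1.0 - float(s.mean()), -dx


def _fd(z: np.ndarray, axis: int) -> np.ndarray:
    return np.roll(z, -1, axis=axis) - z


def _fd_adjoint(z: np.ndarray, axis: int) -> np.ndarray:
    return np.roll(z, 1, axis=axis) - z


def _grad_loss_grad(f: np.ndarray, a: np.ndarray, b: np.ndarray):
    """Gradient-preservation term: match the larger source gradient per pixel."""
    loss = 0.0
    df = np.zeros_like(f)
    n = f.size
    for axis in (0, 1):
        ga, gb, gf = _fd(a, axis), _fd(b, axis), _fd(f, axis)
        target = np.where(np.abs(ga) >= np.abs(gb), ga, gb)
        r = gf - target
        loss += float(np.mean(r**2))
        df += (2.0 / n) * _fd_adjoint(r, axis)
    return loss, df


def fusion_loss_grad(fused: np.ndarray, a: np.ndarray, b: np.ndarray, loss_weights):
    """Total unsupervised fusion loss and its gradient w.r.t. the fused image."""
    wa, wb, wg = loss_weights
    la, da = _ssim_loss_grad(fused, a)
    lb, db_ = _ssim_loss_grad(fused, b)
    lg, dg = _grad_loss_grad(fused, a, b)
    return wa * la + wb * lb + wg * lg, wa * da + wb * db_ + wg * dg


# ---------------------------------------------------------------------------
# REA enhancement of the second branch

def rea_enhance(b: np.ndarray, edge_energy: np.ndarray | None) -> np.ndarray:
    """Additively boost the second branch input with normalized REA energy.

    Keeps the stage-1 kernel bank shared across two single-channel branches
    (the written equations admit no extra input channel); a None energy map
    returns the input unchanged.
    """
    if edge_energy is None:
        return np.asarray(b, dtype=float)
    e = np.asarray(edge_energy, dtype=float)
    if e.shape != b.shape:
        raise ShapeError("edge energy shape must match the image")
    peak = e.max()
    if peak > 0:
        e = e / peak
    return np.clip(b + _REA_GAIN * e, 0.0, 1.0)


def _prepare_inputs(pair: ModalityPair, use_rea: bool):
    from .edges import optimize_slopes  # local import to avoid cycle at import time

    if pair.pet_rgb is not None:
        y, _, _ = to_ycbcr(pair.pet_rgb)
        a, b = pair.mr, y
    elif pair.ct is not None:
        a, b = pair.mr, pair.ct
    else:
        raise ParameterError("pair needs a second modality (ct or pet_rgb)")
    if use_rea:
        b = rea_enhance(b, optimize_slopes(b).energy)
    return a, b


# ---------------------------------------------------------------------------
# training / inference

def train_fusion(
    pairs: list[ModalityPair], cfg: FusionConfig = FusionConfig(), use_rea: bool = True
) -> FusionTraining:
    """Train the fusion network on phantom pairs (unsupervised).

    The SSIM terms always target the *original* modality images; REA
    enhancement (when enabled) only alters the network input.  With
    ``epochs=0`` the seeded initialization is returned untouched and the
    loss trace is empty.
    """
    if len(pairs) == 0:
        raise ParameterError("need at least one training pair")
    if cfg.epochs > 0 and len(pairs) < 4:
        raise ParameterError("need at least 4 pairs to train")
    wts = FusionWeights.initialize(cfg.seed)
    trace: list[float] = []
    if cfg.epochs == 0:
        return FusionTraining(weights=wts, loss_trace=trace)

    prepared = []
    for pair in pairs:
        a, b = _prepare_inputs(pair, use_rea)
        target_a = np.asarray(pair.mr, dtype=float)
        target_b = np.asarray(pair.ct if pair.pet_rgb is None else to_ycbcr(pair.pet_rgb)[0], dtype=float)
        prepared.append((a, b, target_a, target_b))

    params = wts.as_dict()
    opt = _nn.Adam(params, lr=cfg.lr)
    order_rng = np.random.default_rng(cfg.seed + 1)
    for _ in range(cfg.epochs):
        losses = []
        for idx in order_rng.permutation(len(prepared)):
            a, b, ta, tb = prepared[idx]
            fused, _, cache = _forward(a, b, wts)
            loss, dfused = fusion_loss_grad(fused, ta, tb, cfg.loss_weights)
            grads = _backward(dfused, wts, cache)
            opt.step(grads)
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    return FusionTraining(weights=wts, loss_trace=trace)


def fuse_pair(pair: ModalityPair, wts: FusionWeights, use_rea: bool = True) -> np.ndarray:
    """Fuse one modality pair.

    Grayscale path: fuse MR with CT directly.  Color path (``pet_rgb``
    present): fuse MR with the luma channel, re-attach chroma, return RGB.
    """
    a, b = _prepare_inputs(pair, use_rea)
    fused = forward_fuse(a, b, wts)
    if pair.pet_rgb is not None:
        _, cb, cr = to_ycbcr(pair.pet_rgb)
        return np.clip(from_ycbcr(fused, cb, cr), 0.0, 1.0)
    return fused


def average_fuse(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pixel-average baseline fusion, the reference point for training gains."""
    return 0.5 * (np.asarray(a, dtype=float) + np.asarray(b, dtype=float))
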