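"""Evaluation panels: fusion quality and the ten-metric confusion panel.

Fusion quality of a fused image F against its sources A and B reports:

* entropy of F's 256-bin intensity histogram (bits);
* mutual information, summed over sources: MI(F,A) + MI(F,B) (bits, 256x256
  joint histogram);
* PSNR and SSIM, each averaged over the two sources (PSNR capped at 100 dB
  for identical images; SSIM with the canonical 11-pixel Gaussian window,
  sigma 1.5, K1=0.01, K2=0.03);
* standard deviation of F's intensities (on the [0,1] scale).

The confusion panel computes the ten closed-form binary metrics (accuracy,
sensitivity, specificity, precision, NPV, FPR, FDR, FNR, F1, MCC) from the
2x2 counts; cells whose denominator vanishes report the documented value 0
and are listed in ``degenerate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import peak_signal_noise_ratio, structural_similarity
from sklearn.metrics import mutual_info_score

from .errors import ShapeError

__all__ = ["FusionQuality", "ConfusionPanel", "fusion_quality", "confusion_panel", "entropy_bits", "mutual_information_bits"]

PSNR_CAP = 100.0
_BINS = 256


@dataclass(frozen=True)
class FusionQuality:
    entropy: float  # bits
    mi: float  # bits, summed over the two sources
    psnr: float  # dB, mean over sources, capped
    ssim: float  # mean over sources
    std: float  # intensity units on [0,1]


@dataclass(frozen=True)
class ConfusionPanel:
    tp: int
    fp: int
    tn: int
    fn: int
    acc: float
    sen: float
    spec: float
    pr: float
    npv: float
    fpr: float
    fdr: float
    fnr: float
    f1: float
    mcc: float
    degenerate: tuple[str, ...] = field(default=())

    def as_dict(self) -> dict[str, float]:
        return {
            k: getattr(self, k)
            for k in ("acc", "sen", "spec", "pr", "npv", "fpr", "fdr", "fnr", "f1", "mcc")
        }


def entropy_bits(img: np.ndarray) -> float:
    """Shannon entropy of the 256-bin histogram of a [0,1] grid, in bits."""
    hist, _ = np.histogram(np.asarray(img, dtype=float), bins=_BINS, range=(0.0, 1.0))
    p = hist[hist > 0] / hist.sum()
    return float(-np.sum(p * np.log2(p)))


def _digitize(img: np.ndarray) -> np.ndarray:
    q = np.floor(np.clip(np.asarray(img, dtype=float), 0.0, 1.0) * _BINS).astype(int)
    return np.minimum(q, _BINS - 1)


def mutual_information_bits(x: np.ndarray, y: np.ndarray) -> float:
    """MI between two [0,1] grids from their 256x256 joint histogram, in bits."""
    if x.shape != y.shape:
        raise ShapeError("images must share a shape")
    joint = np.histogram2d(_digitize(x).ravel(), _digitize(y).ravel(), bins=_BINS, range=[[0, _BINS], [0, _BINS]])[0]
    return float(mutual_info_score(None, None, contingency=joint) / np.log(2))


def fusion_quality(fused: np.ndarray, a: np.ndarray, b: np.ndarray) -> FusionQuality:
    """Quality panel of a fused [0,1] grid against its two sources."""
    fused = np.asarray(fused, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (fused.shape == a.shape == b.shape):
        raise ShapeError("fused and source images must share a shape")

    def psnr_capped(x, y):
        if np.array_equal(x, y):
            return PSNR_CAP
        return min(peak_signal_noise_ratio(y, x, data_range=1.0), PSNR_CAP)

    def ssim_canonical(x, y):
        return structural_similarity(
            x, y, data_range=1.0, gaussian_weights=True, sigma=1.5, use_sample_covariance=False
        )

    return FusionQuality(
        entropy=entropy_bits(fused),
        mi=mutual_information_bits(fused, a) + mutual_information_bits(fused, b),
        psnr=0.5 * (psnr_capped(fused, a) + psnr_capped(fused, b)),
        ssim=0.5 * (ssim_canonical(fused, a) + ssim_canonical(fused, b)),
        std=float(fused.std()),
    )


def confusion_panel(y_true, y_pred) -> ConfusionPanel:
    """Ten binary classification/segmentation metrics from {0,1} arrays."""
    t = np.asarray(y_true).ravel().astype(int)
    p = np.asarray(y_pred).ravel().astype(int)
    if t.shape != p.shape:
        raise ShapeError("y_true and y_pred must have equal length")
    if not (np.isin(t, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ShapeError("inputs must be binary (0/1)")
    tp = int(np.sum((t == 1) & (p == 1)))
    tn = int(np.sum((t == 0) & (p == 0)))
    fp = int(np.sum((t == 0) & (p == 1)))
    fn = int(np.sum((t == 1) & (p == 0)))

    degenerate: list[str] = []

    def ratio(num, den, name):
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    acc = ratio(tp + tn, tp + tn + fp + fn, "acc")
    sen = ratio(tp, tp + fn, "sen")
    spec = ratio(tn, tn + fp, "spec")
    pr = ratio(tp, tp + fp, "pr")
    npv = ratio(tn, tn + fn, "npv")
    fpr = 1.0 - spec if "spec" not in degenerate else 0.0
    fdr = 1.0 - pr if "pr" not in degenerate else 0.0
    fnr = 1.0 - sen if "sen" not in degenerate else 0.0
    f1 = ratio(2 * tp, 2 * tp + fp + fn, "f1")
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        degenerate.append("mcc")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    return ConfusionPanel(
        tp=tp, fp=fp, tn=tn, fn=fn,
        acc=acc, sen=sen, spec=spec, pr=pr, npv=npv,
        fpr=fpr, fdr=fdr, fnr=fnr, f1=f1, mcc=mcc,
        degenerate=tuple(degenerate),
    )
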