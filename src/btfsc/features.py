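"""Hybrid texture/wavelet/color features of a tumor region.

Three extractors feed a fixed 13-entry vector:

* five gray-level co-occurrence (GLCM) statistics — contrast, homogeneity,
  correlation, angular second moment and energy = sqrt(ASM) — computed from
  a symmetric, normalized co-occurrence matrix at 8 quantization levels and
  offset (0, 1);
* six redundant-wavelet statistics — Shannon entropy, mean squared energy
  and GLCM-correlation of the level-1 and level-2 low-pass (LL) bands of an
  undecimated (a trous) Haar transform with unit DC gain and circular
  boundaries, which makes every feature exactly invariant under circular
  shifts of the input;
* two first-order color statistics — mean and population standard deviation.

Feature order: [5 GLCM, 6 RDWT, 2 color].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import graycomatrix

from .errors import ParameterError, ShapeError, SizeError

__all__ = [
    "GlcmMatrix",
    "FeatureVector",
    "glcm",
    "glcm_features",
    "rdwt_ll_bands",
    "rdwt_features",
    "color_stats",
    "hybrid_vector",
    "FEATURE_NAMES",
]

FEATURE_NAMES = (
    "glcm_contrast",
    "glcm_homogeneity",
    "glcm_correlation",
    "glcm_asm",
    "glcm_energy",
    "rdwt_entropy_l1",
    "rdwt_energy_l1",
    "rdwt_corr_l1",
    "rdwt_entropy_l2",
    "rdwt_energy_l2",
    "rdwt_corr_l2",
    "color_mean",
    "color_std",
)

#: fallback for GLCM correlation when a marginal variance vanishes
CORRELATION_DEGENERATE = 1.0


@dataclass
class GlcmMatrix:
    """Normalized co-occurrence probabilities S(a, b) with their provenance."""

    s: np.ndarray  # (levels, levels), sums to 1
    levels: int
    offset: tuple[int, int]
    symmetric: bool = True


@dataclass
class FeatureVector:
    """The 13-entry hybrid feature layout."""

    glcm: dict[str, float]
    rdwt: dict[str, float]
    color: dict[str, float]

    def as_array(self) -> np.ndarray:
        vals = list(self.glcm.values()) + list(self.rdwt.values()) + list(self.color.values())
        return np.asarray(vals, dtype=float)


def _quantize(img: np.ndarray, levels: int) -> np.ndarray:
    """Uniform quantization of a [0,1] grid into ``levels`` integer bins."""
    q = np.floor(np.clip(img, 0.0, 1.0) * levels).astype(np.uint8)
    return np.minimum(q, levels - 1)


def glcm(img: np.ndarray, levels: int = 8, offset: tuple[int, int] = (0, 1)) -> GlcmMatrix:
    """Symmetric, normalized co-occurrence matrix of a quantized [0,1] grid."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ShapeError("expected a 2-D grid")
    if levels < 2:
        raise ParameterError("need at least 2 quantization levels")
    dy, dx = offset
    if abs(dy) >= img.shape[0] or abs(dx) >= img.shape[1]:
        raise ParameterError("offset larger than the image")
    q = _quantize(img, levels)
    distance = float(np.hypot(dy, dx))
    angle = float(np.arctan2(-dy, dx))  # graycomatrix measures angles upward
    m = graycomatrix(q, [distance], [angle], levels=levels, symmetric=True, normed=True)
    return GlcmMatrix(s=m[:, :, 0, 0], levels=levels, offset=offset, symmetric=True)


def glcm_features(g: GlcmMatrix) -> dict[str, float]:
    """Contrast, homogeneity, correlation, ASM and energy of a GLCM.

    Correlation of a constant image is undefined (zero marginal variance);
    the documented fallback value 1 is returned there.
    """
    s = g.s
    n = g.levels
    a = np.arange(n, dtype=float)[:, None]
    b = np.arange(n, dtype=float)[None, :]
    contrast = float(np.sum(s * (a - b) ** 2))
    homogeneity = float(np.sum(s / (1.0 + (a - b) ** 2)))
    mu_a = float(np.sum(s * a))
    mu_b = float(np.sum(s * b))
    var_a = float(np.sum(s * (a - mu_a) ** 2))
    var_b = float(np.sum(s * (b - mu_b) ** 2))
    if var_a <= 0 or var_b <= 0:
        correlation = CORRELATION_DEGENERATE
    else:
        correlation = float(np.sum(s * (a - mu_a) * (b - mu_b)) / np.sqrt(var_a * var_b))
    asm = float(np.sum(s**2))
    return {
        "contrast": contrast,
        "homogeneity": homogeneity,
        "correlation": correlation,
        "asm": asm,
        "energy": float(np.sqrt(asm)),
    }


def _glcm_correlation_wrap(img: np.ndarray, levels: int = 8) -> float:
    """GLCM correlation with circular (0,1) offset pairing.

    The wrap-around pair multiset is exactly invariant under circular shifts
    of the image, which the shift-invariance contract of the wavelet
    features requires.
    """
    q = _quantize(img, levels).astype(int)
    right = np.roll(q, -1, axis=1)
    counts = np.zeros((levels, levels))
    np.add.at(counts, (q.ravel(), right.ravel()), 1.0)
    counts = counts + counts.T
    s = counts / counts.sum()
    return glcm_features(GlcmMatrix(s=s, levels=levels, offset=(0, 1)))["correlation"]


def rdwt_ll_bands(img: np.ndarray, levels: int = 2) -> list[np.ndarray]:
    """LL bands of an undecimated Haar transform, unit DC gain, wrap boundary.

    Level l averages each pixel with its neighbors at distance 2^(l-1)
    (a trous filter dilation), so a constant image maps to itself at every
    level.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ShapeError("expected a 2-D grid")
    if img.shape[0] < 2**levels * 2 or img.shape[1] < 2**levels * 2:
        raise SizeError(f"image too small for a {levels}-level transform")
    bands = []
    ll = img
    for level in range(levels):
        shift = 2**level
        ll = 0.25 * (
            ll
            + np.roll(ll, -shift, axis=0)
            + np.roll(ll, -shift, axis=1)
            + np.roll(np.roll(ll, -shift, axis=0), -shift, axis=1)
        )
        bands.append(ll)
    return bands


def _band_stats(ll: np.ndarray) -> tuple[float, float, float]:
    hist, _ = np.histogram(ll, bins=256, range=(0.0, 1.0))
    p = hist[hist > 0] / hist.sum()
    entropy = float(-np.sum(p * np.log2(p)))
    energy = float(np.mean(ll**2))
    corr = _glcm_correlation_wrap(ll)
    return entropy, energy, corr


def rdwt_features(img: np.ndarray, levels: int = 2) -> dict[str, float]:
    """Entropy (bits), energy and GLCM-correlation of the LL1 and LL2 bands."""
    ll1, ll2 = rdwt_ll_bands(img, levels=levels)
    e1, en1, c1 = _band_stats(ll1)
    e2, en2, c2 = _band_stats(ll2)
    return {
        "entropy_l1": e1,
        "energy_l1": en1,
        "corr_l1": c1,
        "entropy_l2": e2,
        "energy_l2": en2,
        "corr_l2": c2,
    }


def color_stats(img: np.ndarray) -> tuple[float, float]:
    """Mean and population standard deviation of the intensities.

    Defined for square grids in the source formulation (N^2 normalization);
    generalized here to any M x N grid and to multi-channel input.
    """
    img = np.asarray(img, dtype=float)
    if img.size == 0:
        raise ParameterError("empty image")
    return float(img.mean()), float(img.std())


def hybrid_vector(roi: np.ndarray, color_roi: np.ndarray | None = None) -> FeatureVector:
    """Concatenate the three extractors on a region of interest.

    ``roi`` is the (grayscale) bounding-box crop of the segmented tumor in
    the fused image; ``color_roi``, when a color modality is present, feeds
    the color statistics (otherwise they are computed from ``roi``).
    """
    roi = np.asarray(roi, dtype=float)
    if roi.size == 0:
        raise ParameterError("empty region of interest")
    g = glcm_features(glcm(roi))
    r = rdwt_features(roi)
    mean, std = color_stats(roi if color_roi is None else color_roi)
    return FeatureVector(glcm=g, rdwt=r, color={"mean": mean, "std": std})


def roi_from_mask(img: np.ndarray, mask: np.ndarray, pad: int = 2) -> np.ndarray:
    """Bounding-box crop of ``img`` around the true pixels of ``mask``."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ParameterError("mask is empty; no region to crop")
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    r0, r1 = max(rows[0] - pad, 0), min(rows[-1] + pad + 1, img.shape[0])
    c0, c1 = max(cols[0] - pad, 0), min(cols[-1] + pad + 1, img.shape[1])
    return np.asarray(img, dtype=float)[r0:r1, c0:c1]
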