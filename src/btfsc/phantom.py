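"""Synthetic paired-modality brain phantoms with planted tumors.

Every downstream stage of the pipeline (denoising, fusion, segmentation,
feature extraction, classification) is exercised against phantoms generated
here, so ground truth — the clean image, the tumor mask, the class label and
the injected noise level — is always known exactly.

Conventions
-----------
Images ("grids") are 2-D ``float64`` arrays with values in [0, 1].  Noise
levels (``noise_sigma``) are quoted on the 8-bit 0–255 intensity scale, the
scale on which the denoiser's mask-selection rule is defined, and are divided
by 255 internally.

A phantom is a skull ellipse containing two nested soft-tissue plateaus and
an optional tumor.  The two modalities are co-registered by construction:
the MR-like channel emphasizes soft-tissue contrast and the tumor interior
(hyperintense, with internal texture for malignant tumors), while the
CT-like channel emphasizes the bone ring and edges.  Malignant tumors differ
from benign ones in two ways that downstream texture features can detect: a
radially irregular boundary (low-order Fourier perturbation of the ellipse)
and band-limited multiplicative interior texture.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import GeometryError, ParameterError

__all__ = [
    "PhantomSpec",
    "ModalityPair",
    "generate_phantom_pair",
    "add_gaussian_noise",
    "generate_labeled_dataset",
    "pseudo_pet",
]

# intensity plateaus shared by the two modality renderings
_MR_BACKGROUND = 0.05
_MR_SKULL = 0.15
_MR_TUMOR = 0.88
_CT_BACKGROUND = 0.02
_CT_SKULL = 0.80
_CT_TISSUE = 0.25
_CT_INNER = 0.30
_CT_TUMOR = 0.38
# fraction of the skull ellipse occupied by bone
_SKULL_BAND = 0.88
# tumor texture field is clipped at this many standard deviations
_TEXTURE_CLIP = 1.5


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom; identical specs yield identical pairs.

    ``tissue_levels`` are the soft-tissue intensity plateaus of the MR-like
    channel, outermost first; they must be pairwise distinct by >= 0.1 so the
    clustering stage has separable structure.  ``boundary_irregularity`` is
    the relative amplitude of the tumor-boundary perturbation (0 = smooth
    ellipse; benign tumors must be 0).  ``texture_amplitude`` is the relative
    amplitude of the malignant interior texture.
    """

    height: int = 128
    width: int = 128
    skull_axes: tuple[float, float] = (52.0, 44.0)
    tissue_levels: tuple[float, ...] = (0.35,)
    tumor_center: tuple[float, float] = (64.0, 70.0)
    tumor_axes: tuple[float, float] = (14.0, 11.0)
    tumor_class: Literal["benign", "malignant"] = "benign"
    boundary_irregularity: float = 0.0
    texture_amplitude: float = 0.15
    noise_sigma: float = 10.0
    include_pet: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.height < 16 or self.width < 16:
            raise ParameterError("phantom must be at least 16x16")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be nonnegative")
        if self.boundary_irregularity < 0:
            raise ParameterError("boundary_irregularity must be >= 0")
        if self.tumor_class == "benign" and self.boundary_irregularity != 0:
            raise ParameterError("benign tumors have boundary_irregularity 0")
        levels = np.asarray(self.tissue_levels, dtype=float)
        if np.any((levels < 0) | (levels > 1)):
            raise ParameterError("tissue levels must lie in [0, 1]")
        diffs = np.abs(levels[:, None] - levels[None, :])
        if np.any(diffs[np.triu_indices(len(levels), 1)] < 0.1):
            raise ParameterError("tissue plateaus must be distinct by >= 0.1")
        self._check_tumor_inside_skull()

    def _check_tumor_inside_skull(self) -> None:
        a_t, b_t = self.tumor_axes
        if a_t < 0 or b_t < 0:
            raise ParameterError("tumor axes must be nonnegative")
        if a_t == 0 or b_t == 0:
            return  # no tumor planted
        cy, cx = self.height / 2, self.width / 2
        ty, tx = self.tumor_center
        a_s, b_s = self.skull_axes
        # worst-case boundary radius includes the irregularity amplitude
        theta = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        r = _ellipse_radius(a_t, b_t, theta) * (1.0 + self.boundary_irregularity)
        by = ty - cy + r * np.sin(theta)
        bx = tx - cx + r * np.cos(theta)
        inside = (by / (_SKULL_BAND * a_s)) ** 2 + (bx / (_SKULL_BAND * b_s)) ** 2
        if np.any(inside >= 1.0):
            raise GeometryError("tumor ellipse extends outside the skull interior")


@dataclass
class ModalityPair:
    """Co-registered modality pair plus ground truth for one phantom."""

    mr: np.ndarray
    ct: np.ndarray
    truth_mask: np.ndarray
    label: Literal["benign", "malignant"]
    pet_rgb: np.ndarray | None = None
    clean_mr: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    clean_ct: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    spec: PhantomSpec | None = None


def _ellipse_radius(a: float, b: float, theta: np.ndarray) -> np.ndarray:
    """Radius of an axis-aligned ellipse (semi-axes a along y, b along x)."""
    return (a * b) / np.sqrt((b * np.sin(theta)) ** 2 + (a * np.cos(theta)) ** 2)


def _tumor_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    a_t, b_t = spec.tumor_axes
    if a_t == 0 or b_t == 0:
        return np.zeros((spec.height, spec.width), dtype=bool)
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    dy = yy - spec.tumor_center[0]
    dx = xx - spec.tumor_center[1]
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    base = _ellipse_radius(a_t, b_t, theta)
    if spec.boundary_irregularity > 0:
        # low-order Fourier perturbation; amplitudes normalized so the total
        # relative excursion is bounded by boundary_irregularity
        modes = np.arange(3, 7)
        amps = rng.normal(size=modes.size)
        amps *= spec.boundary_irregularity / max(np.sum(np.abs(amps)), 1e-12)
        phases = rng.uniform(0, 2 * np.pi, size=modes.size)
        pert = np.zeros_like(theta)
        for m, a, p in zip(modes, amps, phases):
            pert += a * np.cos(m * theta + p)
        base = base * (1.0 + pert)
    else:
        # keep the generator's random stream layout identical for both classes
        rng.normal(size=4)
        rng.uniform(0, 2 * np.pi, size=4)
    return rho <= base


def _render(spec: PhantomSpec, mask: np.ndarray, rng: np.random.Generator):
    """Render the clean MR-like and CT-like channels."""
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    cy, cx = spec.height / 2, spec.width / 2
    a_s, b_s = spec.skull_axes
    r2 = ((yy - cy) / a_s) ** 2 + ((xx - cx) / b_s) ** 2
    skull = r2 <= 1.0
    interior = r2 <= _SKULL_BAND**2
    bone = skull & ~interior

    mr = np.full((spec.height, spec.width), _MR_BACKGROUND)
    ct = np.full((spec.height, spec.width), _CT_BACKGROUND)
    mr[bone] = _MR_SKULL
    ct[bone] = _CT_SKULL
    mr[interior] = spec.tissue_levels[0]
    ct[interior] = _CT_TISSUE
    # nested plateaus shrink toward the centre
    for i, level in enumerate(spec.tissue_levels[1:], start=1):
        scale = _SKULL_BAND * (1.0 - 0.3 * i)
        inner = ((yy - cy) / (scale * a_s)) ** 2 + ((xx - cx) / (scale * b_s)) ** 2 <= 1.0
        mr[inner] = level
        ct[inner] = _CT_INNER

    tumor_mr = np.full_like(mr, _MR_TUMOR)
    if spec.tumor_class == "malignant" and spec.texture_amplitude > 0:
        # band-limited multiplicative texture: smoothed white noise,
        # unit variance, clipped
        t = gaussian_filter(rng.normal(size=mr.shape), sigma=1.5)
        t /= max(t.std(), 1e-12)
        t = np.clip(t, -_TEXTURE_CLIP, _TEXTURE_CLIP)
        tumor_mr = tumor_mr * (1.0 + spec.texture_amplitude * t)
    else:
        rng.normal(size=mr.shape)  # keep stream layout identical
    mr[mask] = np.clip(tumor_mr[mask], 0.0, 1.0)
    ct[mask] = _CT_TUMOR
    return mr, ct


def pseudo_pet(img: np.ndarray) -> np.ndarray:
    """Map a [0,1] grayscale grid to RGB via a fixed 'hot' colormap.

    r, g, b ramp up in succession (r on [0,1/3], g on [1/3,2/3], b on
    [2/3,1]); the map is monotone in luminance and documented so the YCbCr
    fusion path has a deterministic color modality to exercise.
    """
    v = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    r = np.clip(3.0 * v, 0.0, 1.0)
    g = np.clip(3.0 * v - 1.0, 0.0, 1.0)
    b = np.clip(3.0 * v - 2.0, 0.0, 1.0)
    return np.stack([r, g, b], axis=-1)


def add_gaussian_noise(img: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Additive zero-mean Gaussian noise, X = O + G, clipped to [0, 1].

    ``sigma`` is on the 0–255 intensity scale.  ``sigma = 0`` returns the
    input unchanged (a copy).
    """
    if sigma < 0:
        raise ParameterError("sigma must be nonnegative")
    img = np.asarray(img, dtype=float)
    if sigma == 0:
        return img.copy()
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma / 255.0, size=img.shape)
    return np.clip(img + noise, 0.0, 1.0)


def generate_phantom_pair(spec: PhantomSpec) -> ModalityPair:
    """Generate one co-registered phantom pair from a spec.

    Deterministic for a fixed spec (including its seed): geometry, texture
    and noise each draw from independent child streams of ``spec.seed``, so
    the same spec with ``noise_sigma=0`` yields exactly the clean images that
    underlie a noisy render.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    structure_ss, mr_noise_ss, ct_noise_ss = ss.spawn(3)
    rng = np.random.default_rng(structure_ss)

    mask = _tumor_mask(spec, rng)
    clean_mr, clean_ct = _render(spec, mask, rng)
    mr = add_gaussian_noise(clean_mr, spec.noise_sigma, mr_noise_ss.generate_state(1)[0])
    ct = add_gaussian_noise(clean_ct, spec.noise_sigma, ct_noise_ss.generate_state(1)[0])
    pet = pseudo_pet(mr) if spec.include_pet else None
    return ModalityPair(
        mr=mr,
        ct=ct,
        truth_mask=mask,
        label=spec.tumor_class,
        pet_rgb=pet,
        clean_mr=clean_mr,
        clean_ct=clean_ct,
        spec=spec,
    )


def generate_labeled_dataset(
    n: int,
    class_balance: float,
    seed: int,
    *,
    height: int = 128,
    width: int = 128,
    noise_sigma: float = 10.0,
    include_pet: bool = False,
) -> list[ModalityPair]:
    """Generate ``n`` phantom pairs with randomized geometry and labels.

    ``class_balance`` is the benign fraction; the benign count is
    ``round(n * class_balance)`` (round half to even), the documented
    rounding rule.  Per-item seeds are drawn from a generator seeded with the
    master seed, so the dataset is reproducible item by item.
    """
    if n < 2:
        raise ParameterError("need at least 2 phantoms")
    if not 0 < class_balance < 1:
        raise ParameterError("class_balance must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_benign = int(round(n * class_balance))
    labels = np.array(["benign"] * n_benign + ["malignant"] * (n - n_benign))
    rng.shuffle(labels)
    item_seeds = rng.integers(0, 2**31 - 1, size=n)

    pairs = []
    for label, item_seed in zip(labels, item_seeds):
        label = str(label)
        geo = np.random.default_rng(item_seed)
        cy = height / 2 + geo.uniform(-0.06, 0.06) * height
        cx = width / 2 + geo.uniform(-0.06, 0.06) * width
        a_t = geo.uniform(0.08, 0.12) * height
        b_t = geo.uniform(0.065, 0.10) * width
        malignant = label == "malignant"
        spec = PhantomSpec(
            height=height,
            width=width,
            skull_axes=(0.41 * height, 0.34 * width),
            tumor_center=(cy, cx),
            tumor_axes=(a_t, b_t),
            tumor_class=label,  # type: ignore[arg-type]
            boundary_irregularity=geo.uniform(0.25, 0.45) if malignant else 0.0,
            texture_amplitude=geo.uniform(0.12, 0.20) if malignant else 0.0,
            noise_sigma=noise_sigma,
            include_pet=include_pet,
            seed=int(item_seed),
        )
        pairs.append(generate_phantom_pair(spec))
    return pairs


def clean_spec(spec: PhantomSpec) -> PhantomSpec:
    """The same phantom without acquisition noise (identical geometry/texture)."""
    return replace(spec, noise_sigma=0.0)
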