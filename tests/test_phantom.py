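"""Phantom generator: determinism, geometry, class structure, noise model."""

import numpy as np
import pytest
from skimage.measure import perimeter

from btfsc.errors import GeometryError, ParameterError
from btfsc.phantom import (
    PhantomSpec,
    add_gaussian_noise,
    generate_labeled_dataset,
    generate_phantom_pair,
)


class TestGeneratePhantomPair:
    def test_deterministic_for_fixed_spec(self):
        spec = PhantomSpec(tumor_class="malignant", boundary_irregularity=0.3, seed=4)
        p1 = generate_phantom_pair(spec)
        p2 = generate_phantom_pair(spec)
        assert np.array_equal(p1.mr, p2.mr)
        assert np.array_equal(p1.ct, p2.ct)
        assert np.array_equal(p1.truth_mask, p2.truth_mask)

    def test_empty_tumor_gives_empty_mask(self):
        p = generate_phantom_pair(PhantomSpec(tumor_axes=(0, 0)))
        assert not p.truth_mask.any()

    def test_tumor_outside_skull_rejected(self):
        spec = PhantomSpec(tumor_center=(64.0, 120.0))
        with pytest.raises(GeometryError):
            generate_phantom_pair(spec)

    def test_malignant_boundary_less_compact_than_benign(self):
        kw = dict(tumor_axes=(14.0, 11.0), noise_sigma=0.0, seed=2)
        benign = generate_phantom_pair(PhantomSpec(tumor_class="benign", **kw))
        malignant = generate_phantom_pair(
            PhantomSpec(tumor_class="malignant", boundary_irregularity=0.35, **kw)
        )

        def compactness(mask):
            return perimeter(mask) ** 2 / mask.sum()

        assert compactness(malignant.truth_mask) > compactness(benign.truth_mask)

    def test_mask_pixels_contrast_against_surrounding_plateau(self):
        spec = PhantomSpec(
            tumor_class="malignant", boundary_irregularity=0.3, noise_sigma=0.0, seed=3
        )
        p = generate_phantom_pair(spec)
        plateau = max(spec.tissue_levels)
        assert np.all(np.abs(p.mr[p.truth_mask] - plateau) >= 0.1)

    def test_benign_spec_with_irregular_boundary_rejected(self):
        with pytest.raises(ParameterError):
            generate_phantom_pair(
                PhantomSpec(tumor_class="benign", boundary_irregularity=0.2)
            )

    def test_pseudo_pet_is_rgb_of_mr_luminance_order(self):
        p = generate_phantom_pair(PhantomSpec(include_pet=True, seed=5))
        assert p.pet_rgb.shape == p.mr.shape + (3,)
        assert p.pet_rgb.min() >= 0 and p.pet_rgb.max() <= 1


class TestAddGaussianNoise:
    def test_sigma_zero_is_identity(self, rng):
        img = rng.uniform(0, 1, (32, 32))
        assert np.array_equal(add_gaussian_noise(img, 0.0, 1), img)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ParameterError):
            add_gaussian_noise(np.zeros((8, 8)), -1.0, 0)

    def test_residual_std_matches_sigma(self):
        img = np.full((256, 256), 128 / 255)
        noisy = add_gaussian_noise(img, 10.0, 0)
        resid = (noisy - img) * 255
        clipped = (noisy == 0) | (noisy == 1)
        std = resid[~clipped].std()
        assert abs(std - 10.0) <= 0.5

    def test_seeded_noise_reproducible(self, rng):
        img = rng.uniform(0.2, 0.8, (64, 64))
        assert np.array_equal(add_gaussian_noise(img, 12.0, 9), add_gaussian_noise(img, 12.0, 9))

    def test_noise_calibration_improves_with_area(self):
        img = np.full((512, 512), 0.5)
        noisy = add_gaussian_noise(img, 15.0, 3)
        std = ((noisy - img) * 255).std()
        assert abs(std - 15.0) / 15.0 <= 0.03


class TestGenerateLabeledDataset:
    def test_exact_balance(self):
        pairs = generate_labeled_dataset(10, 0.5, 1)
        labels = [p.label for p in pairs]
        assert labels.count("benign") == 5 and labels.count("malignant") == 5

    def test_rounding_rule_on_odd_counts(self):
        labels = [p.label for p in generate_labeled_dataset(3, 0.5, 1)]
        assert labels.count("benign") == round(3 * 0.5)

    def test_reproducible_and_sized(self):
        a = generate_labeled_dataset(6, 0.5, 42)
        b = generate_labeled_dataset(6, 0.5, 42)
        assert len(a) == 6
        assert all(np.array_equal(x.mr, y.mr) for x, y in zip(a, b))
        assert [x.label for x in a] == [y.label for y in b]

    @pytest.mark.parametrize("n,balance", [(1, 0.5), (10, 0.0), (10, 1.0)])
    def test_parameter_validation(self, n, balance):
        with pytest.raises(ParameterError):
            generate_labeled_dataset(n, balance, 0)
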