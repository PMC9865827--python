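"""Hybrid features: GLCM formulas, redundant-wavelet stats, color stats."""

import numpy as np
import pytest

from btfsc.errors import ParameterError
from btfsc.features import (
    FEATURE_NAMES,
    color_stats,
    glcm,
    glcm_features,
    hybrid_vector,
    rdwt_features,
    rdwt_ll_bands,
    roi_from_mask,
)


def glcm_oracle(img, levels=8, offset=(0, 1)):
    """Independent double-loop GLCM + feature evaluation."""
    q = np.minimum(np.floor(np.clip(img, 0, 1) * levels).astype(int), levels - 1)
    h, w = q.shape
    dy, dx = offset
    counts = np.zeros((levels, levels))
    for i in range(h):
        for j in range(w):
            i2, j2 = i + dy, j + dx
            if 0 <= i2 < h and 0 <= j2 < w:
                counts[q[i, j], q[i2, j2]] += 1
                counts[q[i2, j2], q[i, j]] += 1
    s = counts / counts.sum()
    a = np.arange(levels)[:, None]
    b = np.arange(levels)[None, :]
    mu_a, mu_b = (s * a).sum(), (s * b).sum()
    va = (s * (a - mu_a) ** 2).sum()
    vb = (s * (b - mu_b) ** 2).sum()
    corr = ((s * (a - mu_a) * (b - mu_b)).sum() / np.sqrt(va * vb)) if va > 0 and vb > 0 else 1.0
    asm = (s**2).sum()
    return {
        "contrast": (s * (a - b) ** 2).sum(),
        "homogeneity": (s / (1 + (a - b) ** 2)).sum(),
        "correlation": corr,
        "asm": asm,
        "energy": np.sqrt(asm),
    }


class TestGlcm:
    def test_constant_image_single_entry(self):
        g = glcm(np.full((6, 6), 0.4))
        assert g.s.sum() == pytest.approx(1.0)
        assert np.count_nonzero(g.s) == 1

    def test_two_by_two_alternating_pattern(self):
        img = np.array([[0.0, 0.9], [0.0, 0.9]])
        g = glcm(img, levels=2)
        assert g.s[0, 1] == pytest.approx(0.5)
        assert g.s[1, 0] == pytest.approx(0.5)

    def test_normalization(self, rng):
        g = glcm(rng.uniform(0, 1, (12, 12)))
        assert abs(g.s.sum() - 1.0) < 1e-12

    def test_oversized_offset_rejected(self):
        with pytest.raises(ParameterError):
            glcm(np.zeros((4, 4)), offset=(0, 10))


class TestGlcmFeatures:
    def test_constant_image_degenerate_values(self):
        f = glcm_features(glcm(np.full((5, 5), 0.2)))
        assert f["contrast"] == 0
        assert f["homogeneity"] == 1
        assert f["asm"] == 1 and f["energy"] == 1
        assert f["correlation"] == 1  # documented fallback

    def test_alternating_pattern_closed_forms(self):
        f = glcm_features(glcm(np.array([[0.0, 0.9], [0.0, 0.9]]), levels=2))
        assert f["contrast"] == pytest.approx(1.0)
        assert f["homogeneity"] == pytest.approx(0.5)
        assert f["asm"] == pytest.approx(0.5)
        assert f["energy"] == pytest.approx(np.sqrt(0.5))
        assert f["correlation"] == pytest.approx(-1.0)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(10):
            img = rng.uniform(0, 1, (8, 8))
            mine = glcm_features(glcm(img))
            ref = glcm_oracle(img)
            for k in mine:
                assert mine[k] == pytest.approx(ref[k], abs=1e-10)


class TestRdwtFeatures:
    def test_constant_image_degenerate(self):
        f = rdwt_features(np.full((16, 16), 0.3))
        assert f["entropy_l1"] == 0 and f["entropy_l2"] == 0
        assert f["energy_l1"] == pytest.approx(0.09)
        assert f["energy_l2"] == pytest.approx(0.09)

    def test_circular_shift_invariance(self, rng):
        img = rng.uniform(0, 1, (32, 32))
        f1 = rdwt_features(img)
        f2 = rdwt_features(np.roll(np.roll(img, 3, axis=0), 5, axis=1))
        for k in f1:
            assert abs(f1[k] - f2[k]) < 1e-8

    def test_malignant_texture_raises_ll_entropy(self):
        from btfsc.phantom import PhantomSpec, generate_phantom_pair

        kw = dict(noise_sigma=0.0, seed=7)
        benign = generate_phantom_pair(PhantomSpec(**kw))
        malignant = generate_phantom_pair(
            PhantomSpec(tumor_class="malignant", boundary_irregularity=0.3, **kw)
        )
        rb = roi_from_mask(benign.mr, benign.truth_mask)
        rm = roi_from_mask(malignant.mr, malignant.truth_mask)
        assert rdwt_features(rm)["entropy_l1"] > rdwt_features(rb)["entropy_l1"]

    def test_ll_band_agrees_with_pywt_swt_up_to_gain(self, rng):
        pywt = pytest.importorskip("pywt")
        img = rng.uniform(0, 1, (32, 32))
        mine = rdwt_ll_bands(img)[0]
        ref = pywt.swt2(img, "haar", level=1)[0][0] / 2.0  # orthonormal 2-D gain
        # compare away from the boundary rows/cols where extension modes differ
        corr = np.corrcoef(mine[8:-8, 8:-8].ravel(), ref[8:-8, 8:-8].ravel())[0, 1]
        assert corr > 0.999


class TestColorStats:
    def test_constant(self):
        assert color_stats(np.full((4, 4), 0.6)) == (pytest.approx(0.6), pytest.approx(0.0))

    def test_small_grid_closed_form(self):
        mean, std = color_stats(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert mean == pytest.approx(2.5)
        assert std == pytest.approx(np.sqrt(1.25))

    def test_matches_two_pass_oracle(self, rng):
        img = rng.uniform(size=(9, 7))
        mean, std = color_stats(img)
        mu = img.sum() / img.size
        sd = np.sqrt(((img - mu) ** 2).sum() / img.size)
        assert mean == pytest.approx(mu, abs=1e-12)
        assert std == pytest.approx(sd, abs=1e-12)


class TestHybridVector:
    def test_length_and_finiteness(self, rng):
        vec = hybrid_vector(rng.uniform(0, 1, (20, 20))).as_array()
        assert vec.shape == (13,)
        assert np.isfinite(vec).all()
        assert len(FEATURE_NAMES) == 13

    def test_concatenation_matches_sub_extractors(self, rng):
        roi = rng.uniform(0, 1, (16, 16))
        fv = hybrid_vector(roi)
        assert fv.glcm == glcm_features(glcm(roi))
        assert fv.rdwt == rdwt_features(roi)
        assert fv.color == dict(zip(("mean", "std"), color_stats(roi)))

    def test_deterministic(self, rng):
        roi = rng.uniform(0, 1, (16, 16))
        assert np.array_equal(hybrid_vector(roi).as_array(), hybrid_vector(roi).as_array())

    def test_empty_mask_rejected(self):
        with pytest.raises(ParameterError):
            roi_from_mask(np.zeros((8, 8)), np.zeros((8, 8), dtype=bool))
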