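"""Fusion network: color conversion, forward oracle, gradients, training."""

import numpy as np
import pytest
from skimage.metrics import structural_similarity as ssim

from btfsc.errors import ParameterError, ShapeError
from btfsc.fusion import (
    FusionConfig,
    FusionWeights,
    average_fuse,
    forward_fuse,
    from_ycbcr,
    fuse_pair,
    fusion_loss_grad,
    to_ycbcr,
    train_fusion,
)
from btfsc.phantom import pseudo_pet


def naive_same_conv(x, w, bias):
    """Loop-based same-padding convolution oracle, (C,H,W) -> (F,H,W)."""
    c, h, wd = x.shape
    f = w.shape[0]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    y = np.zeros((f, h, wd))
    for fi in range(f):
        for i in range(h):
            for j in range(wd):
                y[fi, i, j] = np.sum(xp[:, i : i + 3, j : j + 3] * w[fi]) + bias[fi]
    return y


class TestYcbcr:
    def test_gray_axis_maps_to_neutral_chroma(self, rng):
        v = rng.uniform(0, 1, (8, 8))
        y, cb, cr = to_ycbcr(np.stack([v, v, v], axis=-1))
        assert np.allclose(y, v)
        assert np.allclose(cb, 0.5) and np.allclose(cr, 0.5)

    def test_round_trip(self, rng):
        rgb = rng.uniform(0, 1, (10, 10, 3))
        back = from_ycbcr(*to_ycbcr(rgb))
        assert np.abs(back - rgb).max() < 1e-6

    def test_pure_red_luma(self):
        red = np.zeros((2, 2, 3))
        red[..., 0] = 1.0
        y, _, _ = to_ycbcr(red)
        assert y == pytest.approx(np.full((2, 2), 0.299))

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ShapeError):
            to_ycbcr(np.zeros((4, 4, 2)))


class TestForwardFuse:
    def test_zero_weights_zero_output(self, rng):
        wts = FusionWeights.initialize(0, stage1=4, stage2=6)
        for k, v in wts.as_dict().items():
            v[...] = 0.0
        out = forward_fuse(rng.uniform(size=(8, 8)), rng.uniform(size=(8, 8)), wts)
        assert np.array_equal(out, np.zeros((8, 8)))

    def test_stage2_maps_identical(self, rng):
        wts = FusionWeights.initialize(1, stage1=4, stage2=6)
        _, (f1, f2, f3, f4) = forward_fuse(
            rng.uniform(size=(12, 12)), rng.uniform(size=(12, 12)), wts, return_maps=True
        )
        assert np.array_equal(f3, f4)

    def test_matches_loop_convolution_oracle(self, rng):
        wts = FusionWeights.initialize(7, stage1=4, stage2=6)
        a = rng.uniform(0, 1, (16, 16))
        b = rng.uniform(0, 1, (16, 16))
        fused = forward_fuse(a, b, wts)
        f1 = np.maximum(naive_same_conv(a[None], wts.w1, wts.b1), 0)
        f2 = np.maximum(naive_same_conv(b[None], wts.w1, wts.b1), 0)
        f3 = np.maximum(naive_same_conv(f1 + f2, wts.w2, wts.b2), 0)
        expected = np.clip(
            np.maximum(naive_same_conv(np.concatenate([f3, f3]), wts.w3, wts.b3), 0), 0, 1
        )
        assert np.abs(fused - expected[0]).max() < 1e-5

    def test_shape_mismatch_rejected(self):
        wts = FusionWeights.initialize(0, stage1=2, stage2=2)
        with pytest.raises(ShapeError):
            forward_fuse(np.zeros((8, 8)), np.zeros((8, 9)), wts)


class TestLossGradient:
    def test_analytic_gradient_matches_finite_differences(self, rng):
        f = rng.uniform(0.2, 0.8, (12, 12))
        a = rng.uniform(0, 1, (12, 12))
        b = rng.uniform(0, 1, (12, 12))
        loss, grad = fusion_loss_grad(f, a, b, (0.4, 0.4, 0.2))
        eps = 1e-6
        for _ in range(10):
            i, j = rng.integers(0, 12, 2)
            fp = f.copy()
            fp[i, j] += eps
            lp, _ = fusion_loss_grad(fp, a, b, (0.4, 0.4, 0.2))
            assert (lp - loss) / eps == pytest.approx(grad[i, j], abs=1e-5)


class TestTrainFusion:
    def test_zero_epochs_returns_untouched_init(self, small_pairs):
        res = train_fusion(small_pairs, FusionConfig(epochs=0, seed=5))
        ref = FusionWeights.initialize(5)
        assert res.loss_trace == []
        assert np.array_equal(res.weights.w1, ref.w1)

    def test_short_training_reduces_loss(self, small_pairs):
        res = train_fusion(small_pairs[:4], FusionConfig(epochs=3, seed=2), use_rea=False)
        assert res.loss_trace[-1] < res.loss_trace[0]

    def test_empty_pair_list_rejected(self):
        with pytest.raises(ParameterError):
            train_fusion([], FusionConfig(epochs=1))

    def test_bad_loss_weights_rejected(self):
        with pytest.raises(ParameterError):
            FusionConfig(loss_weights=(0.0, 0.0, 0.0))


class TestFusePair:
    def test_color_path_on_gray_rgb_matches_gray_path(self, small_pairs):
        import dataclasses

        wts = FusionWeights.initialize(3)
        pair = small_pairs[0]
        gray = fuse_pair(pair, wts, use_rea=False)
        v = pair.ct
        rgb_pair = dataclasses.replace(pair, pet_rgb=np.stack([v, v, v], axis=-1))
        color = fuse_pair(rgb_pair, wts, use_rea=False)
        assert np.abs(color - gray[..., None]).max() < 1e-3

    def test_rea_toggle_keeps_output_in_range(self, small_pairs):
        wts = FusionWeights.initialize(3)
        for use_rea in (True, False):
            out = fuse_pair(small_pairs[0], wts, use_rea=use_rea)
            assert out.min() >= 0 and out.max() <= 1

    def test_pseudo_pet_fusion_returns_rgb(self, small_pairs):
        import dataclasses

        wts = FusionWeights.initialize(3)
        pair = small_pairs[0]
        rgb_pair = dataclasses.replace(pair, pet_rgb=pseudo_pet(pair.mr))
        out = fuse_pair(rgb_pair, wts, use_rea=False)
        assert out.shape == pair.mr.shape + (3,)
        assert out.min() >= 0 and out.max() <= 1


def test_average_fuse_is_pixel_mean(rng):
    a = rng.uniform(size=(6, 6))
    b = rng.uniform(size=(6, 6))
    assert np.allclose(average_fuse(a, b), (a + b) / 2)
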