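"""Weighted-ranking k-means init + fuzzy c-means segmentation."""

import numpy as np
import pytest

from btfsc.errors import DegenerateInputError, ParameterError
from btfsc.segmentation import akmc_init, fkcm_iterate, segment, weighted_points


class TestWeightedPoints:
    def test_unit_weight_is_identity(self):
        wp = weighted_points(np.array([3.0, 1.0, 2.0]), [1.0])
        assert np.allclose(wp.u, [3.0, 1.0, 2.0])
        assert list(wp.order) == [1, 2, 0]

    def test_scalar_weight_scales(self):
        wp = weighted_points(np.array([1.0, 2.0, 3.0]), [0.5])
        assert np.allclose(wp.u, [0.5, 1.0, 1.5])

    def test_shared_weight_preserves_rank(self, rng):
        v = rng.normal(size=50)
        assert np.array_equal(
            weighted_points(v, [2.7]).order, weighted_points(v, [1.0]).order
        )

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ParameterError):
            weighted_points(np.array([1.0, 2.0]), [0.0])


class TestAkmcInit:
    def test_block_means_of_sorted_points(self):
        wp = weighted_points(np.array([1.0, 2, 3, 4, 5, 6]), [1.0])
        assert np.allclose(akmc_init(wp, 2), [2.0, 5.0])

    def test_k_equals_n_gives_sorted_points(self):
        wp = weighted_points(np.array([5.0, 1.0, 3.0]), [1.0])
        assert np.allclose(akmc_init(wp, 3), [1.0, 3.0, 5.0])

    def test_deterministic(self, rng):
        wp = weighted_points(rng.normal(size=30), [1.0])
        assert np.array_equal(akmc_init(wp, 4), akmc_init(wp, 4))

    def test_k_larger_than_n_rejected(self):
        wp = weighted_points(np.array([1.0, 2.0]), [1.0])
        with pytest.raises(ParameterError):
            akmc_init(wp, 3)


class TestFkcmIterate:
    def test_single_cluster_closed_form(self, rng):
        v = rng.normal(size=40)
        wp = weighted_points(v, [1.0])
        model = fkcm_iterate(wp, np.array([0.0]))
        assert model.centroids[0] == pytest.approx(v.mean())
        assert np.allclose(model.memberships, 1.0)

    def test_planted_two_gaussian_recovery(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(0, 0.5, 100), rng.normal(10, 0.5, 100)])
        wp = weighted_points(x, [1.0])
        model = fkcm_iterate(wp, akmc_init(wp, 2))
        c = np.sort(model.centroids)
        assert abs(c[0] - 0.0) <= 0.3 and abs(c[1] - 10.0) <= 0.3
        own = model.memberships[np.arange(200), np.argsort(model.centroids)[(x > 5).astype(int)]]
        assert own.min() >= 0.9

    def test_objective_trace_non_increasing(self, rng):
        wp = weighted_points(rng.uniform(size=300), [1.0])
        model = fkcm_iterate(wp, akmc_init(wp, 3))
        trace = np.asarray(model.objective_trace)
        assert np.all(np.diff(trace) <= 1e-9)

    def test_membership_rows_sum_to_one(self, rng):
        wp = weighted_points(rng.uniform(size=200), [1.0])
        model = fkcm_iterate(wp, akmc_init(wp, 4))
        assert np.allclose(model.memberships.sum(axis=1), 1.0, atol=1e-9)

    def test_coincident_point_gets_hard_membership(self):
        wp = weighted_points(np.array([0.0, 1.0, 2.0]), [1.0])
        model = fkcm_iterate(wp, np.array([0.0, 2.0]), max_iter=1)
        assert model.memberships[0, 0] == 1.0

    def test_fuzzifier_must_exceed_one(self, rng):
        wp = weighted_points(rng.uniform(size=10), [1.0])
        with pytest.raises(ParameterError):
            fkcm_iterate(wp, np.array([0.1, 0.9]), m=1.0)


class TestSegment:
    def test_two_level_disc_recovered_exactly(self):
        rng = np.random.default_rng(0)
        img = np.full((40, 40), 0.2)
        yy, xx = np.mgrid[:40, :40]
        disc = (yy - 20) ** 2 + (xx - 20) ** 2 <= 100
        img[disc] = 0.8
        img = np.clip(img + rng.normal(0, 1e-3, img.shape), 0, 1)
        res = segment(img, 2, local_mean=False)
        assert np.array_equal(res.tumor_mask, disc)

    def test_planted_tumor_dice(self, malignant_pair):
        from btfsc.denoise import hpwf_denoise

        den = hpwf_denoise(malignant_pair.mr).output
        res = segment(den, 4)
        truth = malignant_pair.truth_mask
        dice = 2 * (res.tumor_mask & truth).sum() / (res.tumor_mask.sum() + truth.sum())
        assert dice >= 0.8

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateInputError):
            segment(np.full((20, 20), 0.5), 2)

    def test_label_map_matches_memberships_argmax(self, malignant_pair):
        from btfsc.denoise import hpwf_denoise

        den = hpwf_denoise(malignant_pair.mr).output
        res = segment(den, 4)
        assert np.array_equal(
            res.label_map.ravel(), res.model.memberships.argmax(axis=1)
        )
        assert np.array_equal(res.tumor_mask, res.label_map == res.tumor_cluster_id)
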