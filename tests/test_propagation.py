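"""Geodesic ordering, pairwise weights, confidence, and the ordered filter."""

import numpy as np
import pytest

from histopatch import (
    GuidedImage,
    PropagationParams,
    ReliabilityMask,
    compute_order_field,
    ordered_filter,
    pair_weight_B,
    pair_weight_G,
    propagate_confidence,
    reduced_distance_decay_filter,
)


def make_mask(reliable):
    return ReliabilityMask(mask=np.asarray(reliable, dtype=bool), tau=0.1, window_radius=1)


def bfs_chessboard_oracle(reliable):
    """Breadth-first 8-neighbor distance to the reliable set."""
    h, w = reliable.shape
    T = np.full((h, w), -1, int)
    frontier = list(zip(*np.nonzero(reliable)))
    for i, j in frontier:
        T[i, j] = 0
    t = 0
    while frontier:
        t += 1
        nxt = []
        for i, j in frontier:
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    y, x = i + di, j + dj
                    if 0 <= y < h and 0 <= x < w and T[y, x] < 0:
                        T[y, x] = t
                        nxt.append((y, x))
        frontier = nxt
    return T


class TestPairWeights:
    def test_B_identical_pixels_is_one(self):
        assert pair_weight_B([0.2, 0.3, 0.4], [0.2, 0.3, 0.4], 0.5, 0.5, 100, 1e4) == 1.0

    def test_B_zero_gammas_is_one_for_any_pair(self):
        assert pair_weight_B([0.0, 0.0, 0.0], [1.0, 1.0, 1.0], 0.0, 1.0, 0.0, 0.0) == 1.0

    def test_B_direct_evaluation(self):
        # ||dI||^2 = 0.01 with gamma_I = 100 and equal D -> exp(-1).
        w = pair_weight_B([0.1, 0.0, 0.0], [0.0, 0.0, 0.0], 0.5, 0.5, 100.0, 1e4)
        assert w == pytest.approx(np.exp(-1), rel=1e-12)

    def test_B_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            pair_weight_B([0], [0], 0, 0, -1.0, 0.0)

    def test_G_parallel_is_one(self):
        assert pair_weight_G([0, 1], [0, 2], delta=0.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("other", [[1, 0], [0, -1]])
    def test_G_orthogonal_or_opposite_clamps_to_floor(self, other):
        assert pair_weight_G([0, 1], other, delta=0.0) == 0.0

    def test_G_delta_one_reduction(self):
        assert pair_weight_G([0, 1], [0, -1], delta=1.0) == 1.0

    def test_G_zero_direction_rejected(self):
        with pytest.raises(ValueError):
            pair_weight_G([0, 0], [1, 0])


class TestComputeOrderField:
    def test_all_reliable_gives_zero_field(self):
        order = compute_order_field(make_mask(np.ones((4, 4))))
        assert (order.T == 0).all()

    def test_single_unreliable_pixel(self):
        rel = np.ones((3, 3), bool)
        rel[1, 1] = False
        order = compute_order_field(make_mask(rel))
        assert order.T[1, 1] == 1
        assert order.T.sum() == 1

    def test_row_distance_profile(self):
        rel = np.zeros((1, 7), bool)
        rel[0, [0, 6]] = True
        order = compute_order_field(make_mask(rel))
        assert list(order.T[0]) == [0, 1, 2, 3, 2, 1, 0]

    def test_matches_bfs_oracle(self, rng):
        for _ in range(5):
            rel = rng.random((16, 16)) > 0.7
            rel[0, 0] = True
            order = compute_order_field(make_mask(rel))
            assert np.array_equal(order.T, bfs_chessboard_oracle(rel))

    def test_level_recurrence(self, rng):
        # Every unreliable pixel sits one step above its neighborhood minimum.
        rel = rng.random((12, 12)) > 0.6
        rel[3, 3] = True
        T = compute_order_field(make_mask(rel)).T
        h, w = T.shape
        for i in range(h):
            for j in range(w):
                if T[i, j] > 0:
                    nbrs = T[max(0, i - 1):i + 2, max(0, j - 1):j + 2]
                    assert T[i, j] == 1 + nbrs.min()

    def test_directions_are_unit(self, rng):
        rel = rng.random((10, 10)) > 0.5
        rel[0, 0] = True
        order = compute_order_field(make_mask(rel))
        np.testing.assert_allclose(np.linalg.norm(order.dir_plus, axis=-1), 1.0, atol=1e-12)

    def test_no_reliable_pixels_rejected(self):
        with pytest.raises(ValueError):
            compute_order_field(make_mask(np.zeros((3, 3))))


def _guided(D):
    D = np.asarray(D, dtype=float)
    return GuidedImage(I=np.stack([D] * 3, axis=-1), D=D)


class TestPropagateConfidence:
    def test_reliable_pixels_keep_unit_confidence(self, rng):
        rel = rng.random((8, 8)) > 0.4
        rel[0, 0] = True
        order = compute_order_field(make_mask(rel))
        conf = propagate_confidence(order, _guided(rng.random((8, 8))))
        assert (conf.c_plus[rel] == 1.0).all()
        assert (conf.c_minus[rel] == 0.0).all()

    def test_single_unreliable_pixel_gets_decay_factor(self):
        rel = np.ones((3, 3), bool)
        rel[1, 1] = False
        order = compute_order_field(make_mask(rel))
        params = PropagationParams(a=0.8, gamma_i=0.0, gamma_d=0.0, delta=1.0)
        conf = propagate_confidence(order, _guided(np.zeros((3, 3))), params)
        assert conf.c_plus[1, 1] == pytest.approx(0.8)

    def test_zero_decay_annihilates_confidence(self, rng):
        rel = rng.random((8, 8)) > 0.5
        rel[0, 0] = True
        order = compute_order_field(make_mask(rel))
        params = PropagationParams(a=0.0)
        conf = propagate_confidence(order, _guided(rng.random((8, 8))), params)
        assert (conf.c_plus[~rel] == 0.0).all()
        assert (conf.c_minus[~rel] == 0.0).all()

    def test_confidence_normalized_to_unit_interval(self, rng):
        for _ in range(3):
            rel = rng.random((12, 12)) > 0.6
            rel[5, 5] = True
            order = compute_order_field(make_mask(rel))
            conf = propagate_confidence(order, _guided(rng.random((12, 12))))
            for arr in (conf.c_plus, conf.c_minus):
                assert arr.min() >= 0.0 and arr.max() <= 1.0


class TestOrderedFilter:
    def test_constant_raster_unchanged(self, rng):
        rel = rng.random((8, 8)) > 0.5
        rel[0, 0] = True
        order = compute_order_field(make_mask(rel))
        guided = _guided(np.full((8, 8), 0.7))
        conf = propagate_confidence(order, guided)
        np.testing.assert_allclose(ordered_filter(guided, order, conf), 0.7, atol=1e-12)

    def test_all_reliable_is_identity(self, rng):
        D = rng.random((6, 6))
        order = compute_order_field(make_mask(np.ones((6, 6))))
        guided = _guided(D)
        conf = propagate_confidence(order, guided)
        assert np.array_equal(ordered_filter(guided, order, conf), D)

    def test_row_gap_takes_unweighted_mean(self):
        # [4, unreliable, 8] with B = G = C = 1 -> middle becomes 6.
        rel = np.array([[True, False, True]])
        order = compute_order_field(make_mask(rel))
        guided = _guided(np.array([[4.0, 0.0, 8.0]]))
        params = PropagationParams(a=0.9, gamma_i=0.0, gamma_d=0.0, delta=1.0)
        conf = propagate_confidence(order, guided, params)
        out = ordered_filter(guided, order, conf, params)
        assert out[0, 1] == pytest.approx(6.0)

    def test_reliable_pixels_bit_identical(self, rng):
        for _ in range(5):
            D = rng.random((16, 16))
            rel = rng.random((16, 16)) > 0.6
            rel[2, 2] = True
            order = compute_order_field(make_mask(rel))
            guided = _guided(D)
            conf = propagate_confidence(order, guided)
            out = ordered_filter(guided, order, conf)
            assert np.array_equal(out[rel], D[rel])

    def test_filtered_values_inside_reliable_hull(self, rng):
        for _ in range(5):
            D = rng.random((16, 16))
            rel = rng.random((16, 16)) > 0.6
            rel[2, 2] = True
            order = compute_order_field(make_mask(rel))
            guided = _guided(D)
            conf = propagate_confidence(order, guided)
            out = ordered_filter(guided, order, conf)
            assert out.min() >= D[rel].min() - 1e-12
            assert out.max() <= D[rel].max() + 1e-12

    def test_reduction_equals_distance_decay_oracle(self, rng):
        # gamma_I = gamma_D = 0, delta = 1: weights collapse to C = a^T and
        # the filter must match the independent distance-decay implementation.
        params = PropagationParams(a=0.8, gamma_i=0.0, gamma_d=0.0, delta=1.0)
        for _ in range(5):
            D = rng.random((16, 16))
            rel = rng.random((16, 16)) > 0.6
            rel[0, 0] = True
            order = compute_order_field(make_mask(rel))
            guided = _guided(D)
            conf = propagate_confidence(order, guided, params)
            out = ordered_filter(guided, order, conf, params)
            ref = reduced_distance_decay_filter(D, rel, 0.8)
            assert np.abs(out - ref).max() <= 1e-10
            # and the confidence collapses to a^T
            expect = np.where(rel, 1.0, 0.8 ** order.T)
            assert np.abs(np.where(rel, 1.0, conf.c_plus) - expect).max() <= 1e-10
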