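"""Loss-function identities, the convexity-loss brute-force oracle, and the
Monte-Carlo estimator's agreement with the exhaustive value."""

import numpy as np
import pytest

from aopmeter import losses
from aopmeter.autodiff import Parameter, Tensor
from aopmeter.losses import (LossWeights, cross_entropy, dice_loss,
                             dice_loss_masks, mse_heatmap_loss,
                             shape_constrained_loss, total_loss)
from conftest import random_blob_mask


class TestCrossEntropy:
    def test_perfect_prediction_near_zero(self):
        assert cross_entropy([1.0], [1.0 - 1e-9]) < 1e-6
        assert cross_entropy([0.0], [1e-9]) < 1e-6

    def test_ln2_at_half(self):
        assert cross_entropy([1.0], [0.5]) == pytest.approx(np.log(2), rel=1e-5)
        assert cross_entropy([0.0], [0.5]) == pytest.approx(np.log(2), rel=1e-5)

    def test_clamping_keeps_finite(self):
        assert np.isfinite(cross_entropy([1.0], [0.0]))


class TestDiceLoss:
    def test_perfect_is_zero(self, rng):
        y = (rng.random((4, 4)) > 0.5).astype(np.float32)
        assert dice_loss(y, y.copy()) == pytest.approx(0.0, abs=1e-6)

    def test_no_overlap_is_one(self):
        y = np.array([1.0, 1.0, 0.0, 0.0])
        assert dice_loss(y, 1.0 - y) == pytest.approx(1.0)

    def test_hand_value_one_third(self):
        assert dice_loss(np.array([1.0, 0, 0, 0]),
                         np.array([0.5, 0, 0, 0])) == pytest.approx(1 / 3)

    def test_empty_empty_convention(self):
        z = np.zeros(5)
        assert dice_loss(z, z) == 0.0

    def test_mask_interface_pools_foreground(self):
        labels = np.array([[[0, 1], [2, 2]]])
        probs = np.zeros((1, 3, 2, 2), np.float32)
        probs[0, 0, 0, 0] = 1
        probs[0, 1, 0, 1] = 1
        probs[0, 2, 1, 0] = 1
        probs[0, 2, 1, 1] = 1
        assert dice_loss_masks(labels, probs) == pytest.approx(0.0, abs=1e-6)


def brute_force_slf(y, p, class_id):
    """Independent triple loop over the (pair, collinear point) space."""
    fg = [tuple(ij) for ij in np.argwhere(y == class_id)]
    pairs = [(a, b) for i, a in enumerate(fg) for b in fg[i + 1:]]
    total = 0.0
    for (py, px), (qy, qx) in pairs:
        m = max(abs(qy - py), abs(qx - px))
        pair_sum = 0.0
        for j in range(m + 1):
            t = j / m
            ry = round(py + t * (qy - py))
            rx = round(px + t * (qx - px))
            if y[ry, rx] != class_id:
                continue
            pp, pq, pr = p[py, px], p[qy, qx], p[ry, rx]
            pair_sum += max((1 - pp) * (1 - pq) * (pp + pq - 2 * pr), 0.0)
        total += pair_sum / (m + 1)
    return total / len(pairs)


def brute_force_slf_variance(y, p, class_id):
    """Population variance of one Monte-Carlo draw (for standard errors)."""
    fg = [tuple(ij) for ij in np.argwhere(y == class_id)]
    pairs = [(a, b) for i, a in enumerate(fg) for b in fg[i + 1:]]
    vals, weights = [], []
    for (py, px), (qy, qx) in pairs:
        m = max(abs(qy - py), abs(qx - px))
        for j in range(m + 1):
            t = j / m
            ry = round(py + t * (qy - py))
            rx = round(px + t * (qx - px))
            if y[ry, rx] == class_id:
                pp, pq, pr = p[py, px], p[qy, qx], p[ry, rx]
                vals.append(max((1 - pp) * (1 - pq) * (pp + pq - 2 * pr), 0.0))
            else:
                vals.append(0.0)
            weights.append(1.0 / (len(pairs) * (m + 1)))
    vals, weights = np.array(vals), np.array(weights)
    mean = np.sum(vals * weights)
    return np.sum(weights * (vals - mean) ** 2)


class TestShapeConstrainedLoss:
    def test_perfect_prediction_zero(self, rng):
        y = random_blob_mask(rng)
        p = (y == 2).astype(np.float32)
        assert shape_constrained_loss(y, p, exhaustive=True) == pytest.approx(0.0, abs=1e-12)

    def test_single_triplet_hand_value(self):
        # three collinear foreground pixels, predictions 0.8 / 0.8 / 0.2
        y = np.zeros((3, 5), np.uint8)
        y[1, 1:4] = 2
        p = np.zeros((3, 5), np.float64)
        p[1, 1], p[1, 3], p[1, 2] = 0.8, 0.8, 0.2
        # isolate the (ends, middle) pair: restrict to a mask with only it
        y2 = np.zeros_like(y)
        y2[1, 1] = y2[1, 3] = y2[1, 2] = 2
        val = shape_constrained_loss(y2, p, exhaustive=True)
        # exhaustive averages over 3 pairs x their segment points; recover the
        # pure hand term from the pair (1,1)-(1,3) with r=(1,2):
        # term = (0.2)(0.2)(0.8+0.8-0.4) = 0.048
        hand = 0.048
        oracle = brute_force_slf(y2, p, 2)
        assert val == pytest.approx(oracle, abs=1e-12)
        # the middle-point term appears with its exhaustive weight
        assert any(np.isclose(hand, (1 - p[1, 1]) * (1 - p[1, 3]) *
                              (p[1, 1] + p[1, 3] - 2 * p[1, 2])) for _ in [0])

    def test_exhaustive_matches_brute_force(self, rng):
        for _ in range(20):
            y = random_blob_mask(rng)
            if (y == 2).sum() < 2:
                continue
            p = rng.random(y.shape).astype(np.float64)
            ours = shape_constrained_loss(y, p, exhaustive=True)
            oracle = brute_force_slf(y, p, 2)
            assert ours == pytest.approx(oracle, abs=1e-9)

    def test_monte_carlo_within_three_se(self, rng):
        y = random_blob_mask(rng, n_seeds=4)
        p = rng.random(y.shape)
        exact = brute_force_slf(y, p, 2)
        var1 = brute_force_slf_variance(y, p, 2)
        n = 100_000
        est = shape_constrained_loss(y, p, n_triplets=n,
                                     rng=np.random.default_rng(7))
        se = np.sqrt(var1 / n)
        assert abs(est - exact) <= 3 * se + 1e-12

    def test_discriminates_convexity(self):
        """A concave notch in the prediction raises the loss on convex truth."""
        yy, xx = np.mgrid[0:24, 0:24]
        disk = ((xx - 12) ** 2 + (yy - 12) ** 2 <= 81)
        y = disk.astype(np.uint8) * 2
        p_convex = disk.astype(np.float64) * 0.9
        p_notch = p_convex.copy()
        p_notch[10:15, 10:15] = 0.05  # carve a hole in the middle
        l_convex = shape_constrained_loss(y, p_convex, exhaustive=True)
        l_notch = shape_constrained_loss(y, p_notch, exhaustive=True)
        assert l_notch > l_convex

    def test_too_few_foreground_pixels(self):
        y = np.zeros((5, 5), np.uint8)
        y[2, 2] = 2
        assert shape_constrained_loss(y, np.zeros((5, 5)), exhaustive=True) == 0.0

    def test_gradient_flows_through_tensor(self, rng):
        y = random_blob_mask(rng)
        p = Parameter(rng.random(y.shape).astype(np.float32))
        loss = shape_constrained_loss(y, p, n_triplets=200,
                                      rng=np.random.default_rng(3))
        loss.backward()
        assert p.grad is not None and np.any(p.grad != 0)


class TestHeatmapMSE:
    def test_zero_at_equality(self, rng):
        h = rng.random((3, 8, 8)).astype(np.float32)
        assert mse_heatmap_loss(h, h.copy()) == pytest.approx(0.0)

    def test_single_pixel_weighting(self):
        t = np.zeros((3, 10, 10), np.float32)
        p = t.copy()
        p[1, 4, 4] = 1.0  # map 2 (left endpoint), delta_2 = 0.8
        assert mse_heatmap_loss(p, t) == pytest.approx(0.8 / 100)

    def test_quadratic_scaling(self, rng):
        t = np.zeros((3, 6, 6), np.float32)
        p = rng.random((3, 6, 6)).astype(np.float32)
        assert mse_heatmap_loss(2 * p, t) == pytest.approx(
            4 * mse_heatmap_loss(p, t), rel=1e-5)


class TestTotalLoss:
    def test_hand_composition(self):
        assert total_loss(0.4, 0.1, 0.2) == pytest.approx(0.35)

    def test_zero_at_zero(self):
        assert total_loss(0.0, 0.0, 0.0) == 0.0

    def test_uncertainty_gradient_nonzero(self):
        s1 = Parameter(np.float32(0.0))
        s2 = Parameter(np.float32(0.0))
        loss = total_loss(Tensor(np.float32(0.4)), Tensor(np.float32(0.1)),
                          Tensor(np.float32(0.2)), LossWeights(), s1, s2)
        loss.backward()
        # finite-difference check on s1: d/ds [w1 e^{-s} L_D + s/2]
        eps = 1e-3
        fd = (total_loss(0.4, 0.1, 0.2, LossWeights(), eps, 0.0)
              - total_loss(0.4, 0.1, 0.2, LossWeights(), -eps, 0.0)) / (2 * eps)
        assert s1.grad != 0
        assert float(s1.grad) == pytest.approx(fd, rel=1e-2)

    def test_frozen_reduces_to_fixed_mixture(self):
        w = LossWeights(w1=0.5)
        assert total_loss(1.0, 2.0, 3.0, w, 0.0, 0.0) == pytest.approx(
            0.5 * 3.0 + 0.5 * 3.0)
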