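"""Composite loss analytics: closed forms, brute-force oracles, gradients."""

import numpy as np
import pytest
from scipy.special import ndtr

from scarseg.supervision import (
    LossConfig,
    bce_loss,
    dice_loss,
    kl_loss,
    make_soft_labels,
    total_loss,
    total_loss_grad,
)


class TestSoftLabels:
    def test_constant_masks_are_fixed_points(self):
        ones = np.ones((32, 32))
        zeros = np.zeros((32, 32))
        assert np.allclose(make_soft_labels(ones, 2.0), 1.0)
        assert np.allclose(make_soft_labels(zeros, 2.0), 0.0)

    def test_sigma_zero_is_identity(self):
        g = (np.random.default_rng(0).random((16, 16)) > 0.5).astype(float)
        assert np.array_equal(make_soft_labels(g, 0.0), g)

    def test_half_plane_boundary_matches_erf_oracle(self):
        # mask = 1 for rows >= 32; treating pixels as unit cells, the blurred
        # profile at the first foreground row is Phi(0.5/sigma), at the last
        # background row Phi(-0.5/sigma)
        g = np.zeros((64, 64))
        g[32:, :] = 1.0
        s = make_soft_labels(g, 2.0)
        assert abs(s[32, 32] - ndtr(0.5 / 2.0)) < 0.02
        assert abs(s[31, 32] - ndtr(-0.5 / 2.0)) < 0.02

    def test_mass_conserved_away_from_border(self):
        g = np.zeros((64, 64))
        g[24:40, 24:40] = 1.0  # >= 3 sigma from the border
        s = make_soft_labels(g, 2.0)
        assert abs(s.sum() - g.sum()) / g.sum() < 0.005


class TestDiceLoss:
    def test_perfect_prediction_is_zero(self):
        g = np.zeros((16, 16))
        g[4:10, 4:10] = 1.0
        assert dice_loss(g, g) == pytest.approx(0.0, abs=1e-12)

    def test_both_empty_is_zero(self):
        z = np.zeros((8, 8))
        assert dice_loss(z, z) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_masks_closed_form(self):
        p = np.zeros((20, 20))
        g = np.zeros((20, 20))
        p[:5, :20] = 1.0  # 100 px
        g[10:15, :20] = 1.0  # 100 px, disjoint
        eps = 1e-6
        assert dice_loss(p, g, eps) == pytest.approx(1.0 - eps / (200.0 + eps), rel=1e-12)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(20):
            p = rng.random((8, 8))
            g = (rng.random((8, 8)) > 0.5).astype(float)
            assert 0.0 <= dice_loss(p, g) <= 1.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(Exception):
            dice_loss(np.zeros((4, 4)), np.zeros((5, 5)))


class TestBceLoss:
    def test_uniform_half_gives_ln2(self):
        g = (np.random.default_rng(1).random((16, 16)) > 0.5).astype(float)
        assert bce_loss(np.full((16, 16), 0.5), g) == pytest.approx(np.log(2.0), abs=1e-9)

    def test_perfect_prediction_clamp_limited(self):
        g = (np.random.default_rng(2).random((16, 16)) > 0.5).astype(float)
        assert bce_loss(g, g) <= -np.log(1 - 1e-6) + 1e-9

    def test_matches_pixel_loop_oracle(self, rng):
        p = rng.uniform(0.05, 0.95, (4, 4))
        g = (rng.random((4, 4)) > 0.5).astype(float)
        manual = -np.mean(
            [
                g[i, j] * np.log(p[i, j]) + (1 - g[i, j]) * np.log(1 - p[i, j])
                for i in range(4)
                for j in range(4)
            ]
        )
        assert bce_loss(p, g) == pytest.approx(manual, rel=1e-12)


class TestKlLoss:
    def test_self_divergence_near_zero(self):
        s = np.full((16, 16), 0.5)
        assert abs(kl_loss(s, s)) < s.size * 1e-6

    def test_zero_entries_contribute_nothing(self):
        s = np.array([[1.0, 0.0]])
        p = np.array([[0.5, 0.5]])
        expected = np.log(1.0 / 0.500001)
        assert kl_loss(s, p, eps=1e-6) == pytest.approx(expected, rel=1e-6)

    def test_mean_reduction_divides_by_n(self, rng):
        s = rng.uniform(0.1, 0.9, (6, 6))
        p = rng.uniform(0.1, 0.9, (6, 6))
        assert kl_loss(s, p, reduction="mean") == pytest.approx(kl_loss(s, p) / 36.0, rel=1e-12)


class TestTotalLoss:
    def test_perfect_binary_prediction_sigma_zero_vanishes(self):
        g = np.zeros((16, 16))
        g[5:10, 5:10] = 1.0
        cfg = LossConfig(sigma=0.0)
        total, _ = total_loss(g, g, cfg)
        assert abs(total) < 10 * g.size * cfg.epsilon

    def test_zero_weights_give_zero(self, rng):
        p = rng.random((8, 8))
        g = (rng.random((8, 8)) > 0.5).astype(float)
        total, _ = total_loss(p, g, LossConfig(lambda_dice=0, lambda_bce=0, lambda_kl=0))
        assert total == 0.0

    @pytest.mark.parametrize("reduction", ["sum", "mean"])
    def test_compositionality(self, rng, reduction):
        p = rng.uniform(0.05, 0.95, (8, 8))
        g = (rng.random((8, 8)) > 0.5).astype(float)
        cfg = LossConfig(kl_reduction=reduction)
        total, parts = total_loss(p, g, cfg)
        s = make_soft_labels(g, cfg.sigma)
        expected = (
            cfg.lambda_dice * dice_loss(p, g, cfg.epsilon)
            + cfg.lambda_bce * bce_loss(p, g, cfg.epsilon)
            + cfg.lambda_kl * kl_loss(s, p, cfg.epsilon, reduction)
        )
        assert total == pytest.approx(expected, abs=1e-10)

    def test_normalize_lambdas_flag(self, rng):
        p = rng.uniform(0.05, 0.95, (8, 8))
        g = (rng.random((8, 8)) > 0.5).astype(float)
        t_raw, _ = total_loss(p, g, LossConfig())
        t_norm, _ = total_loss(p, g, LossConfig(normalize_lambdas=True))
        lam_sum = 0.60 + 0.62 + 0.64
        assert t_norm == pytest.approx(t_raw / lam_sum, rel=1e-9)


class TestGradient:
    @pytest.mark.parametrize("reduction", ["sum", "mean"])
    def test_finite_difference_agreement(self, rng, reduction):
        """Analytic gradient of the composite loss matches central finite
        differences to 1e-4 relative on a 6x6 instance."""
        cfg = LossConfig(kl_reduction=reduction)
        p = rng.uniform(0.2, 0.8, (6, 6))
        g = (rng.random((6, 6)) > 0.5).astype(float)
        grad = total_loss_grad(p, g, cfg)
        h = 1e-6
        for i in range(6):
            for j in range(6):
                pp = p.copy()
                pp[i, j] += h
                pm = p.copy()
                pm[i, j] -= h
                fd = (total_loss(pp, g, cfg)[0] - total_loss(pm, g, cfg)[0]) / (2 * h)
                assert grad[i, j] == pytest.approx(fd, rel=1e-4, abs=1e-9)

    def test_gradient_descent_on_single_pixel_decreases_loss(self):
        cfg = LossConfig(sigma=0.0, kl_reduction="mean")
        g = np.array([[1.0]])
        p = np.array([[0.2]])
        prev = np.inf
        for _ in range(50):
            val, _ = total_loss(p, g, cfg)
            assert val <= prev + 1e-12
            prev = val
            p = np.clip(p - 0.1 * total_loss_grad(p, g, cfg), 1e-4, 1 - 1e-4)
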