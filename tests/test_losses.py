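"""Focal, Dice and Dynamically Weighted Dice losses.

The DWD oracle used here is an independent straight-from-formula evaluation
(soft precision/recall coefficients, weight pairing, smoothed denominator)
kept deliberately separate from the library implementation.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from esunet.losses import (
    LossConfig,
    dice_loss,
    dwd_loss,
    focal_term,
    pr_coefficients,
    total_loss,
    total_loss_grad,
)


def _oracle_total(y, p, gamma=2.0, alpha=1.0, eps=1e-6, pairing="narrative",
                  clip=(0.0, 2.0)):
    """Brute-force evaluation of the combined objective."""
    y = np.asarray(y, float).ravel()
    p = np.asarray(p, float).ravel()
    t = y * p + (1 - y) * (1 - p)
    focal = float(np.mean(-((1 - t) ** gamma) * np.log(t + eps)))
    sy, sp, inter = (y**2).sum(), (p**2).sum(), (y * p).sum()
    if sy + sp == 0:
        return focal
    c_p, c_r = inter / (sp + eps), inter / (sy + eps)
    w_p = min(max(1 - (c_p - c_r), clip[0]), clip[1])
    w_r = min(max(1 - (c_r - c_p), clip[0]), clip[1])
    wy, wp = (w_r, w_p) if pairing == "narrative" else (w_p, w_r)
    return focal + alpha * (1 - 2 * inter / (wy * sy + wp * sp + eps))


def _soft_inputs(rng, n=50):
    y = (rng.uniform(size=n) < 0.35).astype(float)
    p = rng.uniform(0.0, 1.0, size=n)
    return y, p


class TestFocal:
    def test_perfect_prediction_is_zero(self):
        assert focal_term([1, 0, 1], [1, 0, 1]) == pytest.approx(0.0, abs=1e-5)

    def test_worked_value_gamma_two(self):
        # 0.25 * (-ln 0.5)
        assert focal_term([1], [0.5], 2.0) == pytest.approx(0.173287, abs=1e-5)

    def test_gamma_zero_reduces_to_cross_entropy(self):
        assert focal_term([1], [0.5], 0.0) == pytest.approx(np.log(2), abs=1e-5)

    def test_length_mismatch_and_range_rejected(self):
        with pytest.raises(ValueError):
            focal_term([1, 0], [0.5])
        with pytest.raises(ValueError):
            focal_term([1], [1.5])


class TestDice:
    def test_identical_binary_masks_zero(self):
        assert dice_loss([1, 1, 0], [1, 1, 0]) == pytest.approx(0.0, abs=1e-5)

    def test_disjoint_masks_one(self):
        assert dice_loss([1, 0], [0, 1]) == pytest.approx(1.0, abs=1e-5)

    def test_worked_value(self):
        assert dice_loss([1, 1, 0, 0], [1, 0, 0, 0]) == pytest.approx(1 / 3, abs=1e-4)

    def test_both_empty_scores_zero(self):
        assert dice_loss([0, 0], [0.0, 0.0]) == 0.0


class TestPRCoefficients:
    def test_worked_example(self):
        c = pr_coefficients([1, 0, 0, 0], [1, 1, 0, 0])
        assert c.c_p == pytest.approx(0.5, abs=1e-4)
        assert c.c_r == pytest.approx(1.0, abs=1e-4)
        assert c.w_p == pytest.approx(1.5, abs=1e-4)
        assert c.w_r == pytest.approx(0.5, abs=1e-4)

    def test_equal_masks_give_unit_weights(self):
        c = pr_coefficients([1, 0, 1], [1, 0, 1])
        assert c.c_p == pytest.approx(c.c_r, abs=1e-5)
        assert c.w_p == pytest.approx(1.0, abs=1e-5)
        assert c.w_r == pytest.approx(1.0, abs=1e-5)

    def test_soft_prediction_clipping(self):
        # y=[1], p=[0.5]: C_P=2, C_R=0.5, raw weights -0.5 and 2.5 -> clipped
        c = pr_coefficients([1], [0.5])
        assert c.c_p == pytest.approx(2.0, abs=1e-4)
        assert c.c_r == pytest.approx(0.5, abs=1e-4)
        assert c.w_p == 0.0
        assert c.w_r == 2.0

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_weights_sum_to_two_before_clipping(self, seed):
        rng = np.random.default_rng(seed)
        y, p = _soft_inputs(rng)
        c = pr_coefficients(y, p, LossConfig(weight_clip=(-100.0, 100.0)))
        assert c.w_p + c.w_r == pytest.approx(2.0, abs=1e-9)


class TestDWD:
    def test_degenerates_to_dice_for_binary_equality(self):
        y = np.array([1, 0, 1, 1, 0], float)
        assert dwd_loss(y, y) == pytest.approx(dice_loss(y, y), abs=1e-9)
        assert dwd_loss(y, y) == pytest.approx(0.0, abs=1e-5)

    def test_worked_value_narrative(self):
        assert dwd_loss([1, 0, 0, 0], [1, 1, 0, 0]) == pytest.approx(0.428571, abs=1e-4)

    def test_worked_value_as_printed(self):
        cfg = LossConfig(pairing="as_printed")
        assert dwd_loss([1, 0, 0, 0], [1, 1, 0, 0], cfg) == pytest.approx(0.2, abs=1e-4)

    def test_narrative_magnifies_over_dice(self):
        y, p = [1, 0, 0, 0], [1, 1, 0, 0]
        assert dwd_loss(y, p) > dice_loss(y, p)

    @given(st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_narrative_dominates_dice_when_unclipped(self, seed):
        # denominator difference = (C_R-C_P)^2 * Syp / (C_P*C_R) >= 0
        rng = np.random.default_rng(seed)
        y, p = _soft_inputs(rng)
        cfg = LossConfig()
        c = pr_coefficients(y, p, cfg)
        if not (0.0 < c.w_p < 2.0 and 0.0 < c.w_r < 2.0):
            return  # clipping active; dominance claim applies to unclipped regime
        d, w = dice_loss(y, p), dwd_loss(y, p, cfg)
        assert w >= d - 1e-9
        if abs(c.c_p - c.c_r) > 1e-6 and (y * p).sum() > 0:
            assert w > d

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_as_printed_shrinks_below_dice_when_unclipped(self, seed):
        # documents the printed-form inconsistency the narrative pairing fixes
        rng = np.random.default_rng(seed)
        y, p = _soft_inputs(rng)
        cfg = LossConfig(pairing="as_printed")
        c = pr_coefficients(y, p, cfg)
        if not (0.0 < c.w_p < 2.0 and 0.0 < c.w_r < 2.0):
            return
        assert dwd_loss(y, p, cfg) <= dice_loss(y, p) + 1e-9


class TestTotalLoss:
    def test_perfect_binary_prediction_is_zero(self):
        y = np.array([1, 0, 1], float)
        assert total_loss(y, y) == pytest.approx(0.0, abs=1e-4)

    def test_worked_value(self):
        assert total_loss([1, 0], [0.5, 0.5]) == pytest.approx(0.601858, abs=1e-4)

    def test_alpha_zero_is_focal_alone(self):
        y, p = [1, 0, 1, 0], [0.8, 0.3, 0.6, 0.1]
        cfg = LossConfig(alpha=0.0)
        assert total_loss(y, p, cfg) == pytest.approx(focal_term(y, p), abs=1e-9)

    def test_matches_independent_oracle_on_random_inputs(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            y, p = _soft_inputs(rng)
            assert total_loss(y, p) == pytest.approx(_oracle_total(y, p), abs=1e-6)

    def test_all_losses_nonnegative(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            y, p = _soft_inputs(rng)
            assert focal_term(y, p) >= 0
            assert 0 <= dice_loss(y, p) <= 1
            assert total_loss(y, p) >= 0


class TestGradient:
    def test_matches_finite_differences_with_frozen_weights(self):
        rng = np.random.default_rng(0)
        cfg = LossConfig()
        for _ in range(10):
            y, p = _soft_inputs(rng, n=20)
            p = np.clip(p, 0.02, 0.98)
            g = total_loss_grad(y, p, cfg)
            c = pr_coefficients(y, p, cfg)

            def frozen(pv):
                f = focal_term(y, pv, cfg.gamma, cfg.epsilon)
                den = c.w_r * (y * y).sum() + c.w_p * (pv * pv).sum() + cfg.epsilon
                return f + cfg.alpha * (1 - 2 * (y * pv).sum() / den)

            i = int(rng.integers(0, y.size))
            eps = 1e-6
            pp, pm = p.copy(), p.copy()
            pp[i] += eps
            pm[i] -= eps
            num = (frozen(pp) - frozen(pm)) / (2 * eps)
            assert g[i] == pytest.approx(num, rel=1e-4, abs=1e-7)

    def test_finite_at_probability_boundaries(self):
        y = np.array([1.0, 0.0, 1.0, 0.0])
        p = np.array([0.0, 1.0, 1.0, 0.0])
        g = total_loss_grad(y, p)
        assert np.isfinite(g).all()
        assert np.isfinite(total_loss(y, p))
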