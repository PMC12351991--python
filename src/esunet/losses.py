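"""Segmentation training objectives: focal, Dice, and Dynamically Weighted Dice.

The Dynamically Weighted Dice (DWD) loss is a Dice-style region loss whose
denominator terms are reweighted each evaluation by the gap between soft
precision and recall coefficients computed on the current probabilities:

    C_P = Σ y·p / Σ p²      (soft precision)
    C_R = Σ y·p / Σ y²      (soft recall)
    w_P = 1 - (C_P - C_R),  w_R = 1 - (C_R - C_P)        (so w_P + w_R = 2)

    L_DWD = 1 - 2 Σ y·p / (w_R Σ y² + w_P Σ p²)          ("narrative" pairing)

When C_P = C_R both weights are 1 and DWD degenerates to the plain Dice
loss; under a precision/recall disparity the narrative pairing provably
magnifies the loss relative to Dice, steering optimisation toward the weaker
of the two.  The alternative "as_printed" pairing (w_P on Σ y², w_R on Σ p²)
is kept behind a flag; it shrinks rather than magnifies the loss under
disparity, which is why it is not the default.

With soft predictions the coefficients can exceed 1 (e.g. y=[1], p=[0.5]
gives C_P = 2), making a raw weight negative; weights are therefore clipped
to ``weight_clip`` (default [0, 2]), which leaves the equal-coefficient
regime untouched.

The total objective is mean focal loss over voxels plus α times DWD.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "LossConfig",
    "PRCoefficients",
    "focal_term",
    "dice_loss",
    "pr_coefficients",
    "dwd_loss",
    "total_loss",
    "total_loss_grad",
]

_PAIRINGS = ("narrative", "as_printed")


@dataclasses.dataclass
class LossConfig:
    """Constants of the combined focal + DWD objective.

    γ (``gamma``) is the focal focusing exponent, 2 by default; α (``alpha``)
    balances the region term against the voxel-wise term, 1 by default;
    ``epsilon`` smooths every ratio denominator.
    """

    gamma: float = 2.0
    alpha: float = 1.0
    epsilon: float = 1e-6
    pairing: str = "narrative"
    weight_clip: tuple[float, float] = (0.0, 2.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 5.0:
            raise ValueError(f"gamma must be in [0, 5], got {self.gamma}")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.pairing not in _PAIRINGS:
            raise ValueError(f"pairing must be one of {_PAIRINGS}, got {self.pairing!r}")
        lo, hi = self.weight_clip
        if not lo <= 1.0 <= hi:
            raise ValueError("weight_clip must bracket 1")


@dataclasses.dataclass
class PRCoefficients:
    """Soft precision/recall coefficients and the derived denominator weights."""

    c_p: float
    c_r: float
    w_p: float
    w_r: float


def _check(y: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=np.float64).ravel()
    p = np.asarray(p, dtype=np.float64).ravel()
    if y.shape != p.shape:
        raise ValueError(f"y and p lengths differ: {y.size} vs {p.size}")
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("predictions must lie in [0, 1]")
    return y, p


def focal_term(y: np.ndarray, p: np.ndarray, gamma: float = 2.0, epsilon: float = 1e-6) -> float:
    """Mean focal loss over voxels.

    Per voxel, with t = y·p + (1-y)·(1-p) the probability assigned to the
    true class: -(1-t)^γ · log(t + ε), averaged over the volume.  γ = 0
    reduces to plain cross-entropy.
    """
    y, p = _check(y, p)
    t = y * p + (1.0 - y) * (1.0 - p)
    return float(np.mean(-((1.0 - t) ** gamma) * np.log(t + epsilon)))


def dice_loss(y: np.ndarray, p: np.ndarray, epsilon: float = 1e-6) -> float:
    """Soft Dice loss 1 - 2Σyp / (Σy² + Σp² + ε); 0 for two empty masks."""
    y, p = _check(y, p)
    denom = float((y * y).sum() + (p * p).sum())
    if denom == 0.0:
        return 0.0
    return float(1.0 - 2.0 * (y * p).sum() / (denom + epsilon))


def pr_coefficients(y: np.ndarray, p: np.ndarray, cfg: LossConfig | None = None) -> PRCoefficients:
    """Soft precision/recall coefficients and clipped denominator weights."""
    cfg = cfg or LossConfig()
    y, p = _check(y, p)
    inter = float((y * p).sum())
    c_p = inter / (float((p * p).sum()) + cfg.epsilon)
    c_r = inter / (float((y * y).sum()) + cfg.epsilon)
    lo, hi = cfg.weight_clip
    w_p = float(np.clip(1.0 - (c_p - c_r), lo, hi))
    w_r = float(np.clip(1.0 - (c_r - c_p), lo, hi))
    return PRCoefficients(c_p=c_p, c_r=c_r, w_p=w_p, w_r=w_r)


def _dwd_denominator_weights(coeff: PRCoefficients, pairing: str) -> tuple[float, float]:
    """Return (weight on Σy², weight on Σp²) for the chosen pairing."""
    if pairing == "narrative":
        return coeff.w_r, coeff.w_p
    return coeff.w_p, coeff.w_r


def dwd_loss(y: np.ndarray, p: np.ndarray, cfg: LossConfig | None = None) -> float:
    """Dynamically Weighted Dice loss.

    Equals the plain Dice loss whenever C_P = C_R; under the default
    narrative pairing it is >= Dice, with the gap growing with the
    precision/recall disparity.
    """
    cfg = cfg or LossConfig()
    y, p = _check(y, p)
    if float((y * y).sum() + (p * p).sum()) == 0.0:
        return 0.0
    coeff = pr_coefficients(y, p, cfg)
    wy, wp = _dwd_denominator_weights(coeff, cfg.pairing)
    denom = wy * float((y * y).sum()) + wp * float((p * p).sum()) + cfg.epsilon
    return float(1.0 - 2.0 * (y * p).sum() / denom)


def total_loss(y: np.ndarray, p: np.ndarray, cfg: LossConfig | None = None) -> float:
    """Combined objective: mean focal term + α · DWD."""
    cfg = cfg or LossConfig()
    return focal_term(y, p, cfg.gamma, cfg.epsilon) + cfg.alpha * dwd_loss(y, p, cfg)


def total_loss_grad(y: np.ndarray, p: np.ndarray, cfg: LossConfig | None = None) -> np.ndarray:
    """Gradient of :func:`total_loss` with respect to the probabilities ``p``.

    The DWD denominator weights are treated as constants of the current
    state (recomputed each call, not differentiated through): the dynamic
    weighting adapts the loss landscape between steps rather than adding a
    second-order gradient path.  Returns an array of the same shape as ``p``.
    """
    cfg = cfg or LossConfig()
    shape = np.shape(p)
    y, p = _check(y, p)
    t = y * p + (1.0 - y) * (1.0 - p)
    one_m = 1.0 - t
    dfdt = np.where(
        one_m > 0,
        cfg.gamma * one_m ** np.maximum(cfg.gamma - 1.0, 0.0) * np.log(t + cfg.epsilon)
        - one_m ** cfg.gamma / (t + cfg.epsilon),
        -(one_m ** cfg.gamma) / (t + cfg.epsilon),
    )
    grad = dfdt * (2.0 * y - 1.0) / y.size

    sum_sq = float((y * y).sum() + (p * p).sum())
    if cfg.alpha > 0 and sum_sq > 0.0:
        coeff = pr_coefficients(y, p, cfg)
        wy, wp = _dwd_denominator_weights(coeff, cfg.pairing)
        inter = float((y * p).sum())
        denom = wy * float((y * y).sum()) + wp * float((p * p).sum()) + cfg.epsilon
        # d/dp_i of (1 - 2*inter/denom) with weights held fixed
        ddwd = -2.0 * (y * denom - inter * wp * 2.0 * p) / denom**2
        grad = grad + cfg.alpha * ddwd
    return grad.reshape(shape)
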