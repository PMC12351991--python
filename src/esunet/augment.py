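"""Geometric augmentation: mirroring, rotation, and Region Specific Scaling.

Region Specific Scaling (RSS) rescales, along one axis at a time, only the
slab of the volume spanning the labelled region: the volume is split at the
label's global min/max indices along the axis, the middle slab (image
channels and label together) is resampled by a ratio r drawn from
[r1, r2] = [2/3, 3/2], and the outer slabs are reattached untouched.  A
shrunken assembly is re-centred and mirror-padded back to the original
extent; an enlarged one has the excess cropped symmetrically.  Each axis is
selected independently with probability p_axis chosen so the chance of
applying RSS on at least one axis equals p_overall = 0.5:
1 - (1 - p_axis)^3 = 0.5, i.e. p_axis = 1 - 0.5^(1/3) ≈ 0.2063.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage

from .io import Sample, resize_along_axis

__all__ = [
    "RSSConfig",
    "AugmentConfig",
    "per_axis_probability",
    "label_bounds",
    "rss_axis",
    "apply_rss",
    "mirror_and_rotate",
    "augment_sample",
]

logger = logging.getLogger(__name__)

_AXES = {"depth": 0, "height": 1, "width": 2}
_AXIS_ORDER = ("depth", "height", "width")


def per_axis_probability(p_overall: float, n_axes: int = 3) -> float:
    """Per-axis selection probability giving overall probability ``p_overall``.

    Solves 1 - (1 - p)^n = p_overall.  For the default (0.5, 3) this is
    1 - 0.5^(1/3) ≈ 0.2063.
    """
    if not 0.0 <= p_overall <= 1.0:
        raise ValueError(f"p_overall must be in [0, 1], got {p_overall}")
    if n_axes < 1:
        raise ValueError("n_axes must be a positive integer")
    return 1.0 - (1.0 - p_overall) ** (1.0 / n_axes)


@dataclasses.dataclass
class RSSConfig:
    """Region Specific Scaling parameters.

    ``r1``/``r2`` bound the scaling ratio (defaults 2/3 and 3/2); ``p_overall``
    is the probability that at least one axis is transformed, from which the
    per-axis probability is derived.  ``split_draw`` switches the ratio
    distribution from one Uniform(r1, r2) draw to a fair coin between the
    reduction interval [r1, 1] and the enlargement interval [1, r2].
    """

    r1: float = 2.0 / 3.0
    r2: float = 3.0 / 2.0
    p_overall: float = 0.5
    n_axes: int = 3
    split_draw: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.r1 <= 1.0 <= self.r2:
            raise ValueError(f"need 0 < r1 <= 1 <= r2, got r1={self.r1}, r2={self.r2}")
        if not 0.0 <= self.p_overall <= 1.0:
            raise ValueError("p_overall must be in [0, 1]")

    @property
    def p_axis(self) -> float:
        return per_axis_probability(self.p_overall, self.n_axes)


@dataclasses.dataclass
class AugmentConfig:
    """Full augmentation pipeline: mirror -> rotate -> RSS."""

    mirror_prob: float = 0.5
    rotation_max_deg: float = 15.0
    rss: RSSConfig = dataclasses.field(default_factory=RSSConfig)

    def __post_init__(self) -> None:
        if not 0.0 <= self.mirror_prob <= 1.0:
            raise ValueError("mirror_prob must be in [0, 1]")
        if self.rotation_max_deg < 0:
            raise ValueError("rotation_max_deg must be non-negative")


def label_bounds(label: np.ndarray, axis: str | int) -> tuple[int, int] | None:
    """Global inclusive (min, max) indices of nonzero label voxels along ``axis``.

    Computed over the whole 3-D volume, not slice-wise, so for several
    disjoint lesions the bounds span all of them.  Returns ``None`` for an
    all-zero label.
    """
    ax = _AXES[axis] if isinstance(axis, str) else int(axis)
    nz = np.any(label != 0, axis=tuple(i for i in range(3) if i != ax))
    idx = np.flatnonzero(nz)
    if idx.size == 0:
        return None
    return int(idx[0]), int(idx[-1])


def _scale_slab(arr: np.ndarray, axis: int, new_len: int, order: int) -> np.ndarray:
    return resize_along_axis(arr, axis, new_len, order)


def rss_axis(sample: Sample, axis: str | int, r: float, cfg: RSSConfig | None = None) -> Sample:
    """Apply the split–scale–reattach transform along one axis.

    The slab spanning the label bounds is resampled by ``r`` along ``axis``
    (trilinear for image channels, nearest for the label); the outer slabs
    are reattached unscaled.  For r < 1 the assembly is re-centred and both
    ends mirror-padded (reflect without edge repeat; an odd remainder pads
    the low-index end) back to the input extent; for r > 1 the excess is
    removed symmetrically (an odd remainder comes off the high-index end).
    Output shape always equals input shape.  An empty label is a logged
    no-op.
    """
    cfg = cfg or RSSConfig()
    if not cfg.r1 <= r <= cfg.r2:
        raise ValueError(f"scaling ratio {r} outside configured range [{cfg.r1}, {cfg.r2}]")
    ax = _AXES[axis] if isinstance(axis, str) else int(axis)
    bounds = label_bounds(sample.label, ax)
    if bounds is None:
        logger.info("RSS: empty label for case %s; axis %s left untouched",
                    sample.meta.get("case_id"), axis)
        return sample.copy()
    lo, hi = bounds
    n = sample.label.shape[ax]
    extent = hi - lo + 1
    new_extent = max(1, int(round(r * extent)))
    if new_extent == extent:
        return sample.copy()

    def transform(arr: np.ndarray, order: int) -> np.ndarray:
        a = ax + (arr.ndim - 3)  # spatial axes are the trailing three
        sl = [slice(None)] * arr.ndim
        sl_before, sl_mid, sl_after = list(sl), list(sl), list(sl)
        sl_before[a] = slice(0, lo)
        sl_mid[a] = slice(lo, hi + 1)
        sl_after[a] = slice(hi + 1, n)
        mid = _scale_slab(arr[tuple(sl_mid)], a, new_extent, order)
        out = np.concatenate([arr[tuple(sl_before)], mid, arr[tuple(sl_after)]], axis=a)
        total = out.shape[a]
        if total < n:  # reduction: centre then mirror-pad both ends
            deficit = n - total
            pad_lo, pad_hi = (deficit + 1) // 2, deficit // 2
            pad = [(0, 0)] * arr.ndim
            pad[a] = (pad_lo, pad_hi)
            out = np.pad(out, pad, mode="reflect")
        elif total > n:  # enlargement: symmetric crop
            excess = total - n
            crop_lo, crop_hi = excess // 2, (excess + 1) // 2
            sl_crop = [slice(None)] * arr.ndim
            sl_crop[a] = slice(crop_lo, total - crop_hi)
            out = out[tuple(sl_crop)]
        return out

    image = transform(sample.image, order=1)
    label = transform(sample.label, order=0)
    return Sample(np.ascontiguousarray(image), np.ascontiguousarray(label), dict(sample.meta))


def draw_rss_plan(cfg: RSSConfig, rng: np.random.Generator) -> list[tuple[str, float]]:
    """Draw the per-axis RSS decisions for one sample.

    Axes are visited in the fixed order (depth, height, width); for each, one
    uniform deviate decides selection against ``p_axis`` and, if selected,
    one further draw picks the ratio.  This fixed consumption order makes
    runs replayable from the seed.
    """
    plan: list[tuple[str, float]] = []
    for axis in _AXIS_ORDER:
        if rng.uniform() < cfg.p_axis:
            if cfg.split_draw:
                if rng.uniform() < 0.5:
                    r = rng.uniform(cfg.r1, 1.0)
                else:
                    r = rng.uniform(1.0, cfg.r2)
            else:
                r = rng.uniform(cfg.r1, cfg.r2)
            plan.append((axis, float(r)))
    return plan


def apply_rss(sample: Sample, cfg: RSSConfig, rng: np.random.Generator) -> Sample:
    """Apply RSS sequentially along independently selected axes.

    Label bounds are recomputed immediately before each selected axis's
    transform, so an earlier axis's transform influences later bounds
    (sequential, not simultaneous, semantics).
    """
    out = sample
    for axis, r in draw_rss_plan(cfg, rng):
        out = rss_axis(out, axis, r, cfg)
    return out.copy() if out is sample else out


def mirror_and_rotate(sample: Sample, cfg: AugmentConfig, rng: np.random.Generator) -> Sample:
    """Random mirroring then small random rotations about each axis.

    With probability ``mirror_prob`` the volume is flipped along one randomly
    chosen spatial axis; then an in-plane rotation by an angle drawn from
    Uniform(-rotation_max_deg, +rotation_max_deg) is applied about each of
    the three axes in fixed order (image trilinear, label nearest; shape
    preserved).
    """
    image = sample.image.astype(np.float64, copy=True)
    label = sample.label.copy()
    if rng.uniform() < cfg.mirror_prob:
        ax = int(rng.integers(0, 3))
        image = np.flip(image, axis=ax + 1)
        label = np.flip(label, axis=ax)
    for ax in range(3):
        angle = float(rng.uniform(-cfg.rotation_max_deg, cfg.rotation_max_deg))
        if angle == 0.0:
            continue
        plane = tuple(i for i in range(3) if i != ax)
        image = np.stack(
            [
                ndimage.rotate(ch, angle, axes=plane, reshape=False, order=1, mode="nearest")
                for ch in image
            ]
        )
        label = ndimage.rotate(
            label.astype(np.float32), angle, axes=plane, reshape=False, order=0, mode="constant"
        )
    label = (np.asarray(label) >= 0.5).astype(np.int8)
    return Sample(np.ascontiguousarray(image), np.ascontiguousarray(label), dict(sample.meta))


def augment_sample(sample: Sample, cfg: AugmentConfig, rng: np.random.Generator) -> Sample:
    """Full training-time augmentation: mirror -> rotate -> RSS."""
    out = mirror_and_rotate(sample, cfg, rng)
    return apply_rss(out, cfg.rss, rng)
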