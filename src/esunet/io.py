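"""Volumetric case I/O and canonicalisation.

Every volume in the package lives as a :class:`Sample`: a ``(channels, depth,
height, width)`` float array (channel 0 structure/CT-like, channel 1
uptake/PET-like when present) plus an aligned binary label volume and spatial
metadata.  NIfTI files are read and written with nibabel; volumes are brought
to a single canonical anatomical orientation on load so that axis conventions
are identical across cases.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

__all__ = [
    "Sample",
    "read_case",
    "resize_volume",
    "normalize_volume",
    "write_mask",
    "NORMALIZATION_SCHEMES",
]

NORMALIZATION_SCHEMES = ("zscore_per_channel", "minmax_per_channel", "none")


@dataclasses.dataclass
class Sample:
    """One co-registered multi-channel volume with its binary label mask.

    Attributes
    ----------
    image:
        ``(C, D, H, W)`` float array, ``C`` in {1, 2}.  Channel 0 is the
        structure-like (CT) channel; channel 1, if present, the uptake-like
        (PET) channel.
    label:
        ``(D, H, W)`` integer array with values in {0, 1}.
    meta:
        Spatial metadata: ``spacing`` (mm per spatial axis), ``affine``
        (4x4 voxel-to-world map), ``case_id`` and free-form flags such as
        ``inference`` (no label supplied).
    """

    image: np.ndarray
    label: np.ndarray
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        self.label = np.asarray(self.label)
        if self.image.ndim != 4:
            raise ValueError(
                f"image must be (channels, depth, height, width), got shape {self.image.shape}"
            )
        if self.image.shape[0] not in (1, 2):
            raise ValueError(f"channel count must be 1 or 2, got {self.image.shape[0]}")
        if self.label.ndim != 3:
            raise ValueError(f"label must be 3-D, got shape {self.label.shape}")
        if self.image.shape[1:] != self.label.shape:
            raise ValueError(
                f"image spatial shape {self.image.shape[1:]} != label shape {self.label.shape}"
            )
        vals = np.unique(self.label)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"label must be binary, found values {vals[:10]}")
        self.meta.setdefault("spacing", (1.0, 1.0, 1.0))
        self.meta.setdefault("affine", np.eye(4))
        self.meta.setdefault("case_id", "case")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.label.shape

    def copy(self) -> "Sample":
        return Sample(self.image.copy(), self.label.copy(), dict(self.meta))


def _load_canonical(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume reoriented to RAS canonical axes."""
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    return np.asarray(data, dtype=np.float64), np.asarray(img.affine)


def read_case(
    ct_path: str | Path,
    pet_path: str | Path | None = None,
    label_path: str | Path | None = None,
    case_id: str | None = None,
) -> Sample:
    """Read one case (CT, optional PET, optional label) into a :class:`Sample`.

    Channels are stacked in (CT, PET) order.  If no label is given the mask is
    all-zero and ``meta["inference"]`` is set — the case can still be pushed
    through prediction.  Modalities must share shape and affine.
    """
    ct, affine = _load_canonical(ct_path)
    channels = [ct]
    if pet_path is not None:
        pet, pet_affine = _load_canonical(pet_path)
        if pet.shape != ct.shape:
            raise ValueError(
                f"CT/PET shape mismatch: CT {ct.shape} vs PET {pet.shape}"
            )
        if not np.allclose(pet_affine, affine, atol=1e-3):
            raise ValueError("CT and PET affines differ beyond tolerance; "
                             "inputs must be co-registered")
        channels.append(pet)
    image = np.stack(channels, axis=0)

    meta: dict = {
        "affine": affine,
        "spacing": tuple(float(s) for s in nib.affines.voxel_sizes(affine)),
        "case_id": case_id or Path(ct_path).name.split(".")[0],
    }
    if label_path is not None:
        label, lab_affine = _load_canonical(label_path)
        if label.shape != ct.shape:
            raise ValueError(
                f"CT/label shape mismatch: CT {ct.shape} vs label {label.shape}"
            )
        if not np.allclose(label, np.round(label)):
            raise ValueError("label volume contains non-integer values")
        label = np.round(label).astype(np.int8)
        meta["inference"] = False
    else:
        label = np.zeros(ct.shape, dtype=np.int8)
        meta["inference"] = True
    return Sample(image, label, meta)


def _axis_interp_weights(n_in: int, n_out: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linear resampling along one axis: indices (lo, hi) and blend weight.

    Uses the half-pixel-centre convention: output index m samples source
    coordinate (m + 0.5) * n_in/n_out - 0.5, clamped to the valid range.
    """
    scale = n_in / n_out
    x = (np.arange(n_out) + 0.5) * scale - 0.5
    x = np.clip(x, 0.0, n_in - 1.0)
    lo = np.floor(x).astype(np.intp)
    hi = np.minimum(lo + 1, n_in - 1)
    w = x - lo
    return lo, hi, w


def resize_along_axis(arr: np.ndarray, axis: int, n_out: int, order: int) -> np.ndarray:
    """Resample ``arr`` along ``axis`` to ``n_out`` samples.

    ``order=1`` linear, ``order=0`` nearest-neighbour.  Identity sizes return
    the input unchanged (bit-exact).
    """
    n_in = arr.shape[axis]
    if n_out == n_in:
        return arr
    if n_out < 1:
        raise ValueError("target length must be positive")
    lo, hi, w = _axis_interp_weights(n_in, n_out)
    if order == 0:
        idx = np.where(w < 0.5, lo, hi)
        return np.take(arr, idx, axis=axis)
    a = np.take(arr, lo, axis=axis)
    b = np.take(arr, hi, axis=axis)
    shape = [1] * arr.ndim
    shape[axis] = n_out
    w = w.reshape(shape)
    return a * (1.0 - w) + b * w


def resize_3d(arr: np.ndarray, target: tuple[int, int, int], order: int) -> np.ndarray:
    """Separable resize of the last three axes of ``arr`` to ``target``."""
    out = arr
    nd = arr.ndim
    for k, n_out in enumerate(target):
        out = resize_along_axis(out, nd - 3 + k, int(n_out), order)
    return out


def resize_volume(sample: Sample, target_shape: tuple[int, int, int]) -> Sample:
    """Resample a case to ``target_shape`` (trilinear image, nearest label).

    Voxel spacing in the metadata is rescaled so physical extent is
    preserved.  A target equal to the current shape returns a bit-identical
    copy.
    """
    target = tuple(int(t) for t in target_shape)
    if len(target) != 3 or any(t <= 0 for t in target):
        raise ValueError(f"target_shape must be 3 positive integers, got {target_shape}")
    old = sample.spatial_shape
    image = resize_3d(sample.image, target, order=1)
    label = resize_3d(sample.label, target, order=0)
    meta = dict(sample.meta)
    spacing = meta.get("spacing", (1.0, 1.0, 1.0))
    meta["spacing"] = tuple(float(s) * o / t for s, o, t in zip(spacing, old, target))
    return Sample(image.copy(), label.copy(), meta)


def normalize_volume(sample: Sample, scheme: str = "zscore_per_channel") -> Sample:
    """Apply per-channel intensity normalization over the whole volume.

    ``zscore_per_channel`` maps each channel to zero mean / unit sd (a
    constant channel maps to all-zero rather than dividing by zero);
    ``minmax_per_channel`` maps each channel affinely onto [0, 1]; ``none``
    is the identity.  The label is untouched.
    """
    if scheme not in NORMALIZATION_SCHEMES:
        raise ValueError(
            f"unknown normalization scheme {scheme!r}; valid: {NORMALIZATION_SCHEMES}"
        )
    if scheme == "none":
        return sample.copy()
    image = sample.image.astype(np.float64).copy()
    for c in range(image.shape[0]):
        ch = image[c]
        if scheme == "zscore_per_channel":
            sd = ch.std()
            image[c] = 0.0 if sd == 0 else (ch - ch.mean()) / sd
        else:
            lo, hi = ch.min(), ch.max()
            image[c] = 0.0 if hi == lo else (ch - lo) / (hi - lo)
    return Sample(image, sample.label.copy(), dict(sample.meta))


def write_mask(mask: np.ndarray, ref: "Sample | Mapping", path: str | Path) -> None:
    """Write a binary mask as NIfTI carrying the reference affine.

    ``ref`` may be a :class:`Sample` (its spatial shape is then enforced) or a
    bare metadata mapping.
    """
    mask = np.asarray(mask)
    if isinstance(ref, Sample):
        if tuple(mask.shape) != ref.spatial_shape:
            raise ValueError(
                f"mask shape {mask.shape} != reference shape {ref.spatial_shape}"
            )
        ref_meta: Mapping = ref.meta
    else:
        ref_meta = ref
        ref_shape = ref_meta.get("spatial_shape")
        if ref_shape is not None and tuple(mask.shape) != tuple(ref_shape):
            raise ValueError(
                f"mask shape {mask.shape} != reference shape {tuple(ref_shape)}"
            )
    vals = np.unique(mask)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("mask must be binary")
    affine = np.asarray(ref_meta.get("affine", np.eye(4)))
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


def write_volume(volume: np.ndarray, ref: "Sample | Mapping", path: str | Path) -> None:
    """Write a single-channel float volume (e.g. a probability map) as NIfTI."""
    ref_meta = ref.meta if isinstance(ref, Sample) else ref
    affine = np.asarray(ref_meta.get("affine", np.eye(4)))
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))
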