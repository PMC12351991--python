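"""Seeded PET/CT-like phantom volumes with binary lesion masks.

The generator emulates the data regime of co-registered head-and-neck PET/CT
tumour cases: a structure channel made of a few tissue-intensity plateaus
plus Gaussian noise, an uptake channel with elevated signal inside the
lesion, and a small, connected, irregular-boundary lesion mask.  Lesions are
star-shaped (perturbed ellipsoids), so masks are guaranteed 6-connected, and
everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import Sample

__all__ = ["PhantomSpec", "make_phantom", "make_fixture_suite"]

# Structure-channel plateau intensities: background, body, dense core.
_CT_BACKGROUND = -100.0
_CT_BODY = 40.0
_CT_CORE = 200.0
_PET_BACKGROUND = 1.0


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of one synthetic PET/CT-like case.

    ``boundary_irregularity`` is the amplitude of a smooth low-order radial
    perturbation of each ellipsoidal lesion (0 gives exact ellipsoids);
    ``uptake_contrast`` is the mean uptake elevation inside the lesion over
    the uptake background.  Identical spec + seed always produces identical
    arrays.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    n_lesions: int = 1
    lesion_radius_range: tuple[float, float] = (6.0, 10.0)
    boundary_irregularity: float = 0.25
    noise_sd: float = 1.0
    uptake_contrast: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s < 4 for s in self.shape):
            raise ValueError(f"shape must be 3 integers >= 4, got {self.shape}")
        rmin, rmax = self.lesion_radius_range
        if not 0 < rmin <= rmax:
            raise ValueError("lesion_radius_range must satisfy 0 < min <= max")
        margin = 2.0
        if any(2 * (rmax + margin) >= s for s in self.shape):
            raise ValueError(
                f"lesion radius {rmax} does not fit inside shape {self.shape} "
                f"with a {margin}-voxel margin"
            )
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be non-negative")
        if self.boundary_irregularity < 0 or self.noise_sd < 0:
            raise ValueError("irregularity and noise_sd must be non-negative")
        if self.uptake_contrast <= 0:
            raise ValueError("uptake_contrast must be positive")


def _ellipsoid_field(shape, center, axes):
    """Normalised squared radius rho^2 = sum(((x-c)/a)^2) on the voxel grid."""
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
    rho2 = np.zeros(shape, dtype=np.float64)
    for g, c, a in zip(grids, center, axes):
        rho2 += ((g - c) / a) ** 2
    return grids, rho2


def _radial_perturbation(grids, center, amplitude, rng):
    """Smooth low-order angular modulation of the lesion radius.

    A random quadratic form on the unit direction vector — the real degree-2
    spherical-harmonic subspace — which keeps the boundary smooth and, with
    the amplitude clipped below 0.5, keeps the lesion star-shaped and hence
    6-connected.
    """
    if amplitude == 0:
        return 0.0
    d = [g - c for g, c in zip(grids, center)]
    norm = np.sqrt(d[0] ** 2 + d[1] ** 2 + d[2] ** 2) + 1e-9
    u = [di / norm for di in d]
    coef = rng.standard_normal(6)
    coef /= np.sqrt((coef**2).sum()) + 1e-12
    field = (
        coef[0] * (u[0] * u[1])
        + coef[1] * (u[1] * u[2])
        + coef[2] * (u[0] * u[2])
        + coef[3] * (u[0] ** 2 - u[1] ** 2)
        + coef[4] * (u[1] ** 2 - u[2] ** 2)
        + coef[5] * (u[2] ** 2 - 1.0 / 3.0)
    )
    return np.clip(amplitude * field, -0.45, 0.45)


def _lesion_mask(shape, center, axes, irregularity, rng):
    grids, rho2 = _ellipsoid_field(shape, center, axes)
    pert = _radial_perturbation(grids, center, irregularity, rng)
    # inside iff radial distance <= (1 + pert) * ellipsoid radius
    return np.sqrt(rho2) <= 1.0 + pert


def make_phantom(spec: PhantomSpec) -> Sample:
    """Generate one two-channel phantom with its lesion mask.

    Channel 0 (structure): nested-ellipsoid intensity plateaus + noise.
    Channel 1 (uptake): low background, smoothly elevated inside each lesion
    by ~``uptake_contrast``, + noise.  Label: union of ``n_lesions`` perturbed
    ellipsoids, each connected.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    center = tuple((s - 1) / 2.0 for s in shape)

    # Structure channel: body ellipsoid with a denser core, 3 plateaus.
    body_axes = tuple(0.42 * s for s in shape)
    core_axes = tuple(0.18 * s for s in shape)
    _, body_rho2 = _ellipsoid_field(shape, center, body_axes)
    _, core_rho2 = _ellipsoid_field(shape, center, core_axes)
    ct = np.full(shape, _CT_BACKGROUND)
    ct[body_rho2 <= 1.0] = _CT_BODY
    ct[core_rho2 <= 1.0] = _CT_CORE

    pet = np.full(shape, _PET_BACKGROUND)
    label = np.zeros(shape, dtype=np.int8)

    rmin, rmax = spec.lesion_radius_range
    for _ in range(spec.n_lesions):
        axes = rng.uniform(rmin, rmax, size=3)
        margin = axes.max() * (1.45 if spec.boundary_irregularity > 0 else 1.0) + 2.0
        c = tuple(
            rng.uniform(margin, s - 1 - margin) if s - 1 - margin > margin else (s - 1) / 2.0
            for s in shape
        )
        mask = _lesion_mask(shape, c, axes, spec.boundary_irregularity, rng)
        label[mask] = 1
        # Uptake: hottest at the lesion centre, still clearly elevated at the rim.
        _, rho2 = _ellipsoid_field(shape, c, axes)
        profile = np.clip(1.0 - 0.5 * rho2, 0.3, 1.0)
        pet = np.where(mask, _PET_BACKGROUND + 1.3 * spec.uptake_contrast * profile, pet)

    if spec.noise_sd > 0:
        ct = ct + rng.normal(0.0, spec.noise_sd, shape)
        pet = pet + rng.normal(0.0, spec.noise_sd, shape)

    image = np.stack([ct, pet], axis=0)
    meta = {
        "case_id": f"phantom-{spec.seed}",
        "spacing": (1.0, 1.0, 1.0),
        "affine": np.eye(4),
        "inference": False,
    }
    return Sample(image, label, meta)


def make_fixture_suite(seed: int = 0, shape: tuple[int, int, int] = (48, 48, 48)) -> dict[str, Sample]:
    """Deterministic suite of edge-case phantoms keyed by descriptive name.

    Contains at least: an empty-label case, a single-voxel-label case, a
    full-volume-label case, a standard one-lesion case and a two-lesion case
    (disjoint lesions, so per-axis label bounds span both).  Per-case RNG
    streams derive from ``(seed, case index)``.
    """
    shape = tuple(int(s) for s in shape)
    radius = (5.0, 8.0)

    def sub(idx):  # independent per-case stream
        return int(np.random.default_rng([seed, idx]).integers(0, 2**31 - 1))

    suite: dict[str, Sample] = {}

    empty = make_phantom(PhantomSpec(shape, n_lesions=0, lesion_radius_range=radius, seed=sub(0)))
    suite["empty_label"] = empty

    single = make_phantom(PhantomSpec(shape, n_lesions=0, lesion_radius_range=radius, seed=sub(1)))
    cz = tuple(s // 2 for s in shape)
    single.label[cz] = 1
    single.image[1][cz] += single.meta.get("uptake_contrast", 6.0)
    suite["single_voxel_label"] = single

    full = make_phantom(PhantomSpec(shape, n_lesions=0, lesion_radius_range=radius, seed=sub(2)))
    full.label[...] = 1
    suite["full_volume_label"] = full

    suite["one_lesion"] = make_phantom(
        PhantomSpec(shape, n_lesions=1, lesion_radius_range=radius, seed=sub(3))
    )

    # Two disjoint lesions placed explicitly in opposite corners.
    rng = np.random.default_rng(sub(4))
    two = make_phantom(PhantomSpec(shape, n_lesions=0, lesion_radius_range=radius, seed=sub(4)))
    label = np.zeros(shape, dtype=np.int8)
    pet = two.image[1]
    for frac in (0.28, 0.72):
        c = tuple(frac * (s - 1) for s in shape)
        axes = rng.uniform(*radius, size=3)
        mask = _lesion_mask(shape, c, axes, 0.2, rng)
        label[mask] = 1
        pet[mask] = _PET_BACKGROUND + 1.3 * 6.0
    two.label = label
    suite["two_lesions"] = two
    return suite
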