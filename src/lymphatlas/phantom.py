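"""Synthetic head-and-neck phantom cohort generator.

Real cervical CT cohorts with expert-drawn nodal-level contours cannot be
shipped, so every downstream stage (segmentation, correspondence,
registration, retrieval, evaluation) is exercised on synthetic subjects
that reproduce the geometry the pipeline relies on: an ellipsoidal
soft-tissue "body" containing high-intensity bone structures (a spine-like
vertical column, a mandible-like flattened arch, a small hyoid), tubular
contrast-enhanced vessels (jugular/carotid analogs), and labeled nodal
region masks standing in for expert contours.

Intensities are CT-like (air ~ -1000, soft tissue ~ 40, contrast vessel
~ 200, bone ~ 700) so intensity windows behave like Hounsfield ranges.
Structure primitives are analytic (ellipsoid / z-axis tube / box)
rasterized at voxel centers, which makes expected volumes and centroids
exact for oracle tests.

Inter-subject variation has two parts: per-structure pose/scale jitter,
and a smooth ground-truth warp that is itself a cubic B-spline field on a
coarse control grid — so a registration that uses the same transform model
can represent perfect recovery, turning registration tests into
parameter-recovery tests.  The cohort is a pure function of its spec: one
root seed, per-subject derived streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from . import ffd
from .spatial import RegionMask, VolumeGeometry, VolumeImage

__all__ = [
    "Primitive",
    "PhantomSpec",
    "CohortSpec",
    "SubjectBundle",
    "PhantomSpecError",
    "default_phantom_spec",
    "generate_phantom",
    "generate_cohort",
    "generate_graded_cohort",
    "warp_volume",
    "warp_mask",
    "dense_displacement",
]

# CT-like intensity levels (arbitrary Hounsfield-style units)
AIR = -1000.0
SOFT_TISSUE = 40.0
VESSEL = 200.0
BONE = 700.0


class PhantomSpecError(ValueError):
    """A phantom spec places structures outside the volume or is inconsistent."""


@dataclass(frozen=True)
class Primitive:
    """Analytic shape primitive in world mm.

    ``kind``:
      * ``ellipsoid`` — ``size`` are semi-axes;
      * ``tube`` — z-axis cylinder, ``size = (radius, radius, half_length)``;
      * ``box`` — ``size`` are half-widths.
    """

    name: str
    kind: Literal["ellipsoid", "tube", "box"]
    center: tuple[float, float, float]
    size: tuple[float, float, float]
    intensity: float = SOFT_TISSUE

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership for points of shape ``(..., 3)``."""
        rel = (np.asarray(points, float) - np.asarray(self.center)) / np.asarray(self.size)
        if self.kind == "ellipsoid":
            return (rel**2).sum(axis=-1) <= 1.0
        if self.kind == "tube":
            return ((rel[..., 0] ** 2 + rel[..., 1] ** 2) <= 1.0) & (
                np.abs(rel[..., 2]) <= 1.0
            )
        if self.kind == "box":
            return np.all(np.abs(rel) <= 1.0, axis=-1)
        raise PhantomSpecError(f"unknown primitive kind {self.kind!r}")

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center, float)
        s = np.asarray(self.size, float)
        return c - s, c + s

    def analytic_volume(self) -> float:
        a, b, c = self.size
        if self.kind == "ellipsoid":
            return 4.0 / 3.0 * np.pi * a * b * c
        if self.kind == "tube":
            return np.pi * a * b * (2 * c)
        return 8.0 * a * b * c


@dataclass(frozen=True)
class PhantomSpec:
    """One subject: body ellipsoid, landmark structures, nodal regions, noise.

    ``noise_sd`` is voxelwise Gaussian intensity noise.  ``texture_sd`` /
    ``texture_length_mm`` add a smooth random intensity texture inside
    the body — soft tissue in CT is not uniform, and the texture keeps
    intensity-driven registration informative away from structure
    boundaries.  Both are zero-able for piecewise-constant oracles.
    """

    geometry: VolumeGeometry
    body: Primitive
    structures: tuple[Primitive, ...]
    nodal_regions: tuple[Primitive, ...]
    noise_sd: float = 10.0
    texture_sd: float = 0.0
    texture_length_mm: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "structures", tuple(self.structures))
        object.__setattr__(self, "nodal_regions", tuple(self.nodal_regions))
        if self.noise_sd < 0 or self.texture_sd < 0:
            raise PhantomSpecError("noise_sd and texture_sd must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """A cohort: base subject plus jitter and smooth-warp variation.

    ``warp_amplitude_mm`` is the peak displacement magnitude of each
    subject's ground-truth warp; ``warp_control_spacing_mm`` the control
    grid spacing of the B-spline field generating it.  ``jitter_mm`` /
    ``jitter_scale`` are the SDs of per-structure center translation and
    relative size perturbation.
    """

    base: PhantomSpec
    n_subjects: int = 20
    jitter_mm: float = 3.0
    jitter_scale: float = 0.05
    warp_amplitude_mm: float = 5.0
    warp_control_spacing_mm: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise PhantomSpecError("n_subjects must be >= 1")
        if self.warp_amplitude_mm < 0:
            raise PhantomSpecError("warp amplitude must be >= 0")


@dataclass
class SubjectBundle:
    """One generated subject with its ground truth.

    ``warp`` is the B-spline displacement grid of the ground-truth
    deformation: the subject volume satisfies
    ``subject(x) = prewarp(x + D(x))`` where ``prewarp`` is the jittered
    (but unwarped) phantom — i.e. the warp maps subject coordinates onto
    the pre-warp frame.
    """

    subject_id: str
    volume: VolumeImage
    structures: RegionMask
    nodal_regions: RegionMask
    warp: ffd.ControlGrid | None
    prewarp_volume: VolumeImage
    prewarp_structures: RegionMask
    prewarp_nodal: RegionMask


def default_phantom_spec(
    dims: tuple[int, int, int] = (96, 96, 72),
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.5),
    noise_sd: float = 10.0,
    texture_sd: float = 50.0,
    seed: int = 0,
) -> PhantomSpec:
    """Neck-like default subject (~192 x 192 x 180 mm field of view).

    Anterior is +y, superior is +z.  The body is a vertical ellipsoid;
    the spine a posterior bone tube; the mandible a flattened anterior
    bone ellipsoid near the top; the hyoid a small bone ellipsoid below
    it; jugular/carotid analogs are lateral contrast tubes; nodal levels
    1B/2 (left/right) are soft ellipsoids between mandible and vessels.
    """
    geometry = VolumeGeometry(dims, spacing)
    ext = geometry.extent
    cx, cy, cz = ext / 2.0
    body = Primitive("body", "ellipsoid", (cx, cy, cz), (0.40 * ext[0], 0.36 * ext[1], 0.48 * ext[2]), SOFT_TISSUE)
    structures = (
        Primitive("spine", "tube", (cx, cy - 0.18 * ext[1], cz), (9.0, 9.0, 0.44 * ext[2]), BONE),
        Primitive("mandible", "ellipsoid", (cx, cy + 0.16 * ext[1], cz + 0.28 * ext[2]), (26.0, 16.0, 9.0), BONE),
        Primitive("hyoid", "ellipsoid", (cx, cy + 0.18 * ext[1], cz + 0.04 * ext[2]), (11.0, 6.0, 4.5), BONE),
        Primitive("jugular_left", "tube", (cx - 0.22 * ext[0], cy + 0.02 * ext[1], cz), (5.5, 5.5, 0.42 * ext[2]), VESSEL),
        Primitive("jugular_right", "tube", (cx + 0.22 * ext[0], cy + 0.02 * ext[1], cz), (5.5, 5.5, 0.42 * ext[2]), VESSEL),
        Primitive("carotid_left", "tube", (cx - 0.13 * ext[0], cy + 0.06 * ext[1], cz), (3.5, 3.5, 0.42 * ext[2]), VESSEL),
        Primitive("carotid_right", "tube", (cx + 0.13 * ext[0], cy + 0.06 * ext[1], cz), (3.5, 3.5, 0.42 * ext[2]), VESSEL),
    )
    nodal = (
        Primitive("level_1B_left", "ellipsoid", (cx - 0.12 * ext[0], cy + 0.20 * ext[1], cz + 0.17 * ext[2]), (14.0, 11.0, 13.0)),
        Primitive("level_1B_right", "ellipsoid", (cx + 0.12 * ext[0], cy + 0.20 * ext[1], cz + 0.17 * ext[2]), (14.0, 11.0, 13.0)),
        Primitive("level_2_left", "ellipsoid", (cx - 0.20 * ext[0], cy + 0.10 * ext[1], cz + 0.10 * ext[2]), (12.0, 12.0, 16.0)),
        Primitive("level_2_right", "ellipsoid", (cx + 0.20 * ext[0], cy + 0.10 * ext[1], cz + 0.10 * ext[2]), (12.0, 12.0, 16.0)),
    )
    return PhantomSpec(
        geometry, body, structures, nodal,
        noise_sd=noise_sd, texture_sd=texture_sd, seed=seed,
    )


def generate_phantom(spec: PhantomSpec) -> tuple[VolumeImage, RegionMask, RegionMask]:
    """Rasterize one subject: intensity volume, structure mask, nodal mask.

    Deterministic given ``spec.seed``; Gaussian noise of SD ``noise_sd``
    is added to the intensity volume only, never to the masks.
    """
    geom = spec.geometry
    lo = np.asarray(geom.origin, float)
    hi = lo + geom.extent
    for prim in (spec.body, *spec.structures, *spec.nodal_regions):
        pmin, pmax = prim.bounds()
        if np.any(pmin < lo - 1e-9) or np.any(pmax > hi + 1e-9):
            raise PhantomSpecError(
                f"structure {prim.name!r} extends outside the volume bounds"
            )
    centers = geom.voxel_centers()
    values = np.full(geom.dims, AIR)
    body_in = spec.body.contains(centers)
    values[body_in] = spec.body.intensity

    struct_labels = np.zeros(geom.dims, dtype=np.int32)
    struct_names: dict[int, str] = {}
    for i, prim in enumerate(spec.structures, start=1):
        inside = prim.contains(centers)
        values[inside] = prim.intensity
        struct_labels[inside] = i
        struct_names[i] = prim.name

    nodal_labels = np.zeros(geom.dims, dtype=np.int32)
    nodal_names: dict[int, str] = {}
    for i, prim in enumerate(spec.nodal_regions, start=1):
        nodal_labels[prim.contains(centers)] = i
        nodal_names[i] = prim.name

    rng = np.random.default_rng(spec.seed)
    if spec.texture_sd > 0:
        sigma_vox = spec.texture_length_mm / np.asarray(geom.spacing)
        tex = gaussian_filter(rng.normal(size=geom.dims), sigma=sigma_vox)
        tex *= spec.texture_sd / max(tex.std(), 1e-12)
        values[body_in] += tex[body_in]
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)

    return (
        VolumeImage(geom, values),
        RegionMask(geom, struct_labels, struct_names),
        RegionMask(geom, nodal_labels, nodal_names),
    )


# ---------------------------------------------------------------------------
# Ground-truth warps


def _random_warp(
    geometry: VolumeGeometry,
    amplitude_mm: float,
    control_spacing_mm: float,
    rng: np.random.Generator,
) -> ffd.ControlGrid:
    """Smooth random B-spline field with peak displacement ``amplitude_mm``.

    Coefficients are drawn i.i.d. normal and the whole field rescaled so
    its maximum magnitude over the voxel grid equals the requested
    amplitude — "amplitude" therefore means peak, not RMS, displacement.
    """
    res = tuple(
        int(max(4, round(geometry.extent[d] / control_spacing_mm))) for d in range(3)
    )
    grid = ffd.build_control_grid(res, geometry)
    if amplitude_mm == 0:
        return grid
    grid.coefficients = rng.normal(size=grid.coefficients.shape)
    disp = dense_displacement(grid, geometry)
    peak = np.linalg.norm(disp, axis=-1).max()
    grid.coefficients *= amplitude_mm / peak
    return grid


def dense_displacement(grid: ffd.ControlGrid, geometry: VolumeGeometry) -> np.ndarray:
    """Displacement field at every voxel center, shape ``dims + (3,)``."""
    centers = geometry.voxel_centers().reshape(-1, 3)
    disp = ffd.evaluate_deformation(centers, grid, check_domain=False)
    return disp.reshape(*geometry.dims, 3)


def _pullback_coords(grid: ffd.ControlGrid, geometry: VolumeGeometry) -> np.ndarray:
    """Fractional voxel coords of ``x + D(x)`` for every voxel center ``x``."""
    disp = dense_displacement(grid, geometry)
    src = geometry.voxel_centers() + disp
    return (src - np.asarray(geometry.origin)) / np.asarray(geometry.spacing)


def warp_volume(volume: VolumeImage, grid: ffd.ControlGrid) -> VolumeImage:
    """Resample: ``out(x) = volume(x + D(x))`` with linear interpolation."""
    coords = _pullback_coords(grid, volume.geometry)
    out = map_coordinates(
        volume.values, coords.reshape(-1, 3).T, order=1, mode="nearest"
    ).reshape(volume.geometry.dims)
    return VolumeImage(volume.geometry, out)


def warp_mask(mask: RegionMask, grid: ffd.ControlGrid) -> RegionMask:
    """Resample labels through the warp with nearest-neighbor lookup."""
    coords = _pullback_coords(grid, mask.geometry)
    out = map_coordinates(
        mask.labels, coords.reshape(-1, 3).T, order=0, mode="constant", cval=0
    ).reshape(mask.geometry.dims)
    return RegionMask(mask.geometry, out.astype(np.int32), dict(mask.label_names))


def _jitter_spec(spec: PhantomSpec, rng: np.random.Generator, cohort: CohortSpec) -> PhantomSpec:
    def jitter(prim: Primitive) -> Primitive:
        shift = rng.normal(0.0, cohort.jitter_mm, size=3)
        scale = 1.0 + rng.normal(0.0, cohort.jitter_scale, size=3)
        scale = np.clip(scale, 0.7, 1.3)
        return replace(
            prim,
            center=tuple(np.asarray(prim.center) + shift),
            size=tuple(np.asarray(prim.size) * scale),
        )

    return replace(
        spec,
        structures=tuple(jitter(p) for p in spec.structures),
        nodal_regions=tuple(jitter(p) for p in spec.nodal_regions),
    )


def generate_cohort(spec: CohortSpec) -> list[SubjectBundle]:
    """Generate ``n_subjects`` variations of the base subject.

    Subject 0 is the base itself (no jitter, no warp) so it can serve as
    a natural reference/query.  Each other subject applies pose jitter to
    the primitives and then a smooth ground-truth warp; nodal masks are
    warped with the same field, standing in for expert contours drawn on
    the warped anatomy.
    """
    root = np.random.default_rng(spec.seed)
    subject_seeds = root.integers(0, 2**31 - 1, size=spec.n_subjects)
    bundles: list[SubjectBundle] = []
    for i in range(spec.n_subjects):
        rng = np.random.default_rng(subject_seeds[i])
        if i == 0:
            sub_spec = replace(spec.base, seed=int(subject_seeds[i]))
            vol, struct, nodal = generate_phantom(sub_spec)
            bundles.append(
                SubjectBundle(f"subject_{i:02d}", vol, struct, nodal, None, vol, struct, nodal)
            )
            continue
        sub_spec = replace(
            _jitter_spec(spec.base, rng, spec), seed=int(subject_seeds[i])
        )
        vol, struct, nodal = generate_phantom(sub_spec)
        warp = _random_warp(
            spec.base.geometry,
            spec.warp_amplitude_mm,
            spec.warp_control_spacing_mm,
            rng,
        )
        bundles.append(
            SubjectBundle(
                f"subject_{i:02d}",
                warp_volume(vol, warp),
                warp_mask(struct, warp),
                warp_mask(nodal, warp),
                warp,
                vol,
                struct,
                nodal,
            )
        )
    return bundles


def generate_graded_cohort(
    base: PhantomSpec,
    amplitudes_mm: Sequence[float],
    control_spacing_mm: float = 40.0,
    seed: int = 0,
) -> list[SubjectBundle]:
    """Warp one base subject by one deformation shape at graded amplitudes.

    All subjects share the base render (no jitter) and a single random
    deformation *shape*; subject i applies it scaled to peak amplitude
    ``amplitudes_mm[i]``.  Scaling one shape (rather than drawing
    independent fields) makes dissimilarity from the base genuinely
    monotone in the amplitude — with independent fields a large warp
    far from the landmark structures can look more similar than a small
    warp right on them — so the construction is a controlled gradient
    for retrieval-ordering experiments.
    """
    root = np.random.default_rng(seed)
    vol, struct, nodal = generate_phantom(replace(base, seed=int(root.integers(2**31))))
    unit_warp = _random_warp(base.geometry, 1.0, control_spacing_mm, root)
    bundles = []
    for i, amp in enumerate(amplitudes_mm):
        warp = unit_warp.copy()
        warp.coefficients = unit_warp.coefficients * float(amp)
        bundles.append(
            SubjectBundle(
                f"graded_{i:02d}",
                warp_volume(vol, warp) if amp > 0 else vol,
                warp_mask(struct, warp) if amp > 0 else struct,
                warp_mask(nodal, warp) if amp > 0 else nodal,
                warp,
                vol,
                struct,
                nodal,
            )
        )
    return bundles
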