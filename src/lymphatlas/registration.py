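"""Multi-resolution mutual-information registration with landmark initialization.

Direction convention (the classic registration pitfall, so stated up
front): the optimized transform ::

    g(x | mu) = R (x - x_C) + x_C + T + D(x | delta)

takes a point ``x`` of the **target** subject's frame to the matching
location in the **reference** subject's frame, i.e. the reference
intensities satisfy ``reference(g(x)) ~= target(x)``.  That is exactly
the map region projection needs: a reference-drawn region lands on the
target by sampling every target voxel center through ``g`` and looking
the label up in the reference mask (nearest neighbor — labels are never
intensity-interpolated).

Pipeline: a rigid mutual-information stage estimates rotation and
translation; the reference is resampled once through the rigid map, and
a multi-resolution B-spline stage refines a deformation grid over the
target geometry (default schedule [6,6,5] -> [10,10,8] -> [15,15,11]).
At the start of each level the previous field is re-expressed at the
level's resolution; when landmark correspondences are supplied, every
control point with a landmark within ``proximity_radius`` has its
deformation value overwritten by the nearest landmark's deformation
vector before the intensity optimization runs — the mutual-information
step then smooths whatever roughness the landmark assignment introduced.

Mutual information is estimated with Mattes' Parzen-windowed joint
histogram (50 bins, 5% random voxel sampling with a fixed seed) and
optimized by SimpleITK's registration framework; the transform lattice
is shared bit-for-bit between this package's
:class:`~lymphatlas.ffd.ControlGrid` and ``sitk.BSplineTransform``, so
optimized coefficients flow back into the package's own transform model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

from . import ffd
from .correspondence import LandmarkPairs
from .spatial import RegionMask, VolumeGeometry, VolumeImage

__all__ = [
    "RegistrationConfig",
    "RegistrationResult",
    "MetricError",
    "DivergenceError",
    "rigid_register",
    "initialize_deformation_from_landmarks",
    "deformable_register",
    "project_region",
    "dense_transform_displacement",
]


class MetricError(RuntimeError):
    """The similarity metric could not be evaluated (e.g. constant image)."""


class DivergenceError(RuntimeError):
    """The optimizer produced a non-finite metric value."""


@dataclass(frozen=True)
class RegistrationConfig:
    """Controls for the rigid and deformable stages.

    ``resolution_schedule`` lists control-grid resolutions coarse to
    fine (non-decreasing per axis); ``proximity_radius_mm`` of ``None``
    means one control-grid spacing at the current level.
    """

    resolution_schedule: tuple[tuple[int, int, int], ...] = (
        (6, 6, 5), (10, 10, 8), (15, 15, 11),
    )
    mi_bins: int = 50
    sample_fraction: float = 0.05
    iterations_per_level: int = 40
    rigid_iterations: int = 200
    convergence_tolerance: float = 1e-6
    proximity_radius_mm: float | None = None
    use_landmarks: bool = False
    seed: int = 12345
    # image pyramid per grid level: voxel shrink factor and smoothing sigma
    # (voxels); padded with the last entry when shorter than the schedule.
    # The final level must run at full resolution — the optimizer's
    # accuracy floor scales with the sampled image's voxel size.
    shrink_factors: tuple[int, ...] = (4, 2, 1)
    smoothing_sigmas: tuple[float, ...] = (2.0, 1.0, 0.0)

    def __post_init__(self) -> None:
        if self.mi_bins < 8:
            raise ValueError("mi_bins must be >= 8")
        if not 0 < self.sample_fraction <= 1:
            raise ValueError("sample_fraction must be in (0, 1]")
        sched = tuple(tuple(int(r) for r in level) for level in self.resolution_schedule)
        object.__setattr__(self, "resolution_schedule", sched)
        for prev, nxt in zip(sched, sched[1:]):
            if any(n < p for p, n in zip(prev, nxt)):
                raise ValueError(f"schedule must be non-decreasing per axis: {sched}")


@dataclass
class RegistrationResult:
    """Optimized transform plus convergence diagnostics."""

    params: ffd.TransformParameters
    converged: bool
    final_metric: float
    metric_trace: list[list[float]] = field(default_factory=list)


def _as_sitk(volume: VolumeImage) -> sitk.Image:
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(volume.values.transpose(2, 1, 0).astype(np.float64))
    )
    img.SetSpacing(tuple(volume.geometry.spacing))
    img.SetOrigin(tuple(volume.geometry.origin))
    return img


def _check_not_constant(volume: VolumeImage, name: str) -> None:
    v = volume.values
    if float(v.max() - v.min()) <= 0:
        raise MetricError(f"{name} image is constant; mutual information is undefined")


def volume_center(geometry: VolumeGeometry) -> np.ndarray:
    """World center of the sampled box (the rigid rotation center x_C)."""
    return np.asarray(geometry.origin) + geometry.extent / 2.0


def rigid_register(
    reference: VolumeImage, target: VolumeImage, config: RegistrationConfig | None = None
) -> ffd.RigidParameters:
    """Maximize mutual information over the 6 rigid parameters.

    Returns the rigid part of ``g`` (target frame to reference frame,
    rotating about the reference-volume center).  Deterministic for a
    fixed config seed.
    """
    config = config or RegistrationConfig()
    _check_not_constant(reference, "reference")
    _check_not_constant(target, "target")
    fixed = _as_sitk(target)
    moving = _as_sitk(reference)
    center = volume_center(reference.geometry)
    tx = sitk.Euler3DTransform()
    tx.SetCenter(tuple(center))

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=config.mi_bins)
    reg.SetMetricSamplingStrategy(reg.RANDOM)
    reg.SetMetricSamplingPercentage(config.sample_fraction, config.seed)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=2.0,
        minStep=1e-4,
        numberOfIterations=config.rigid_iterations,
        relaxationFactor=0.6,
        gradientMagnitudeTolerance=1e-6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    reg.SetInitialTransform(tx, inPlace=True)
    reg.Execute(fixed, moving)

    R = np.asarray(tx.GetMatrix()).reshape(3, 3)
    t = np.asarray(tx.GetTranslation())
    return ffd.RigidParameters.from_matrix(R, t, center)


def _nearest_landmark_values(
    positions: np.ndarray, landmarks: LandmarkPairs, radius: float
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-landmark deformation for each position within ``radius``."""
    tree = cKDTree(landmarks.points)
    dist, idx = tree.query(positions)
    within = dist <= radius
    values = np.zeros_like(positions)
    values[within] = landmarks.deformations[idx[within]]
    return values, within


def initialize_deformation_from_landmarks(
    grid: ffd.ControlGrid, landmarks: LandmarkPairs, proximity_radius: float
) -> ffd.ControlGrid:
    """Overwrite control-point deformations from nearby landmark pairs.

    Every lattice point with a landmark within ``proximity_radius`` takes
    the deformation vector of its *nearest* landmark; all other lattice
    points keep their current deformation value.  Coefficients are then
    re-fit so the spline interpolates the new value grid.  The result may
    be rough; the subsequent intensity optimization smooths it.
    """
    if len(landmarks) == 0:
        return grid.copy()
    axes = grid.lattice_positions()
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    current = ffd.grid_values(grid).reshape(-1, 3)
    new_vals, within = _nearest_landmark_values(pts, landmarks, proximity_radius)
    current[within] = new_vals[within]
    shape = tuple(r + 3 for r in grid.resolution) + (3,)
    return ffd.fit_coefficients_from_values(current.reshape(shape), grid)


def _resample_through_rigid(
    volume: VolumeImage, rigid: ffd.RigidParameters, geometry: VolumeGeometry
) -> VolumeImage:
    """``W(x) = volume(R (x - x_C) + x_C + T)`` on the ``geometry`` grid."""
    centers = geometry.voxel_centers().reshape(-1, 3)
    mapped = rigid.apply(centers)
    coords = (mapped - np.asarray(volume.geometry.origin)) / np.asarray(
        volume.geometry.spacing
    )
    vals = map_coordinates(
        volume.values, coords.T, order=1, mode="nearest"
    ).reshape(geometry.dims)
    return VolumeImage(geometry, vals)


def _sitk_bspline_from_grid(grid: ffd.ControlGrid, geometry: VolumeGeometry) -> sitk.BSplineTransform:
    tx = sitk.BSplineTransform(3, 3)
    tx.SetTransformDomainOrigin(tuple(np.asarray(geometry.origin, float)))
    tx.SetTransformDomainPhysicalDimensions(tuple(geometry.extent))
    tx.SetTransformDomainMeshSize([int(r) for r in grid.resolution])
    tx.SetTransformDomainDirection((1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0))
    flat = np.concatenate(
        [grid.coefficients[..., d].ravel(order="F") for d in range(3)]
    )
    tx.SetParameters(tuple(flat))
    return tx


def _grid_from_sitk(tx: sitk.BSplineTransform, grid: ffd.ControlGrid) -> ffd.ControlGrid:
    out = grid.copy()
    flat = np.asarray(tx.GetParameters())
    per = flat.size // 3
    shape = tuple(r + 3 for r in grid.resolution)
    for d in range(3):
        out.coefficients[..., d] = flat[d * per : (d + 1) * per].reshape(shape, order="F")
    return out


def deformable_register(
    reference: VolumeImage,
    target: VolumeImage,
    init: ffd.TransformParameters | None = None,
    config: RegistrationConfig | None = None,
    landmarks: LandmarkPairs | None = None,
) -> RegistrationResult:
    """Multi-resolution B-spline refinement of the deformation field.

    ``init`` supplies the rigid part (and optionally a starting grid);
    when absent the rigid part is estimated first.  ``landmarks``, when
    ``config.use_landmarks`` is set, are correspondence pairs with
    ``points`` on the reference structures and ``deformations`` pointing
    to the matched target locations; they are applied to in-radius
    control points at the start of every level.

    The deformation grid lives on the target geometry (the domain of
    ``g``); the rigid part is frozen during the B-spline stage.
    """
    config = config or RegistrationConfig()
    if config.use_landmarks and landmarks is None:
        raise ValueError("use_landmarks is set but no landmarks were provided")
    _check_not_constant(reference, "reference")
    _check_not_constant(target, "target")

    if init is None:
        rigid = rigid_register(reference, target, config)
        init_grid = None
    else:
        rigid = init.rigid
        init_grid = init.grid if np.any(init.grid.coefficients) else None
    geometry = target.geometry
    R = rigid.rotation_matrix()

    # Pull the reference once through the rigid map onto the target grid;
    # the B-spline stage then aligns `warped_ref` to `target` in that
    # shared frame.  In it the learned displacement relates to the model
    # deformation by D_model(x) = R @ D_learned(x).
    warped_ref = _resample_through_rigid(reference, rigid, geometry)

    lm = None
    if config.use_landmarks and landmarks is not None and len(landmarks):
        # Landmark pair: reference point v, matched target point w = v + zeta.
        # g must send w to v, so in the rigid-resampled frame the value at
        # grid positions near w is D_learned(w) = R^T (v - rigid(w)).
        target_pts = landmarks.matched
        zeta_learned = (landmarks.points - rigid.apply(target_pts)) @ R
        lm = LandmarkPairs(target_pts, zeta_learned)

    fixed = _as_sitk(target)
    moving = _as_sitk(warped_ref)

    grid = init_grid
    trace: list[list[float]] = []
    final_metric = np.nan
    for level, resolution in enumerate(config.resolution_schedule):
        if grid is None:
            grid = ffd.build_control_grid(resolution, geometry)
        elif tuple(resolution) != tuple(grid.resolution):
            grid = ffd.refine_grid(grid, resolution)
        if lm is not None:
            radius = (
                config.proximity_radius_mm
                if config.proximity_radius_mm is not None
                else float(grid.spacing.max())
            )
            grid = initialize_deformation_from_landmarks(grid, lm, radius)
        tx = _sitk_bspline_from_grid(grid, geometry)

        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=config.mi_bins)
        reg.SetMetricSamplingStrategy(reg.RANDOM)
        reg.SetMetricSamplingPercentage(config.sample_fraction, config.seed + level)
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetOptimizerAsLBFGSB(
            gradientConvergenceTolerance=config.convergence_tolerance,
            numberOfIterations=config.iterations_per_level,
            maximumNumberOfCorrections=5,
            maximumNumberOfFunctionEvaluations=2000,
        )
        shrink = (config.shrink_factors + config.shrink_factors[-1:] * len(
            config.resolution_schedule
        ))[level]
        sigma = (config.smoothing_sigmas + config.smoothing_sigmas[-1:] * len(
            config.resolution_schedule
        ))[level]
        reg.SetShrinkFactorsPerLevel([int(shrink)])
        reg.SetSmoothingSigmasPerLevel([float(sigma)])
        reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
        reg.SetInitialTransform(tx, inPlace=True)
        level_trace: list[float] = []
        reg.AddCommand(
            sitk.sitkIterationEvent,
            lambda reg=reg, lt=level_trace: lt.append(float(reg.GetMetricValue())),
        )
        try:
            reg.Execute(fixed, moving)
        except RuntimeError as exc:
            raise DivergenceError(
                f"optimizer failed at level {level} (resolution {resolution}): {exc}"
            ) from exc
        final_metric = float(reg.GetMetricValue())
        if not np.isfinite(final_metric):
            raise DivergenceError(
                f"non-finite metric at level {level} (resolution {resolution})"
            )
        trace.append(level_trace)
        grid = _grid_from_sitk(tx, grid)

    # rotate learned displacement vectors into the model frame
    model_grid = grid.copy()
    model_grid.coefficients = grid.coefficients @ R.T
    params = ffd.TransformParameters(rigid, model_grid)
    return RegistrationResult(params, True, final_metric, trace)


def dense_transform_displacement(
    params: ffd.TransformParameters, geometry: VolumeGeometry
) -> np.ndarray:
    """``g(x) - x`` at every voxel center of ``geometry``, shape ``dims + (3,)``."""
    centers = geometry.voxel_centers().reshape(-1, 3)
    mapped = params.rigid.apply(centers) + ffd.evaluate_deformation(
        centers, params.grid, check_domain=False
    )
    return (mapped - centers).reshape(*geometry.dims, 3)


def project_region(
    region: RegionMask,
    params: ffd.TransformParameters,
    target_geometry: VolumeGeometry,
) -> RegionMask:
    """Project a reference-frame label mask into the target frame.

    For each target voxel center ``x`` the label is looked up at
    ``g(x | mu)`` in the reference mask with nearest-neighbor sampling;
    voxels mapping outside the reference grid become background.
    """
    centers = target_geometry.voxel_centers().reshape(-1, 3)
    mapped = params.rigid.apply(centers) + ffd.evaluate_deformation(
        centers, params.grid, check_domain=False
    )
    coords = (mapped - np.asarray(region.geometry.origin)) / np.asarray(
        region.geometry.spacing
    )
    labels = map_coordinates(
        region.labels, coords.T, order=0, mode="constant", cval=0
    ).reshape(target_geometry.dims)
    return RegionMask(target_geometry, labels.astype(np.int32), dict(region.label_names))
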