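"""Rigid + cubic B-spline free-form deformation (FFD) transform model.

The transform maps a point ``x`` (mm, reference frame) into the target
frame as::

    g(x) = R (x - x_C) + x_C + T + D(x | delta)

where ``R`` is a rotation about the reference-volume center ``x_C``,
``T`` a translation, and ``D`` a deformation field interpolated from
per-control-point 3-vector coefficients ``delta_j`` on a uniform sparse
grid by tensor-product cubic B-splines.  The full parameter vector is
``mu = (gamma, theta, phi, t_x, t_y, t_z, delta_1, ..., delta_n)``.

Grid convention
---------------
A resolution ``rho = (rho_x, rho_y, rho_z)`` places ``rho_d`` interior
control points per axis with spacing ``q_d * voxel_spacing_d / rho_d``
(``q_d`` = image dimensions), so ``[15, 15, 11]`` means 2475 interior
control points.  The stored coefficient lattice carries one extra ring
before and two after the interior points (``rho_d + 3`` per axis) so the
cubic support covers the whole image extent; this matches the lattice
layout of ITK's ``BSplineTransform`` with mesh size ``rho``, which is
exploited by the registration engine.

Euler angles ``(gamma, theta, phi)`` compose as
``R = Rz(gamma) Ry(theta) Rx(phi)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates, spline_filter1d
from scipy.spatial.transform import Rotation

from .spatial import VolumeGeometry

__all__ = [
    "RigidParameters",
    "ControlGrid",
    "TransformParameters",
    "ConfigurationError",
    "OutOfDomainError",
    "build_control_grid",
    "evaluate_deformation",
    "transform_point",
    "refine_grid",
    "fit_coefficients_from_values",
]


class ConfigurationError(ValueError):
    """Invalid transform configuration (e.g. grid resolution below cubic support)."""


class OutOfDomainError(ValueError):
    """A point falls outside the control grid's supported extent."""


@dataclass
class RigidParameters:
    """Rigid-body part: roll-pitch-yaw Euler angles, translation, rotation center."""

    euler_angles: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def rotation_matrix(self) -> np.ndarray:
        g, t, p = self.euler_angles
        return Rotation.from_euler("ZYX", [g, t, p]).as_matrix()

    def apply(self, points: np.ndarray) -> np.ndarray:
        """``R (x - x_C) + x_C + T`` for points of shape ``(..., 3)``."""
        points = np.asarray(points, float)
        c = np.asarray(self.center, float)
        t = np.asarray(self.translation, float)
        return (points - c) @ self.rotation_matrix().T + c + t

    @classmethod
    def from_matrix(cls, matrix, translation, center) -> "RigidParameters":
        ang = Rotation.from_matrix(np.asarray(matrix, float)).as_euler("ZYX")
        return cls(tuple(ang), tuple(np.asarray(translation, float)), tuple(np.asarray(center, float)))


@dataclass
class ControlGrid:
    """Uniform cubic B-spline control lattice over an image extent.

    ``coefficients`` has shape ``(rho_x + 3, rho_y + 3, rho_z + 3, 3)``:
    interior point ``l`` along an axis sits at ``origin + l * spacing``
    (lattice index ``l + 1``); index 0 is the ghost ring one spacing
    before the origin.
    """

    resolution: tuple[int, int, int]
    spacing: np.ndarray
    origin: np.ndarray
    coefficients: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.resolution = tuple(int(r) for r in self.resolution)
        self.spacing = np.asarray(self.spacing, float)
        self.origin = np.asarray(self.origin, float)
        if any(r < 4 for r in self.resolution):
            raise ConfigurationError(
                f"resolution {self.resolution}: cubic B-spline support needs >= 4 "
                "control points per axis"
            )
        if np.any(self.spacing <= 0):
            raise ConfigurationError(f"grid spacing must be positive, got {self.spacing}")
        shape = tuple(r + 3 for r in self.resolution) + (3,)
        if self.coefficients is None:
            self.coefficients = np.zeros(shape)
        else:
            self.coefficients = np.asarray(self.coefficients, float)
            if self.coefficients.shape != shape:
                raise ConfigurationError(
                    f"coefficients shape {self.coefficients.shape} != {shape}"
                )

    @property
    def n_interior(self) -> int:
        """Interior control-point count, ``rho_x * rho_y * rho_z``."""
        return int(np.prod(self.resolution))

    @property
    def extent(self) -> np.ndarray:
        """Supported physical extent (mm) from the origin."""
        return self.spacing * np.asarray(self.resolution, float)

    def lattice_positions(self) -> list[np.ndarray]:
        """Per-axis world positions of the full coefficient lattice."""
        return [
            self.origin[d] + (np.arange(self.resolution[d] + 3) - 1.0) * self.spacing[d]
            for d in range(3)
        ]

    def interior_positions(self) -> np.ndarray:
        """World positions of the ``rho_x * rho_y * rho_z`` interior points, ``(n, 3)``."""
        axes = [
            self.origin[d] + np.arange(self.resolution[d]) * self.spacing[d]
            for d in range(3)
        ]
        grids = np.meshgrid(*axes, indexing="ij")
        return np.stack(grids, axis=-1).reshape(-1, 3)

    def copy(self) -> "ControlGrid":
        return ControlGrid(
            self.resolution, self.spacing.copy(), self.origin.copy(),
            self.coefficients.copy(),
        )


@dataclass
class TransformParameters:
    """The full parameter vector mu: rigid part plus deformation lattice."""

    rigid: RigidParameters
    grid: ControlGrid

    @property
    def n_parameters(self) -> int:
        return 6 + 3 * self.grid.n_interior

    def to_dict(self) -> dict:
        return {
            "rigid": {
                "euler_angles": list(self.rigid.euler_angles),
                "translation": list(self.rigid.translation),
                "center": list(self.rigid.center),
            },
            "grid": {
                "resolution": list(self.grid.resolution),
                "spacing": self.grid.spacing.tolist(),
                "origin": self.grid.origin.tolist(),
                "coefficients": self.grid.coefficients.ravel().tolist(),
            },
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, doc: dict) -> "TransformParameters":
        g = doc["grid"]
        res = tuple(int(r) for r in g["resolution"])
        shape = tuple(r + 3 for r in res) + (3,)
        grid = ControlGrid(
            res, np.asarray(g["spacing"]), np.asarray(g["origin"]),
            np.asarray(g["coefficients"], float).reshape(shape),
        )
        r = doc["rigid"]
        rigid = RigidParameters(
            tuple(r["euler_angles"]), tuple(r["translation"]), tuple(r["center"])
        )
        return cls(rigid, grid)

    @classmethod
    def load(cls, path) -> "TransformParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def identity(cls, grid: ControlGrid, center=(0.0, 0.0, 0.0)) -> "TransformParameters":
        return cls(RigidParameters(center=tuple(np.asarray(center, float))), grid.copy())


def build_control_grid(resolution, geometry: VolumeGeometry) -> ControlGrid:
    """Zero-coefficient grid over ``geometry``'s extent.

    Spacing per axis is ``q_d * voxel_spacing_d / rho_d`` so the grid's
    supported extent coincides with the image's physical extent.
    """
    resolution = tuple(int(r) for r in resolution)
    if any(r < 4 for r in resolution):
        raise ConfigurationError(
            f"resolution {resolution}: need >= 4 control points per axis"
        )
    spacing = geometry.extent / np.asarray(resolution, float)
    return ControlGrid(resolution, spacing, np.asarray(geometry.origin, float))


def _lattice_coords(points: np.ndarray, grid: ControlGrid) -> np.ndarray:
    """Continuous coefficient-lattice coordinates of world points, ``(n, 3)``."""
    points = np.atleast_2d(np.asarray(points, float))
    return (points - grid.origin) / grid.spacing + 1.0


def _eval_lattice(coeffs: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Evaluate the cubic spline with explicit coefficients at lattice coords.

    ``map_coordinates(order=3, prefilter=False)`` treats its input as
    spline coefficients, which is exactly what the lattice stores; the
    mirror extension only matters for lattice coordinates within one cell
    of the border and is consistent with the mirror boundary used when
    fitting coefficients from values.
    """
    out = np.empty((coords.shape[0], 3))
    for d in range(3):
        out[:, d] = map_coordinates(
            coeffs[..., d], coords.T, order=3, mode="mirror", prefilter=False
        )
    return out


def evaluate_deformation(x, grid: ControlGrid, check_domain: bool = True) -> np.ndarray:
    """Deformation ``D(x | delta)`` (mm) at world points ``x``.

    ``x`` may be a single point or an ``(n, 3)`` array; the output shape
    follows the input.  Points outside the supported extent raise
    :class:`OutOfDomainError` unless ``check_domain`` is False.
    """
    x = np.asarray(x, float)
    single = x.ndim == 1
    coords = _lattice_coords(x, grid)
    if check_domain:
        u = coords - 1.0  # interior-grid coordinates in [0, rho]
        rho = np.asarray(grid.resolution, float)
        if np.any(u < -1e-9) or np.any(u > rho + 1e-9):
            bad = np.atleast_2d(x)[np.any((u < -1e-9) | (u > rho + 1e-9), axis=1)][0]
            raise OutOfDomainError(
                f"point {bad} outside grid support [origin, origin + rho * spacing]"
            )
    out = _eval_lattice(grid.coefficients, coords)
    return out[0] if single else out


def transform_point(x, params: TransformParameters) -> np.ndarray:
    """``g(x) = R (x - x_C) + x_C + T + D(x | delta)``."""
    x = np.asarray(x, float)
    return params.rigid.apply(x) + evaluate_deformation(x, params.grid)


def fit_coefficients_from_values(values: np.ndarray, grid: ControlGrid) -> ControlGrid:
    """Interpolating spline coefficients for prescribed lattice values.

    ``values`` holds the desired deformation ``D'(lambda_j)`` at every
    lattice point (shape ``(rho_x + 3, rho_y + 3, rho_z + 3, 3)``).  The
    returned grid's spline reproduces those values at the lattice points
    (mirror boundary condition).
    """
    values = np.asarray(values, float)
    shape = tuple(r + 3 for r in grid.resolution) + (3,)
    if values.shape != shape:
        raise ConfigurationError(f"values shape {values.shape} != {shape}")
    coeffs = values.copy()
    for axis in range(3):
        coeffs = spline_filter1d(coeffs, order=3, axis=axis, mode="mirror")
    out = grid.copy()
    out.coefficients = coeffs
    return out


def grid_values(grid: ControlGrid) -> np.ndarray:
    """Deformation values at every lattice point (inverse of coefficient fit)."""
    shapes = [r + 3 for r in grid.resolution]
    idx = np.stack(
        np.meshgrid(*[np.arange(s, dtype=float) for s in shapes], indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    return _eval_lattice(grid.coefficients, idx).reshape(*shapes, 3)


def refine_grid(coarse: ControlGrid, fine_resolution) -> ControlGrid:
    """Re-express a deformation field on a finer lattice.

    The coarse field is sampled at the fine lattice points and converted
    back to interpolating coefficients, so the refined grid reproduces
    the coarse field up to the mirror-boundary approximation near the
    extent's edges.
    """
    fine_resolution = tuple(int(r) for r in fine_resolution)
    if any(f < c for f, c in zip(fine_resolution, coarse.resolution)):
        raise ConfigurationError(
            f"fine resolution {fine_resolution} below coarse {coarse.resolution}"
        )
    fine = ControlGrid(
        fine_resolution,
        coarse.extent / np.asarray(fine_resolution, float),
        coarse.origin.copy(),
    )
    axes = fine.lattice_positions()
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    vals = _eval_lattice(coarse.coefficients, _lattice_coords(pts, coarse))
    shape = tuple(r + 3 for r in fine_resolution) + (3,)
    return fit_coefficients_from_values(vals.reshape(shape), fine)
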