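"""Core spatial data types: volumes, label masks, and triangle surface meshes.

Conventions used throughout the package:

* voxel indices are 0-based ``(i, j, k)`` along ``(x, y, z)``;
* world coordinates are millimetres; volumes are axis-aligned (no oblique
  direction cosines), so the index-to-world map is the affine
  ``world = origin + index * spacing``;
* mesh vertices live in world millimetres.

Volumes and masks round-trip through MetaImage (``.mha``/``.mhd``) and
NIfTI (``.nii``/``.nii.gz``); meshes through PLY and STL.  Expert-style
contour stacks (per-slice closed polygons) can be rasterized into label
masks with :func:`rasterize_contour_stack`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import SimpleITK as sitk
import trimesh
from skimage import draw as _draw
from skimage import measure as _measure

__all__ = [
    "VolumeGeometry",
    "VolumeImage",
    "RegionMask",
    "SurfaceMesh",
    "FormatError",
    "EmptyRegionError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "voxel_to_world",
    "world_to_voxel",
    "extract_isosurface",
    "read_mesh",
    "write_mesh",
    "rasterize_contour_stack",
    "mesh_volume",
]


class FormatError(ValueError):
    """A file could not be interpreted as the expected spatial format."""


class EmptyRegionError(ValueError):
    """A requested label has no voxels in the mask."""


@dataclass(frozen=True)
class VolumeGeometry:
    """Grid geometry of a 3D volume: dimensions, spacing and origin.

    Parameters
    ----------
    dims
        Voxels per axis ``(q_x, q_y, q_z)``.
    spacing
        Millimetres per voxel along each axis; strictly positive.
    origin
        World position (mm) of voxel index ``(0, 0, 0)``.
    """

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.dims) != 3 or any(d < 1 for d in self.dims):
            raise ValueError(f"dims must be three integers >= 1, got {self.dims}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positives, got {self.spacing}")

    @property
    def extent(self) -> np.ndarray:
        """Physical size (mm) of the sampled box, ``dims * spacing``."""
        return np.asarray(self.dims, float) * np.asarray(self.spacing, float)

    def voxel_centers(self) -> np.ndarray:
        """World coordinates (mm) of every voxel center, shape ``dims + (3,)``."""
        axes = [
            self.origin[d] + np.arange(self.dims[d]) * self.spacing[d]
            for d in range(3)
        ]
        grids = np.meshgrid(*axes, indexing="ij")
        return np.stack(grids, axis=-1)


def voxel_to_world(index, geometry: VolumeGeometry) -> np.ndarray:
    """Map (fractional) voxel indices to world mm: ``origin + index * spacing``."""
    index = np.asarray(index, dtype=float)
    return np.asarray(geometry.origin) + index * np.asarray(geometry.spacing)


def world_to_voxel(point, geometry: VolumeGeometry) -> np.ndarray:
    """Inverse of :func:`voxel_to_world`; returns fractional indices."""
    point = np.asarray(point, dtype=float)
    return (point - np.asarray(geometry.origin)) / np.asarray(geometry.spacing)


@dataclass
class VolumeImage:
    """A 3D scalar image on a :class:`VolumeGeometry` grid.

    ``values`` is indexed ``[i, j, k]`` along ``(x, y, z)`` — note this is
    the transpose of the ``(z, y, x)`` order used by SimpleITK arrays.
    """

    geometry: VolumeGeometry
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if tuple(self.values.shape) != tuple(self.geometry.dims):
            raise ValueError(
                f"values shape {self.values.shape} != dims {self.geometry.dims}"
            )


@dataclass
class RegionMask:
    """Integer label volume with a name per label (0 is background)."""

    geometry: VolumeGeometry
    labels: np.ndarray
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if tuple(self.labels.shape) != tuple(self.geometry.dims):
            raise ValueError(
                f"labels shape {self.labels.shape} != dims {self.geometry.dims}"
            )
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.label_names)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from label_names")

    def label_of(self, name: str) -> int:
        for lab, nm in self.label_names.items():
            if nm == name:
                return lab
        raise KeyError(name)

    def binary(self, label: int) -> np.ndarray:
        return self.labels == label

    def volume_mm3(self, label: int) -> float:
        """Voxel count of ``label`` times the voxel volume."""
        voxvol = float(np.prod(self.geometry.spacing))
        return float(np.count_nonzero(self.labels == label)) * voxvol

    def centroid_mm(self, label: int) -> np.ndarray:
        idx = np.argwhere(self.labels == label)
        if idx.size == 0:
            raise EmptyRegionError(f"label {label} has no voxels")
        return voxel_to_world(idx.mean(axis=0), self.geometry)


@dataclass
class SurfaceMesh:
    """Triangle mesh with vertices in world millimetres.

    Zero-area faces are dropped at construction so downstream
    point-to-triangle distances never see degenerate triangles.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")
        if self.faces.size:
            tri = self.vertices[self.faces]
            areas = 0.5 * np.linalg.norm(
                np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
            )
            self.faces = self.faces[areas > 1e-12]

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """Face corner coordinates, shape ``(n_faces, 3, 3)``."""
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        tri = self.triangles()
        return 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )

    def transformed(self, matrix: np.ndarray, translation: np.ndarray) -> "SurfaceMesh":
        """Return a copy with vertices mapped through ``R v + t``."""
        v = self.vertices @ np.asarray(matrix, float).T + np.asarray(translation, float)
        return SurfaceMesh(v, self.faces.copy())

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)


# ---------------------------------------------------------------------------
# Volume / mask IO (MetaImage and NIfTI via SimpleITK)

_VOLUME_SUFFIXES = (".mha", ".mhd", ".nii", ".nii.gz")


def _check_volume_path(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _VOLUME_SUFFIXES):
        raise FormatError(
            f"{path}: unsupported volume format (expected one of {_VOLUME_SUFFIXES})"
        )


def _geometry_from_sitk(img: sitk.Image) -> VolumeGeometry:
    return VolumeGeometry(
        dims=tuple(img.GetSize()),
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
    )


def _sitk_from_array(values: np.ndarray, geometry: VolumeGeometry) -> sitk.Image:
    # sitk arrays are (z, y, x)
    img = sitk.GetImageFromArray(np.ascontiguousarray(values.transpose(2, 1, 0)))
    img.SetSpacing(tuple(geometry.spacing))
    img.SetOrigin(tuple(geometry.origin))
    return img


def read_volume(path) -> VolumeImage:
    """Read a MetaImage or NIfTI scalar volume.

    Raises :class:`FormatError` for missing files, unsupported formats, or
    non-3D images.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    _check_volume_path(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - sitk message passthrough
        raise FormatError(f"{path}: unreadable volume ({exc})") from exc
    if img.GetDimension() != 3:
        raise FormatError(f"{path}: expected a 3D volume, got {img.GetDimension()}D")
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(float)
    return VolumeImage(_geometry_from_sitk(img), values)


def write_volume(volume: VolumeImage, path) -> None:
    path = Path(path)
    _check_volume_path(path)
    sitk.WriteImage(_sitk_from_array(volume.values, volume.geometry), str(path))


def read_mask(path, label_names: Mapping[int, str] | None = None) -> RegionMask:
    """Read an integer label volume; ``label_names`` may be supplied or is
    loaded from a ``<path>.labels.json`` sidecar when present."""
    path = Path(path)
    vol = read_volume(path)
    labels = np.rint(vol.values).astype(np.int32)
    if label_names is None:
        sidecar = path.with_name(path.name.split(".")[0] + ".labels.json")
        if sidecar.exists():
            label_names = {
                int(k): v for k, v in json.loads(sidecar.read_text()).items()
            }
        else:
            label_names = {int(l): f"label_{int(l)}" for l in np.unique(labels) if l}
    return RegionMask(vol.geometry, labels, dict(label_names))


def write_mask(mask: RegionMask, path, sidecar: bool = True) -> None:
    path = Path(path)
    _check_volume_path(path)
    img = _sitk_from_array(mask.labels.astype(np.int32), mask.geometry)
    img = sitk.Cast(img, sitk.sitkInt32)
    sitk.WriteImage(img, str(path))
    if sidecar:
        side = path.with_name(path.name.split(".")[0] + ".labels.json")
        side.write_text(json.dumps({str(k): v for k, v in mask.label_names.items()}))


# ---------------------------------------------------------------------------
# Meshes


def extract_isosurface(mask: RegionMask, label: int) -> SurfaceMesh:
    """Closed triangle mesh of a label's boundary, vertices in world mm.

    Marching cubes runs on the zero-padded binary volume so regions that
    touch the grid boundary still produce watertight surfaces.
    """
    binary = mask.binary(label)
    if not binary.any():
        raise EmptyRegionError(
            f"label {label} ({mask.label_names.get(label, '?')}) is empty"
        )
    padded = np.pad(binary.astype(np.uint8), 1)
    verts, faces, _, _ = _measure.marching_cubes(
        padded, level=0.5, spacing=tuple(mask.geometry.spacing)
    )
    # undo the one-voxel pad, then move to world coordinates
    verts = verts - np.asarray(mask.geometry.spacing)
    verts = verts + np.asarray(mask.geometry.origin)
    return SurfaceMesh(verts, faces)


def mesh_volume(mesh: SurfaceMesh) -> float:
    """Enclosed volume (mm^3) of a closed mesh via the signed-tetrahedron sum."""
    tri = mesh.triangles()
    return float(abs(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum()) / 6.0)


_MESH_SUFFIXES = (".ply", ".stl")


def read_mesh(path) -> SurfaceMesh:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    if path.suffix.lower() not in _MESH_SUFFIXES:
        raise FormatError(f"{path}: unsupported mesh format (expected PLY or STL)")
    tm = trimesh.load_mesh(str(path), process=False)
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def write_mesh(mesh: SurfaceMesh, path) -> None:
    path = Path(path)
    if path.suffix.lower() not in _MESH_SUFFIXES:
        raise FormatError(f"{path}: unsupported mesh format (expected PLY or STL)")
    mesh.to_trimesh().export(str(path))


# ---------------------------------------------------------------------------
# Contour stacks (expert-style per-slice closed polygons)


def rasterize_contour_stack(path_or_dict, geometry: VolumeGeometry) -> RegionMask:
    """Rasterize per-slice closed polygons into a label mask.

    The input is a JSON document (path or already-parsed dict) of the form::

        {"regions": [{"name": "level_1B_left", "label": 1,
                      "slices": [{"z_mm": 12.5,
                                  "polygons": [[[x_mm, y_mm], ...], ...]}]}]}

    Polygon vertices are world mm; each polygon is filled on the axial
    slice nearest ``z_mm``.
    """
    if isinstance(path_or_dict, (str, Path)):
        doc = json.loads(Path(path_or_dict).read_text())
    else:
        doc = path_or_dict
    labels = np.zeros(geometry.dims, dtype=np.int32)
    names: dict[int, str] = {}
    for region in doc["regions"]:
        lab = int(region["label"])
        names[lab] = str(region["name"])
        for sl in region["slices"]:
            k = int(round((float(sl["z_mm"]) - geometry.origin[2]) / geometry.spacing[2]))
            if not 0 <= k < geometry.dims[2]:
                continue
            for poly in sl["polygons"]:
                pts = np.asarray(poly, dtype=float)
                ij = (pts - np.asarray(geometry.origin[:2])) / np.asarray(
                    geometry.spacing[:2]
                )
                rr, cc = _draw.polygon(
                    ij[:, 0], ij[:, 1], shape=geometry.dims[:2]
                )
                labels[rr, cc, k] = lab
    return RegionMask(geometry, labels, names)
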