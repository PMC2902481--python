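"""Geometric similarity between subjects and reference ranking.

Two subjects' head-and-neck anatomy is compared through a feature vector
of structure geometry: overall body volume and extents, surface meshes
of the mandible and outer body contour, the 3D mandible-hyoid centroid
offset, 2D hyoid-vessel and hyoid-spine offsets on the axial slice at
the hyoid centroid, normalized centroid locations, and vertical
skull-base/mandible/hyoid distances.  The distance between two feature
vectors is the weighted Euclidean form

    D_F = sqrt( sum_i  w_i * d_i^2 )

where scalar features contribute absolute differences, vector features
Euclidean norms, and mesh features the directional Hausdorff distance
after ICP pre-alignment.  References sorted by ascending D_F give the
feature-space ranking R_F.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .meshdist import closest_on_mesh, point_to_mesh_distance, sample_surface_points
from .segmentation import StructureSet
from .spatial import RegionMask, SurfaceMesh, extract_isosurface, voxel_to_world

__all__ = [
    "IcpResult",
    "DegenerateSourceError",
    "FeatureVector",
    "FeatureWeights",
    "ReferenceRecord",
    "RankedReferences",
    "icp_align",
    "hausdorff_mesh_distance",
    "extract_features",
    "feature_distance",
    "rank_references",
    "point_to_mesh_distance",
]


class DegenerateSourceError(ValueError):
    """ICP source points are collinear or otherwise rank-deficient."""


@dataclass
class IcpResult:
    """Rigid alignment ``x -> R x + t`` with the per-iteration RMS residual trace."""

    rotation: np.ndarray
    translation: np.ndarray
    residuals: list[float]

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m


def _kabsch(source: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform mapping source onto target."""
    sc, tc = source.mean(axis=0), target.mean(axis=0)
    H = (source - sc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, tc - R @ sc


def icp_align(
    source_points: np.ndarray,
    target_mesh: SurfaceMesh,
    max_iterations: int = 50,
    tolerance: float = 1e-8,
    max_points: int = 2000,
    seed: int = 0,
) -> IcpResult:
    """Iterative Closest Point rigid alignment of points onto a mesh.

    Alternates exact closest-point correspondence with the closed-form
    (Kabsch) rigid update; the summed squared point-to-mesh residual is
    non-increasing across iterations.  Source sets larger than
    ``max_points`` are randomly subsampled (deterministic given ``seed``)
    — six rigid parameters never need tens of thousands of
    correspondences.  Raises :class:`DegenerateSourceError` for < 3 or
    collinear source points.
    """
    source_points = np.atleast_2d(np.asarray(source_points, float))
    if len(source_points) < 3:
        raise DegenerateSourceError("ICP needs at least 3 source points")
    if len(source_points) > max_points:
        rng = np.random.default_rng(seed)
        source_points = source_points[
            rng.choice(len(source_points), max_points, replace=False)
        ]
    centered = source_points - source_points.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 2:
        raise DegenerateSourceError("ICP source points are collinear")
    R = np.eye(3)
    t = np.zeros(3)
    residuals: list[float] = []
    prev = np.inf
    for _ in range(max_iterations):
        moved = source_points @ R.T + t
        dist, closest = closest_on_mesh(moved, target_mesh)
        rms = float(np.sqrt((dist**2).mean()))
        residuals.append(rms)
        if prev - rms < tolerance:
            break
        prev = rms
        R, t = _kabsch(source_points, closest)
    return IcpResult(R, t, residuals)


def hausdorff_mesh_distance(
    S_R: SurfaceMesh,
    S_T: SurfaceMesh,
    prealign: bool = False,
    n_samples: int = 5000,
    seed: int = 0,
    symmetric: bool = False,
) -> tuple[float, float]:
    """Directional (reference-to-target) Hausdorff and mean surface distance, mm.

    ``n_samples`` area-uniform points are drawn on ``S_R`` (after optional
    ICP pre-alignment of its vertices onto ``S_T``); the Hausdorff value
    is the maximum and the mean the average of their exact distances to
    ``S_T``.  With ``symmetric=True`` both directions are computed and
    the per-statistic maxima returned.
    """
    if S_R.n_faces == 0 or S_T.n_faces == 0:
        raise ValueError("hausdorff_mesh_distance requires non-empty meshes")

    def directed(a: SurfaceMesh, b: SurfaceMesh) -> tuple[float, float]:
        mesh = a
        if prealign:
            icp = icp_align(a.vertices, b)
            mesh = a.transformed(icp.rotation, icp.translation)
        pts = sample_surface_points(mesh, n_samples, seed=seed)
        dist, _ = closest_on_mesh(pts, b)
        return float(dist.max()), float(dist.mean())

    h, m = directed(S_R, S_T)
    if symmetric:
        h2, m2 = directed(S_T, S_R)
        return max(h, h2), max(m, m2)
    return h, m


# ---------------------------------------------------------------------------
# Feature vectors


@dataclass
class FeatureVector:
    """Per-subject geometric descriptors entering the weighted distance.

    Units: volumes cm^3, lengths/offsets mm, normalized centroids
    dimensionless in [0, 1]^3.
    """

    body_volume_cm3: float
    extents_mm: np.ndarray                    # (3,) body bounding-box size
    mandible_mesh: SurfaceMesh
    body_mesh: SurfaceMesh
    mandible_hyoid_offset_mm: np.ndarray      # (3,)
    hyoid_jugular_offset_2d_mm: np.ndarray    # (2,) axial slice at hyoid centroid
    hyoid_spine_offset_2d_mm: np.ndarray      # (2,)
    hyoid_norm: np.ndarray                    # (3,) in [0,1]^3
    mandible_norm: np.ndarray                 # (3,)
    vertical_distances_mm: np.ndarray         # (2,) skull-base->mandible, mandible->hyoid

    def __post_init__(self) -> None:
        for name in ("hyoid_norm", "mandible_norm"):
            v = np.asarray(getattr(self, name), float)
            if np.any(v < -1e-6) or np.any(v > 1 + 1e-6):
                raise ValueError(f"{name} must lie in [0,1]^3, got {v}")
            setattr(self, name, v)
        if np.any(np.asarray(self.extents_mm) <= 0):
            raise ValueError("extents must be positive")


@dataclass(frozen=True)
class FeatureWeights:
    """Per-feature-group weights, each in [0.1, 10].

    Defaults interpolate the heavy-to-light priority: hyoid-location
    features, then the mandible mesh, then vertical distances, then the
    outer contour and volume, then the rest.
    """

    hyoid_location: float = 10.0
    mandible_mesh: float = 5.0
    vertical: float = 2.0
    body: float = 0.5
    other: float = 0.1

    def __post_init__(self) -> None:
        vals = [self.hyoid_location, self.mandible_mesh, self.vertical, self.body, self.other]
        if any(not 0.1 <= v <= 10.0 for v in vals):
            raise ValueError(f"weights must lie in [0.1, 10], got {vals}")


@dataclass
class ReferenceRecord:
    """One database entry: a subject id, its feature vector, optional payload."""

    ref_id: str
    features: FeatureVector
    payload: Any = None


@dataclass
class RankedReferences:
    """References ordered by ascending feature distance D_F."""

    query_id: str
    ranking: list[tuple[str, float]]

    def ids(self) -> list[str]:
        return [r[0] for r in self.ranking]

    def top(self) -> str:
        return self.ranking[0][0]


_REQUIRED = ("mandible", "hyoid", "spine")


def _combined_centroid(masks: RegionMask, match: str) -> np.ndarray:
    labs = [l for l, n in masks.label_names.items() if match in n]
    if not labs:
        raise ValueError(f"missing required structure {match!r}")
    sel = np.isin(masks.labels, labs)
    idx = np.argwhere(sel)
    return voxel_to_world(idx.mean(axis=0), masks.geometry)


def _slice_centroid_2d(masks: RegionMask, match: str, k: int) -> np.ndarray:
    """XY world centroid of matching labels on axial slice k (falls back to 3D)."""
    labs = [l for l, n in masks.label_names.items() if match in n]
    sel = np.isin(masks.labels[:, :, k], labs)
    if sel.any():
        ij = np.argwhere(sel).mean(axis=0)
        g = masks.geometry
        return np.array([g.origin[0] + ij[0] * g.spacing[0], g.origin[1] + ij[1] * g.spacing[1]])
    return _combined_centroid(masks, match)[:2]


def extract_features(structures: StructureSet, body: RegionMask) -> FeatureVector:
    """Build the geometric feature vector from segmented structures.

    Requires mandible, hyoid, spine and at least one jugular structure in
    ``structures`` and a non-empty body mask; a missing structure raises
    a ``ValueError`` naming it.
    """
    masks = structures.masks
    names = set(masks.label_names.values())
    for req in _REQUIRED:
        if req not in names:
            raise ValueError(f"missing required structure {req!r}")
    if not any("jugular" in n for n in names):
        raise ValueError("missing required structure 'jugular'")
    body_vox = np.argwhere(body.labels > 0)
    if body_vox.size == 0:
        raise ValueError("missing required structure 'body'")

    geom = body.geometry
    spacing = np.asarray(geom.spacing)
    bb_min = voxel_to_world(body_vox.min(axis=0), geom) - spacing / 2
    bb_max = voxel_to_world(body_vox.max(axis=0), geom) + spacing / 2
    extents = bb_max - bb_min
    body_volume_cm3 = len(body_vox) * float(np.prod(spacing)) / 1000.0

    mandible_c = masks.centroid_mm(masks.label_of("mandible"))
    hyoid_c = masks.centroid_mm(masks.label_of("hyoid"))
    k_hyoid = int(round((hyoid_c[2] - geom.origin[2]) / geom.spacing[2]))
    k_hyoid = int(np.clip(k_hyoid, 0, geom.dims[2] - 1))

    body_labels = [l for l in body.label_names if l] or sorted(
        set(np.unique(body.labels)) - {0}
    )
    body_mesh = extract_isosurface(
        RegionMask(geom, (body.labels > 0).astype(np.int32), {1: "body"}), 1
    )
    mandible_mesh = structures.meshes.get("mandible") or extract_isosurface(
        masks, masks.label_of("mandible")
    )

    def norm(c: np.ndarray) -> np.ndarray:
        return np.clip((c - bb_min) / extents, 0.0, 1.0)

    return FeatureVector(
        body_volume_cm3=body_volume_cm3,
        extents_mm=extents,
        mandible_mesh=mandible_mesh,
        body_mesh=body_mesh,
        mandible_hyoid_offset_mm=mandible_c - hyoid_c,
        hyoid_jugular_offset_2d_mm=hyoid_c[:2] - _slice_centroid_2d(masks, "jugular", k_hyoid),
        hyoid_spine_offset_2d_mm=hyoid_c[:2] - _slice_centroid_2d(masks, "spine", k_hyoid),
        hyoid_norm=norm(hyoid_c),
        mandible_norm=norm(mandible_c),
        # the superior body-extent plane stands in for the skull base
        vertical_distances_mm=np.array(
            [bb_max[2] - mandible_c[2], mandible_c[2] - hyoid_c[2]]
        ),
    )


def feature_distance(
    F_d: FeatureVector,
    F_Q: FeatureVector,
    w: FeatureWeights | None = None,
    mesh_samples: int = 1500,
    seed: int = 0,
) -> float:
    """Weighted Euclidean distance ``D_F = sqrt(sum_i w_i d_i^2)``.

    Scalar features use absolute differences, vector features Euclidean
    norms, and the two mesh features the directional Hausdorff distance
    after ICP pre-alignment (making those two terms directional; the
    remaining terms are symmetric in the arguments).
    """
    w = w or FeatureWeights()
    terms: list[tuple[float, float]] = [
        (w.body, abs(F_d.body_volume_cm3 - F_Q.body_volume_cm3)),
        (w.body, float(np.linalg.norm(np.asarray(F_d.extents_mm) - np.asarray(F_Q.extents_mm)))),
        (w.hyoid_location, float(np.linalg.norm(F_d.mandible_hyoid_offset_mm - F_Q.mandible_hyoid_offset_mm))),
        (w.hyoid_location, float(np.linalg.norm(F_d.hyoid_jugular_offset_2d_mm - F_Q.hyoid_jugular_offset_2d_mm))),
        (w.hyoid_location, float(np.linalg.norm(F_d.hyoid_spine_offset_2d_mm - F_Q.hyoid_spine_offset_2d_mm))),
        (w.hyoid_location, float(np.linalg.norm(F_d.hyoid_norm - F_Q.hyoid_norm))),
        (w.other, float(np.linalg.norm(F_d.mandible_norm - F_Q.mandible_norm))),
        (w.vertical, float(np.linalg.norm(F_d.vertical_distances_mm - F_Q.vertical_distances_mm))),
    ]
    for weight, mesh_a, mesh_b in (
        (w.mandible_mesh, F_d.mandible_mesh, F_Q.mandible_mesh),
        (w.body, F_d.body_mesh, F_Q.body_mesh),
    ):
        d_h, _ = hausdorff_mesh_distance(
            mesh_a, mesh_b, prealign=True, n_samples=mesh_samples, seed=seed
        )
        terms.append((weight, d_h))
    return float(np.sqrt(sum(wi * di * di for wi, di in terms)))


def rank_references(
    query: FeatureVector,
    db: Sequence[ReferenceRecord],
    w: FeatureWeights | None = None,
    query_id: str = "query",
    mesh_samples: int = 1500,
    seed: int = 0,
) -> RankedReferences:
    """Rank database references by ascending D_F (stable under ties)."""
    if not db:
        raise ValueError("reference database is empty")
    dists = [
        (rec.ref_id, feature_distance(rec.features, query, w, mesh_samples, seed))
        for rec in db
    ]
    order = sorted(range(len(dists)), key=lambda i: (dists[i][1], i))
    return RankedReferences(query_id, [dists[i] for i in order])
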