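"""Knowledge-based landmark-structure segmentation.

Structures are found progressively, in descending order of detection
reliability.  For each structure a rule encodes domain knowledge: an
intensity window, a 2D size window, negative shape constraints (caps on
elongation and concavity that rule out infeasible candidates), and an
optional location prior expressed relative to a previously found
structure.  Per axial slice, a coarse-to-fine threshold sweep inside the
intensity window keeps the first connected component satisfying all
constraints — a deliberately sub-optimal threshold is fine because the
2D hits only seed a 3D active-contour growth that builds the volume.
Partial growth is acceptable: the structures serve as landmarks, not as
clinical segmentations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as _ndimage
from skimage import measure as _measure
from skimage import segmentation as _segmentation

from .spatial import EmptyRegionError, RegionMask, SurfaceMesh, VolumeImage, extract_isosurface

__all__ = [
    "StructureRule",
    "StructureSet",
    "SeedingError",
    "default_rules",
    "dynamic_threshold_slice",
    "active_contour_3d",
    "progressive_segment",
]

logger = logging.getLogger(__name__)


class SeedingError(ValueError):
    """Active contouring was started without any seed voxels."""


@dataclass(frozen=True)
class LocationPrior:
    """Search box relative to a previously found structure's centroid (mm)."""

    reference: str
    offset_mm: tuple[float, float, float]
    half_extent_mm: tuple[float, float, float]


@dataclass(frozen=True)
class StructureRule:
    """Detection rule for one landmark structure.

    ``max_elongation`` caps the ratio of the major to minor second-moment
    axis of a 2D candidate; ``min_solidity`` rejects strongly concave
    candidates; both are the negative shape constraints.  ``slab_mm``
    optionally restricts the active contour to a range of axial world-z.
    """

    name: str
    intensity_window: tuple[float, float]
    size_window_mm2: tuple[float, float]
    max_elongation: float = 4.0
    min_solidity: float = 0.6
    location_prior: LocationPrior | None = None
    reliability_rank: int = 0
    slab_mm: tuple[float, float] | None = None
    # keep only the largest 3D connected component of the grown region —
    # thresholding may seed fringe slices of other same-intensity structures
    keep_largest_component: bool = True
    # active-contour controls
    iterations: int = 12
    balloon: float = 1.0
    smoothing: int = 1

    def __post_init__(self) -> None:
        lo, hi = self.intensity_window
        if not lo < hi:
            raise ValueError(f"{self.name}: intensity window must satisfy low < high")
        lo, hi = self.size_window_mm2
        if not lo < hi:
            raise ValueError(f"{self.name}: size window must satisfy min < max")


@dataclass
class StructureSet:
    """Segmented landmark structures: label mask plus per-structure mesh."""

    masks: RegionMask
    meshes: dict[str, SurfaceMesh] = field(default_factory=dict)

    def names(self) -> list[str]:
        return [self.masks.label_names[l] for l in sorted(self.masks.label_names)]

    def binary(self, name: str) -> np.ndarray:
        return self.masks.binary(self.masks.label_of(name))


@dataclass(frozen=True)
class Candidate2D:
    """A 2D connected component that satisfied a rule's constraints."""

    slice_index: int
    mask: np.ndarray        # 2D boolean, full slice shape
    area_mm2: float
    centroid_mm: tuple[float, float]


def _region_ok(
    region, rule: StructureRule, pixel_area: float, geometry, k: int,
    context: dict[str, np.ndarray],
) -> bool:
    area = region.area * pixel_area
    if not rule.size_window_mm2[0] <= area <= rule.size_window_mm2[1]:
        return False
    # negative shape constraints
    minor = max(region.axis_minor_length, 1e-6)
    if region.axis_major_length / minor > rule.max_elongation:
        return False
    if region.solidity < rule.min_solidity:
        return False
    if rule.location_prior is not None:
        prior = rule.location_prior
        ref_centroid = context[prior.reference]
        cy, cx = region.centroid  # skimage returns (row=i, col=j)
        world = np.array([
            geometry.origin[0] + cy * geometry.spacing[0],
            geometry.origin[1] + cx * geometry.spacing[1],
            geometry.origin[2] + k * geometry.spacing[2],
        ])
        target = ref_centroid + np.asarray(prior.offset_mm)
        if np.any(np.abs(world - target) > np.asarray(prior.half_extent_mm)):
            return False
    return True


def dynamic_threshold_slice(
    slice_values: np.ndarray,
    rule: StructureRule,
    geometry,
    slice_index: int,
    context: dict[str, np.ndarray] | None = None,
    n_thresholds: int = 8,
) -> list[Candidate2D]:
    """Constraint-based dynamic thresholding of one axial slice.

    Sweeps ``n_thresholds`` evenly spaced thresholds through the rule's
    intensity window (high to low, coarse to fine) and returns the
    connected components of the first threshold at which at least one
    component passes the size, shape, and location constraints.  An empty
    list is a valid outcome — not every slice shows every structure.
    """
    context = context or {}
    if rule.location_prior is not None and rule.location_prior.reference not in context:
        raise ValueError(
            f"{rule.name}: location prior references {rule.location_prior.reference!r} "
            "which is not in the context"
        )
    pixel_area = geometry.spacing[0] * geometry.spacing[1]
    lo, hi = rule.intensity_window
    thresholds = np.linspace(hi, lo, n_thresholds, endpoint=False)
    for thr in thresholds:
        binary = (slice_values >= thr) & (slice_values <= hi)
        if not binary.any():
            continue
        labeled = _measure.label(binary, connectivity=1)
        hits: list[Candidate2D] = []
        for region in _measure.regionprops(labeled):
            if _region_ok(region, rule, pixel_area, geometry, slice_index, context):
                mask = labeled == region.label
                cy, cx = region.centroid
                hits.append(
                    Candidate2D(
                        slice_index,
                        mask,
                        region.area * pixel_area,
                        (
                            geometry.origin[0] + cy * geometry.spacing[0],
                            geometry.origin[1] + cx * geometry.spacing[1],
                        ),
                    )
                )
        if hits:
            return hits
    return []


def active_contour_3d(
    volume: VolumeImage,
    seeds: np.ndarray,
    rule: StructureRule | None = None,
    iterations: int | None = None,
) -> np.ndarray:
    """Grow a 3D region from seed voxels with a morphological active contour.

    A morphological geodesic active contour (inverse-gradient speed image,
    positive balloon force) evolves the seed volume; the result is always
    a superset of the seed, and zero iterations return the seed exactly.
    When the rule specifies an axial slab of interest the evolution is
    confined to it (mirroring the "only the sections near the landmark
    matter" simplification).
    """
    seeds = np.asarray(seeds, bool)
    if not seeds.any():
        raise SeedingError("active contour requires a non-empty seed")
    rule = rule or StructureRule("anon", (0.0, 1.0), (0.0, 1.0))
    n_iter = rule.iterations if iterations is None else int(iterations)
    if n_iter == 0:
        return seeds.copy()
    values = volume.values
    lo, hi = rule.intensity_window
    gimage = _segmentation.inverse_gaussian_gradient(
        np.clip((values - lo) / max(hi - lo, 1e-9), -1.0, 2.0), alpha=100.0, sigma=1.0
    )
    grown = _segmentation.morphological_geodesic_active_contour(
        gimage,
        num_iter=n_iter,
        init_level_set=seeds.astype(np.int8),
        smoothing=rule.smoothing,
        balloon=rule.balloon,
        threshold=0.5,
    ).astype(bool)
    if rule.slab_mm is not None:
        z = volume.geometry.origin[2] + np.arange(volume.geometry.dims[2]) * volume.geometry.spacing[2]
        outside = (z < rule.slab_mm[0]) | (z > rule.slab_mm[1])
        grown[:, :, outside] = False
    return grown | seeds


def _rank_order(rules: Sequence[StructureRule]) -> list[StructureRule]:
    ordered = sorted(rules, key=lambda r: r.reliability_rank)
    seen: set[str] = set()
    for rule in ordered:
        if rule.location_prior is not None and rule.location_prior.reference not in seen:
            raise ValueError(
                f"rule {rule.name!r} depends on {rule.location_prior.reference!r} "
                "which has equal/higher reliability rank (dependency must come first)"
            )
        seen.add(rule.name)
    return ordered


def progressive_segment(volume: VolumeImage, rules: Sequence[StructureRule]) -> StructureSet:
    """Segment all structures in order of detection reliability.

    Each rule thresholds all axial slices, seeds the 3D active contour
    with the 2D hits, and records the grown mask plus its surface mesh.
    Later rules may consult earlier results through their location prior;
    a rule whose dependency was not detected is skipped with a warning.
    """
    geom = volume.geometry
    labels = np.zeros(geom.dims, dtype=np.int32)
    names: dict[int, str] = {}
    meshes: dict[str, SurfaceMesh] = {}
    context: dict[str, np.ndarray] = {}
    next_label = 1
    for rule in _rank_order(rules):
        if rule.location_prior is not None and rule.location_prior.reference not in context:
            logger.warning(
                "skipping %s: prerequisite %s was not detected",
                rule.name, rule.location_prior.reference,
            )
            continue
        seeds = np.zeros(geom.dims, dtype=bool)
        for k in range(geom.dims[2]):
            if rule.slab_mm is not None:
                z = geom.origin[2] + k * geom.spacing[2]
                if not rule.slab_mm[0] <= z <= rule.slab_mm[1]:
                    continue
            for cand in dynamic_threshold_slice(
                volume.values[:, :, k], rule, geom, k, context
            ):
                seeds[:, :, k] |= cand.mask
        if not seeds.any():
            logger.warning("no 2D seeds found for %s", rule.name)
            continue
        grown = active_contour_3d(volume, seeds, rule)
        if rule.keep_largest_component:
            comp, n_comp = _ndimage.label(grown)
            if n_comp > 1:
                sizes = _ndimage.sum_labels(grown, comp, range(1, n_comp + 1))
                grown = comp == (1 + int(np.argmax(sizes)))
        claim = grown & (labels == 0)
        if not claim.any():
            logger.warning("%s: grown region fully overlaps earlier structures", rule.name)
            continue
        labels[claim] = next_label
        names[next_label] = rule.name
        mask = RegionMask(geom, labels, dict(names))
        context[rule.name] = mask.centroid_mm(next_label)
        meshes[rule.name] = extract_isosurface(mask, next_label)
        next_label += 1
    return StructureSet(RegionMask(geom, labels, names), meshes)


def default_rules() -> list[StructureRule]:
    """Rules matched to the default synthetic phantom.

    The intensity/size/shape numbers are configuration for the phantom's
    CT-like intensities, ordered by how reliably each structure is
    detected: big bright spine first, then mandible, then the small hyoid
    (guided by the mandible), then the contrast vessels lateral to it.
    """
    return [
        StructureRule(
            "spine", intensity_window=(400.0, 1200.0), size_window_mm2=(80.0, 1500.0),
            max_elongation=2.5, reliability_rank=0, balloon=0.0, iterations=4,
        ),
        StructureRule(
            "mandible", intensity_window=(400.0, 1200.0), size_window_mm2=(300.0, 4000.0),
            max_elongation=4.0, reliability_rank=1, balloon=0.0, iterations=4,
            location_prior=LocationPrior("spine", (0.0, 60.0, 45.0), (60.0, 60.0, 60.0)),
        ),
        StructureRule(
            "hyoid", intensity_window=(400.0, 1200.0), size_window_mm2=(30.0, 290.0),
            max_elongation=3.5, reliability_rank=2, balloon=0.0, iterations=2,
            location_prior=LocationPrior("mandible", (0.0, 5.0, -40.0), (30.0, 30.0, 40.0)),
        ),
        StructureRule(
            "jugular_left", intensity_window=(120.0, 320.0), size_window_mm2=(30.0, 300.0),
            max_elongation=1.8, min_solidity=0.8, reliability_rank=3, balloon=0.0, iterations=2,
            location_prior=LocationPrior("hyoid", (-45.0, -25.0, 0.0), (25.0, 30.0, 90.0)),
        ),
        StructureRule(
            "jugular_right", intensity_window=(120.0, 320.0), size_window_mm2=(30.0, 300.0),
            max_elongation=1.8, min_solidity=0.8, reliability_rank=4, balloon=0.0, iterations=2,
            location_prior=LocationPrior("hyoid", (45.0, -25.0, 0.0), (25.0, 30.0, 90.0)),
        ),
    ]
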