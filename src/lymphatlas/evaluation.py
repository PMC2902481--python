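"""Quantitative evaluation: Dice overlap, surface distances, ranking agreement.

Projected regions are compared with expert (ground-truth) regions by the
Dice similarity coefficient

    DSC = 2 |V_T ∩ V_C| / (|V_T| + |V_C|)

on voxel counts, and by directional Hausdorff / mean surface distance
between their boundary meshes, reported in centimetres.  Evaluation
distances use *no* ICP pre-alignment: projected and truth regions
already share the target frame, and pre-aligning would hide exactly the
registration error being measured (the retrieval-side mesh distance, by
contrast, does pre-align).

Ranking agreement compares the feature-space ranking R_F against the
registration-outcome ranking R_I (ascending Hausdorff distance of the
projected region): for each target, in which position x of R_I does
R_F's top reference land, binned x = 1, 2, 3, > 3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _stats

from .retrieval import hausdorff_mesh_distance
from .spatial import EmptyRegionError, RegionMask, extract_isosurface

__all__ = [
    "EvaluationReport",
    "dice",
    "region_surface_distances",
    "build_ranking_RI",
    "rank_agreement",
    "distance_correlation",
]

MM_PER_CM = 10.0


@dataclass
class EvaluationReport:
    """Cohort-level evaluation summary."""

    per_region: dict[str, dict[str, float]]      # region -> {dsc, hausdorff_cm, mean_cm}
    dsc_mean: float
    dsc_sd: float
    hausdorff_cm_mean: float
    hausdorff_cm_sd: float
    mean_cm_mean: float
    mean_cm_sd: float
    rank_match_probabilities: dict[str, float] | None = None
    correlation: float | None = None


def _check_same_geometry(a: RegionMask, b: RegionMask) -> None:
    ga, gb = a.geometry, b.geometry
    if (
        ga.dims != gb.dims
        or not np.allclose(ga.spacing, gb.spacing)
        or not np.allclose(ga.origin, gb.origin)
    ):
        raise ValueError("masks must share the same geometry")


def dice(V_T: RegionMask, V_C: RegionMask, label: int = None) -> float:  # type: ignore[assignment]
    """Dice similarity coefficient of one label (or of all foreground).

    Two empty masks agree on absence and score 1.0 by convention (the
    ratio is otherwise 0/0).
    """
    _check_same_geometry(V_T, V_C)
    if label is None:
        a = V_T.labels > 0
        b = V_C.labels > 0
    else:
        a = V_T.labels == label
        b = V_C.labels == label
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def region_surface_distances(
    projected: RegionMask,
    truth: RegionMask,
    label: int,
    n_samples: int = 5000,
    seed: int = 0,
) -> tuple[float, float]:
    """Directional Hausdorff and mean surface distance in cm.

    Meshes both labels' boundaries and measures projected -> truth with
    no pre-alignment (both live in the target frame).
    """
    mesh_p = extract_isosurface(projected, label)
    mesh_t = extract_isosurface(truth, label)
    h, m = hausdorff_mesh_distance(
        mesh_p, mesh_t, prealign=False, n_samples=n_samples, seed=seed
    )
    return h / MM_PER_CM, m / MM_PER_CM


def build_ranking_RI(
    distances: Mapping[str, float],
) -> list[tuple[str, float]]:
    """Registration-outcome ranking: references by ascending Hausdorff distance.

    ``distances`` maps reference id to the Hausdorff distance of its
    projected region against the target's ground truth.  Ties keep the
    lexicographic input order (stable).
    """
    if not distances:
        raise ValueError("no registration distances provided")
    items = list(distances.items())
    order = sorted(range(len(items)), key=lambda i: (items[i][1], i))
    return [items[i] for i in order]


def rank_agreement(
    R_F: Mapping[str, Sequence[str]],
    R_I: Mapping[str, Sequence[str]],
) -> dict[str, float]:
    """Empirical distribution of R_F's top-1 position within R_I.

    Both arguments map a case key (target, or target/region pair) to an
    ordered reference-id list over the same reference set.  Returns the
    frequencies of the position x of ``R_F[case][0]`` inside ``R_I[case]``
    binned as ``{"1": p1, "2": p2, "3": p3, ">3": p_rest}``; the bins sum
    to 1.
    """
    if set(R_F) != set(R_I):
        raise ValueError("R_F and R_I must cover the same cases")
    if not R_F:
        raise ValueError("no cases to compare")
    counts = {"1": 0, "2": 0, "3": 0, ">3": 0}
    for case, rf in R_F.items():
        ri = list(R_I[case])
        if set(ri) != set(rf):
            raise ValueError(f"case {case!r}: reference sets differ")
        pos = ri.index(rf[0]) + 1
        counts[str(pos) if pos <= 3 else ">3"] += 1
    n = len(R_F)
    return {k: v / n for k, v in counts.items()}


def distance_correlation(
    pairs: Sequence[tuple[float, float]], method: str = "pearson"
) -> float:
    """Correlation of (D_F, D_H) pairs; Pearson by default, Spearman optional."""
    arr = np.asarray(pairs, float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 3:
        raise ValueError("need at least 3 (D_F, D_H) pairs")
    if np.ptp(arr[:, 0]) == 0 or np.ptp(arr[:, 1]) == 0:
        raise ValueError("correlation undefined: a coordinate is constant")
    if method == "pearson":
        return float(_stats.pearsonr(arr[:, 0], arr[:, 1]).statistic)
    if method == "spearman":
        return float(_stats.spearmanr(arr[:, 0], arr[:, 1]).statistic)
    raise ValueError(f"unknown method {method!r}")
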