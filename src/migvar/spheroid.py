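"""3D spheroid invasion quantification.

The spheroid core is the unique sphere through four manually annotated
surface points; each nucleus's migration distance is its signed radial
distance to that sphere (negative inside the core). Detection quality of
a 3D nucleus segmentation is scored against an annotation by one-to-one
distance-bounded matching: precision = TP / #segmented,
recall = TP / #annotated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GeometryError",
    "circumsphere",
    "migration_distance",
    "match_precision_recall",
    "border_filter",
    "scene_distances",
]


class GeometryError(ValueError):
    """Degenerate point configuration (coplanar or coincident points)."""


def circumsphere(p1, p2, p3, p4, cond_threshold: float = 1e10):
    """Centre and radius of the unique sphere through four points.

    Solved from the pairwise-equidistance linear system
    2*(p_i - p_1) . c = |p_i|^2 - |p_1|^2. Raises
    :class:`GeometryError` when the points are (near-)coplanar.
    """
    pts = np.asarray([p1, p2, p3, p4], dtype=float)
    if pts.shape != (4, 3):
        raise ValueError("four 3D points are required")
    A = 2.0 * (pts[1:] - pts[0])
    b = np.sum(pts[1:] ** 2, axis=1) - np.sum(pts[0] ** 2)
    scale = float(np.abs(A).max()) or 1.0
    if np.linalg.cond(A / scale) > cond_threshold:
        raise GeometryError("the four points are coplanar or degenerate")
    center = np.linalg.solve(A, b)
    radius = float(np.linalg.norm(pts[0] - center))
    return center, radius


def migration_distance(
    nuclei, center, radius: float, clamp_inside: bool = False
) -> np.ndarray:
    """Signed distance of nucleus centroids to the core sphere (um).

    d = ||nucleus - center|| - radius; negative inside the core.
    ``clamp_inside`` floors distances at 0 for summaries that treat the
    core interior as zero invasion.
    """
    nuclei = np.atleast_2d(np.asarray(nuclei, dtype=float))
    d = np.linalg.norm(nuclei - np.asarray(center, dtype=float), axis=1) - radius
    if clamp_inside:
        d = np.maximum(d, 0.0)
    return d


def match_precision_recall(
    segmented, annotated, match_radius: float = 5.0
) -> tuple[float, float, int]:
    """Greedy one-to-one matching of detections to annotations.

    Candidate pairs within ``match_radius`` are accepted in order of
    increasing distance, each point used at most once. Returns
    (precision, recall, n_true_positive); precision is NaN (undefined)
    for an empty segmentation, recall is 0 then.
    """
    seg = np.atleast_2d(np.asarray(segmented, dtype=float)) if len(segmented) else np.empty((0, 3))
    ann = np.atleast_2d(np.asarray(annotated, dtype=float)) if len(annotated) else np.empty((0, 3))
    if len(seg) == 0:
        return float("nan"), 0.0 if len(ann) else float("nan"), 0
    if len(ann) == 0:
        return 0.0, float("nan"), 0

    d = np.linalg.norm(seg[:, None, :] - ann[None, :, :], axis=2)
    pairs = [
        (d[i, j], i, j)
        for i in range(len(seg))
        for j in range(len(ann))
        if d[i, j] <= match_radius
    ]
    pairs.sort()
    used_s, used_a = set(), set()
    tp = 0
    for _, i, j in pairs:
        if i in used_s or j in used_a:
            continue
        used_s.add(i)
        used_a.add(j)
        tp += 1
    return tp / len(seg), tp / len(ann), tp


def border_filter(centroids, lower, upper, margin: float) -> np.ndarray:
    """Drop centroids within ``margin`` of the bounding box faces.

    Stand-in for removing border-touching segments in a 3D stack.
    Returns a boolean keep-mask.
    """
    c = np.atleast_2d(np.asarray(centroids, dtype=float))
    lo = np.asarray(lower, dtype=float) + margin
    hi = np.asarray(upper, dtype=float) - margin
    return np.all((c >= lo) & (c <= hi), axis=1)


@dataclass
class SceneResult:
    center: np.ndarray
    radius: float
    distances: pd.DataFrame  # one row per nucleus


def scene_distances(scene_table: pd.DataFrame) -> SceneResult:
    """Distances for a scene CSV (role column: core_point | nucleus)."""
    pts = scene_table.loc[scene_table["role"] == "core_point", ["x", "y", "z"]].to_numpy()
    if len(pts) < 4:
        raise GeometryError("a scene needs at least four core points")
    center, radius = circumsphere(*pts[:4])
    nuclei = scene_table.loc[scene_table["role"] == "nucleus", ["x", "y", "z"]].to_numpy()
    d = migration_distance(nuclei, center, radius)
    out = pd.DataFrame(
        {"x": nuclei[:, 0], "y": nuclei[:, 1], "z": nuclei[:, 2], "migration_distance": d}
    )
    return SceneResult(center=center, radius=radius, distances=out)
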