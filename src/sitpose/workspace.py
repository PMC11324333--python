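"""Sitting-workspace geometry and the high-intense-activity rate (HIAR).

The sitting workspace is the polygon obtained by connecting the farthest
trunk center-of-mass points of the eight directional reaches, ordered by
angle about their centroid (a star polygon -- deliberately not the convex
hull, since the eight points are connected directly).  Its area summarizes
overall sitting dynamic balance.

The baseline reaching workspace is the convex polygon encompassing all
fingertip samples of the baseline test.  During training, the fraction of
time the fingertip spends outside that polygon is the high-intense-activity
rate::

    HIAR = high intense activity time / total training time

Each sample is attributed its preceding inter-sample interval; a point on
the polygon boundary (within 1e-9 m) counts as inside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Polygon

from .exceptions import ConfigurationError, DataQualityError, DegenerateGeometryError
from .preprocess import TimeSeriesPlanar
from .reach import DIRECTIONS, ReachTrial, frts

__all__ = [
    "StarPolygon",
    "HiarResult",
    "farthest_points",
    "star_polygon",
    "polygon_area",
    "convex_hull",
    "point_in_polygon",
    "hiar",
]

#: Distance (m) within which a point counts as lying on the boundary.
BOUNDARY_TOL = 1e-9


@dataclass(frozen=True)
class StarPolygon:
    """An ordered, non-self-intersecting planar polygon.

    ``vertices`` is an ``(n, 2)`` array in counterclockwise order about the
    ``centroid`` (mean of the vertices used for angular ordering).
    """

    vertices: np.ndarray
    centroid: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "centroid", np.asarray(self.centroid, dtype=float))
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise DegenerateGeometryError("a polygon needs at least 3 planar vertices")

    def to_shapely(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass(frozen=True)
class HiarResult:
    """HIAR with its numerator and denominator (seconds)."""

    hiar: float
    high_intense_time: float
    total_time: float


def farthest_points(
    trials: Iterable[ReachTrial], use: str = "com"
) -> dict[str, np.ndarray]:
    """Farthest sample of each of the eight directional reaches.

    Requires exactly one trial per direction; returns a mapping from
    direction label to the planar point of the chosen trajectory (``com`` or
    ``fingertip``) at maximum distance from its start, with ties broken by
    the earliest sample.
    """
    trials = list(trials)
    seen = [t.direction for t in trials]
    duplicates = {d for d in seen if seen.count(d) > 1}
    if duplicates:
        raise ConfigurationError(f"duplicate direction labels: {sorted(duplicates)}")
    missing = set(DIRECTIONS) - set(seen)
    if missing:
        raise ConfigurationError(f"missing directions: {sorted(missing)}")
    points: dict[str, np.ndarray] = {}
    for trial in trials:
        series = trial.com if use == "com" else trial.fingertip
        result = frts(trial, use=use)
        points[trial.direction] = series.values[result.index, :2].copy()
    return points


def star_polygon(points: Mapping[str, np.ndarray] | Sequence[np.ndarray]) -> StarPolygon:
    """Order points counterclockwise by angle about their centroid.

    Accepts the mapping produced by :func:`farthest_points` or any sequence
    of planar points.  Raises :class:`DegenerateGeometryError` when fewer
    than three distinct points remain or all points are collinear.
    """
    if isinstance(points, Mapping):
        pts = np.asarray([points[d] for d in DIRECTIONS if d in points], dtype=float)
    else:
        pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise DegenerateGeometryError("points must be planar")
    distinct = np.unique(pts, axis=0)
    if distinct.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 distinct points")
    centroid = pts.mean(axis=0)
    rel = pts - centroid
    # collinearity: rank of the centered point cloud
    if np.linalg.matrix_rank(rel, tol=1e-12) < 2:
        raise DegenerateGeometryError("points are collinear")
    angles = np.arctan2(rel[:, 1], rel[:, 0])
    order = np.lexsort((np.linalg.norm(rel, axis=1), angles))
    return StarPolygon(vertices=pts[order], centroid=centroid)


def polygon_area(poly: StarPolygon) -> float:
    """Area (m^2) of the ordered polygon (shoelace on the ordered vertices)."""
    area = poly.to_shapely().area
    if not area > 0:
        raise DegenerateGeometryError("polygon has zero area")
    return float(area)


def convex_hull(points: Sequence[np.ndarray] | np.ndarray) -> StarPolygon:
    """Convex hull of a planar point set, counterclockwise.

    Every input point lies inside or on the returned polygon.  Degenerate
    inputs (fewer than 3 points, or all collinear) raise
    :class:`DegenerateGeometryError`.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] < 2:
        raise DegenerateGeometryError("points must be planar")
    pts = pts[:, :2]
    if pts.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 points")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate point set: {exc}") from exc
    vertices = pts[hull.vertices]  # scipy returns CCW order in 2-D
    return StarPolygon(vertices=vertices, centroid=vertices.mean(axis=0))


def point_in_polygon(point: Sequence[float], poly: StarPolygon) -> str:
    """Classify a point as ``"inside"``, ``"boundary"`` or ``"outside"``.

    Points within 1e-9 m of the boundary are classified ``"boundary"``
    (and count as inside for HIAR).
    """
    shape = poly.to_shapely()
    p = shapely.Point(point[0], point[1])
    if shape.boundary.distance(p) <= BOUNDARY_TOL:
        return "boundary"
    return "inside" if shape.contains(p) else "outside"


def _outside_mask(xy: np.ndarray, poly: StarPolygon) -> np.ndarray:
    """Vectorized strict-outside classification (boundary counts as inside)."""
    shape = poly.to_shapely()
    shapely.prepare(shape)
    inside = shapely.contains_xy(shape, xy[:, 0], xy[:, 1])
    outside = ~inside
    if outside.any():
        # points exactly on (or within tolerance of) the boundary are inside
        pts = shapely.points(xy[outside])
        near = shapely.dwithin(shape.boundary, pts, BOUNDARY_TOL)
        out_idx = np.flatnonzero(outside)
        outside[out_idx[near]] = False
    return outside


def hiar(
    fingertip_training: TimeSeriesPlanar, baseline_hull: StarPolygon
) -> HiarResult:
    """High-intense-activity rate of a training trajectory.

    ``high_intense_time`` is the sum of the preceding inter-sample intervals
    of all samples classified strictly outside the baseline hull;
    ``total_time`` is the span of the timestamps.
    """
    if fingertip_training.n_samples < 2:
        raise DataQualityError("training trajectory needs at least 2 samples")
    t = fingertip_training.timestamps
    xy = fingertip_training.values[:, :2]
    outside = _outside_mask(xy, baseline_hull)
    dt = np.diff(t)
    high = float(dt[outside[1:]].sum())
    total = float(t[-1] - t[0])
    if total <= 0:
        raise DataQualityError("trajectory has zero duration")
    return HiarResult(hiar=high / total, high_intense_time=high, total_time=total)
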