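"""Scale-free 2D geometric primitives.

Image (raster) coordinate convention throughout: ``x`` grows rightward and
``y`` grows *downward*, so "superior" (toward the top of the radiograph)
means smaller ``y``.  All angles are unsigned, in degrees, in ``[0, 180]``,
as produced by the arccos of a normalized dot product.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from shapely.geometry import LineString

from .errors import CollinearityError, DegenerateGeometryError

__all__ = [
    "Point",
    "Contour",
    "angle_between",
    "circumcircle",
    "segment_contour_intersections",
    "perpendicular_direction",
]

#: relative tolerance for collinearity: twice the signed triangle area must
#: exceed this fraction of the squared bounding-box diagonal
COLLINEARITY_RTOL = 1e-9
#: relative tolerance for point-on-segment / point-on-contour tests,
#: as a fraction of the contour bounding-box diagonal
INTERSECTION_RTOL = 1e-7


class Point(NamedTuple):
    """A 2D point in pixel coordinates (x rightward, y downward)."""

    x: float
    y: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


def as_point(p: Sequence[float] | Point) -> Point:
    pt = Point(float(p[0]), float(p[1]))
    if not (np.isfinite(pt.x) and np.isfinite(pt.y)):
        raise DegenerateGeometryError(f"non-finite point coordinates: {pt}")
    return pt


@dataclass
class Contour:
    """An ordered polyline or polygon of 2D vertices.

    Parameters
    ----------
    vertices
        ``(n, 2)`` array of vertex coordinates, ``n >= 3``.
    closed
        Whether the last vertex connects back to the first.
    """

    vertices: np.ndarray
    closed: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise DegenerateGeometryError(
                f"contour vertices must be (n, 2), got shape {v.shape}"
            )
        if len(v) < 3:
            raise DegenerateGeometryError(
                f"contour needs at least 3 vertices, got {len(v)}"
            )
        if not np.isfinite(v).all():
            raise DegenerateGeometryError("contour contains non-finite vertices")
        tol = INTERSECTION_RTOL * self.bbox_diagonal(v)
        d = np.linalg.norm(np.diff(v, axis=0), axis=1)
        if (d <= tol).any():
            raise DegenerateGeometryError(
                "contour has duplicate consecutive vertices"
            )
        object.__setattr__(self, "vertices", v)

    @staticmethod
    def bbox_diagonal(v: np.ndarray) -> float:
        span = v.max(axis=0) - v.min(axis=0)
        return float(np.hypot(*span)) or 1.0

    @property
    def diagonal(self) -> float:
        return self.bbox_diagonal(self.vertices)

    def edge_array(self) -> np.ndarray:
        """Vertices with the closing vertex appended when the contour is closed."""
        if self.closed:
            return np.vstack([self.vertices, self.vertices[:1]])
        return self.vertices

    def as_linestring(self) -> LineString:
        return LineString(self.edge_array())


def _as_vec(u: Sequence[float]) -> np.ndarray:
    return np.asarray(u, dtype=float).reshape(2)


def angle_between(u: Sequence[float], v: Sequence[float]) -> float:
    """Unsigned angle between two 2-vectors, in degrees in ``[0, 180]``.

    Computed as ``arccos(u·v / (|u||v|))``; symmetric in its arguments and
    invariant under positive scaling of either.

    Raises
    ------
    DegenerateGeometryError
        If either vector has zero length.
    """
    u, v = _as_vec(u), _as_vec(v)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError("angle_between requires nonzero vectors")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def circumcircle(p1, p2, p3) -> tuple[Point, float]:
    """Center and radius of the circle through three non-collinear points.

    Solves the two perpendicular-bisector equations as a 2x2 linear system.

    Raises
    ------
    CollinearityError
        If the points are (nearly) collinear or coincident, judged by the
        scale-free criterion ``|2·area| <= 1e-9 · diag²`` where ``diag`` is
        the bounding-box diagonal of the three points.
    """
    a, b, c = (as_point(p).as_array() for p in (p1, p2, p3))
    pts = np.vstack([a, b, c])
    diag = Contour.bbox_diagonal(pts)
    twice_area = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
    if abs(twice_area) <= COLLINEARITY_RTOL * diag * diag:
        raise CollinearityError(
            f"points {tuple(a)}, {tuple(b)}, {tuple(c)} are collinear or coincident"
        )
    # perpendicular bisector conditions: |o-a|² = |o-b|² = |o-c|²
    m = 2.0 * np.array([b - a, c - a])
    rhs = np.array([b @ b - a @ a, c @ c - a @ a])
    center = np.linalg.solve(m, rhs)
    radius = float(np.linalg.norm(center - a))
    return Point(float(center[0]), float(center[1])), radius


def segment_contour_intersections(pA, pB, contour: Contour) -> list[Point]:
    """Intersections of the segment ``pA–pB`` with a contour's edges.

    Returns the intersection points ordered by distance from ``pA``
    (duplicates within tolerance merged).  An empty list means no crossing.
    """
    a, b = as_point(pA), as_point(pB)
    seg_len = np.hypot(b.x - a.x, b.y - a.y)
    if seg_len == 0.0:
        raise DegenerateGeometryError("segment has zero length")
    seg = LineString([a, b])
    inter = seg.intersection(contour.as_linestring())
    if inter.is_empty:
        return []
    if inter.geom_type == "Point":
        geoms = [inter]
    elif inter.geom_type in ("MultiPoint", "GeometryCollection"):
        geoms = [g for g in inter.geoms if g.geom_type == "Point"]
        # collinear-overlap pieces contribute their endpoints
        for g in inter.geoms:
            if g.geom_type == "LineString":
                geoms.extend(LineString(g).boundary.geoms)
    elif inter.geom_type == "LineString":
        geoms = list(inter.boundary.geoms)
    else:  # pragma: no cover - defensive
        geoms = []
    pts = sorted(
        (Point(g.x, g.y) for g in geoms),
        key=lambda p: np.hypot(p.x - a.x, p.y - a.y),
    )
    tol = INTERSECTION_RTOL * contour.diagonal
    merged: list[Point] = []
    for p in pts:
        if not merged or np.hypot(p.x - merged[-1].x, p.y - merged[-1].y) > tol:
            merged.append(p)
    return merged


def perpendicular_direction(u: Sequence[float], prefer_superior: bool = True) -> np.ndarray:
    """Unit vector perpendicular to ``u``.

    With ``prefer_superior`` the result points toward the top of the image
    (``y <= 0`` in raster convention), which is the orientation of the
    vertical reference used by the CE angle.
    """
    u = _as_vec(u)
    n = np.linalg.norm(u)
    if n == 0.0:
        raise DegenerateGeometryError("cannot take perpendicular of zero vector")
    perp = np.array([-u[1], u[0]]) / n
    if prefer_superior and perp[1] > 0:
        perp = -perp
    return perp
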