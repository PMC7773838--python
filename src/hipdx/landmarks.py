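"""Automatic construction of the femoral-head center from the head contour.

The head center is not marked by the clinician: it is the center of the
circle through three automatically selected contour points —

* ``d``: the superior (uppermost) vertex of the head contour,
* ``e``: the lateral (outermost) vertex, optionally restricted to the arc
  above the head/neck inflection when the delineation includes the neck,
* ``f``: where the line from ``e`` through the inferior acetabular edge
  ``g`` re-crosses the head contour.

Three non-collinear points determine the circle; the construction uses the
delineated vertices directly, with no resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotations import HipAnnotation, lateral_sign
from .errors import DegenerateGeometryError, LandmarkError
from .geometry import (
    Contour,
    Point,
    circumcircle,
    perpendicular_direction,
    segment_contour_intersections,
)

__all__ = [
    "FemoralHeadFit",
    "MeasurementTrace",
    "find_superior_point",
    "find_lateral_point",
    "fit_femoral_head",
    "vertical_reference",
]

#: display length (pixels) of the vertical-reference construction segment
VERTICAL_REFERENCE_LENGTH = 100.0

#: window (vertices) of the discrete turning-angle estimate used for
#: head/neck inflection detection
INFLECTION_WINDOW = 5


@dataclass
class FemoralHeadFit:
    """Fitted head circle plus its three defining contour points."""

    center: Point
    radius: float
    superior_point: Point   # d
    lateral_point: Point    # e
    inferior_intersection: Point  # f


@dataclass
class MeasurementTrace:
    """Construction geometry retained for rendering and debugging."""

    vertical_reference_point: Point
    construction_segments: list[tuple[Point, Point]] = field(default_factory=list)


def find_superior_point(contour: Contour) -> Point:
    """The uppermost contour vertex (minimal y).

    Ties are broken by the vertex whose x is closest to the contour's
    centroid x, then by lowest vertex index.
    """
    v = contour.vertices
    ymin = v[:, 1].min()
    tol = 1e-12 * contour.diagonal
    idx = np.flatnonzero(v[:, 1] <= ymin + tol)
    cx = v[:, 0].mean()
    best = min(idx, key=lambda i: (abs(v[i, 0] - cx), i))
    return Point(*v[best])


def _turning_angles(v: np.ndarray, window: int) -> np.ndarray:
    """Signed turning angle at each vertex over a +-window/2 vertex span."""
    h = max(window // 2, 1)
    n = len(v)
    out = np.zeros(n)
    for i in range(n):
        a, b, c = v[max(i - h, 0)], v[i], v[min(i + h, n - 1)]
        u1, u2 = b - a, c - b
        cross = u1[0] * u2[1] - u1[1] * u2[0]
        dot = u1 @ u2
        out[i] = np.arctan2(cross, dot)
    return out


def find_lateral_point(contour: Contour, side: str, neck_present: bool = False) -> Point:
    """The outermost (most lateral) head-contour vertex.

    When the delineation includes the femoral neck (``neck_present``), the
    search is restricted to vertices superior to the first curvature-sign
    inflection met while walking from the superior point toward the neck,
    so the lateral point lands on the head arc rather than on the neck.
    """
    v = contour.vertices
    sign = lateral_sign(side)
    if not neck_present:
        best = int(np.argmax(sign * v[:, 0]))
        return Point(*v[best])

    apex = find_superior_point(contour)
    apex_idx = int(np.argmin(np.linalg.norm(v - apex.as_array(), axis=1)))
    turning = _turning_angles(v, INFLECTION_WINDOW)

    def walk(indices: np.ndarray) -> int | None:
        # first sign change of the turning angle along this walk
        prev = 0.0
        for k, i in enumerate(indices):
            t = turning[i]
            if abs(t) < 1e-12:
                continue
            if prev != 0.0 and np.sign(t) != np.sign(prev):
                return k
            prev = t
        return None

    # walk inferolaterally: pick the contour direction whose near vertices
    # move laterally from the apex
    fwd = np.arange(apex_idx, len(v))
    bwd = np.arange(apex_idx, -1, -1)
    lat_fwd = sign * (v[fwd[min(3, len(fwd) - 1)], 0] - v[apex_idx, 0])
    lat_bwd = sign * (v[bwd[min(3, len(bwd) - 1)], 0] - v[apex_idx, 0])
    indices = fwd if lat_fwd >= lat_bwd else bwd
    cut = walk(indices)
    if cut is None or cut < 1:
        raise LandmarkError(
            "no head/neck inflection found on the lateral walk "
            "(neck_present=True but the contour shows no curvature sign change)"
        )
    arc = indices[:cut]
    best = arc[int(np.argmax(sign * v[arc, 0]))]
    return Point(*v[best])


def fit_femoral_head(hip: HipAnnotation, neck_present: bool = False) -> FemoralHeadFit:
    """Construct the femoral-head circle for one hip.

    ``d`` and ``e`` are selected on the head contour; ``f`` is the farthest
    crossing of the head contour by the ray from ``e`` through the inferior
    acetabular edge ``g``.  The circle through ``d``, ``e``, ``f`` gives the
    head center and radius.

    Raises
    ------
    LandmarkError
        If the e–g ray meets the contour nowhere but at ``e`` itself.
    DegenerateGeometryError
        If ``d``, ``e``, ``f`` are collinear.
    """
    contour = hip.femoral_head_contour
    d = find_superior_point(contour)
    e = find_lateral_point(contour, hip.side, neck_present=neck_present)
    g = hip.inferior_acetabular_edge

    # extend the e->g ray well past the contour so a g inside the head
    # circle still yields the far crossing
    e_arr, g_arr = e.as_array(), g.as_array()
    direction = g_arr - e_arr
    norm = np.linalg.norm(direction)
    if norm == 0.0:
        raise DegenerateGeometryError(
            "lateral point and inferior acetabular edge coincide"
        )
    far = e_arr + direction / norm * (4.0 * contour.diagonal)
    hits = segment_contour_intersections(e, Point(*far), contour)
    tol = 1e-6 * contour.diagonal
    hits = [p for p in hits if np.hypot(p.x - e.x, p.y - e.y) > tol]
    if not hits:
        raise LandmarkError(
            "the ray from the lateral head point through the inferior "
            "acetabular edge does not re-cross the femoral head contour"
        )
    f = hits[-1]  # farthest from e: the crossing on the inferior head arc
    center, radius = circumcircle(d, e, f)
    return FemoralHeadFit(center=center, radius=radius,
                          superior_point=d, lateral_point=e,
                          inferior_intersection=f)


def vertical_reference(center_right: Point, center_left: Point,
                       for_center: Point,
                       length: float = VERTICAL_REFERENCE_LENGTH) -> MeasurementTrace:
    """The CE angle's vertical reference for one hip.

    The reference direction is the superior perpendicular of the baseline
    joining the two femoral-head centers; the reference point is the hip's
    own center displaced along it by a fixed display length.  Because the
    direction follows the baseline rather than the image axes, the CE angle
    is invariant under in-plane rotation of the radiograph.
    """
    baseline = center_left.as_array() - center_right.as_array()
    if np.linalg.norm(baseline) == 0.0:
        raise DegenerateGeometryError("femoral head centers coincide")
    up = perpendicular_direction(baseline, prefer_superior=True)
    ref = for_center.as_array() + length * up
    ref_pt = Point(float(ref[0]), float(ref[1]))
    return MeasurementTrace(
        vertical_reference_point=ref_pt,
        construction_segments=[(center_right, center_left), (for_center, ref_pt)],
    )
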