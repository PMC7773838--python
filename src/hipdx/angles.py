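"""The three diagnostic angles: center-edge (CE), sharp, and Tönnis.

Each angle is the arccos of a normalized dot product of two direction
vectors, so all three are unsigned degrees in [0, 180]:

* **CE** — at the femoral-head center ``a``, between the vertical reference
  ``a→c`` (perpendicular to the line joining the two head centers) and the
  line ``a→b`` to the lateral acetabular edge.  Low CE means the socket
  covers too little of the head laterally.
* **Sharp** — at the inferior acetabular edge ``g`` (the teardrop), between
  the line ``g→b`` and the inter-teardrop baseline, directed from the
  contralateral to the ipsilateral teardrop.
* **Tönnis** — between the sourcil line (inferomedial sourcil point ``s``
  to lateral edge ``b``) and the same inter-teardrop baseline direction.
  High Tönnis means an up-tilted weight-bearing roof.

Baseline vectors are directed contralateral → ipsilateral; taking the
opposite direction would give the supplement, and this orientation yields
the acute clinical angles for normal anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotations import PelvisAnnotation
from .errors import DegenerateGeometryError, HipdxError
from .geometry import Point, angle_between
from .landmarks import FemoralHeadFit, MeasurementTrace, fit_femoral_head, vertical_reference

__all__ = ["AngleTriplet", "AngleSample", "ce_angle", "sharp_angle",
           "tonnis_angle", "measure_pelvis"]


@dataclass(frozen=True)
class AngleTriplet:
    """One hip's (θCE, θsharp, θTönnis) in degrees; the unit of all
    downstream statistics."""

    ce_deg: float
    sharp_deg: float
    tonnis_deg: float

    def __post_init__(self) -> None:
        for name in ("ce_deg", "sharp_deg", "tonnis_deg"):
            v = getattr(self, name)
            if not 0.0 <= v <= 180.0:
                raise ValueError(f"{name}={v} outside [0, 180]")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.ce_deg, self.sharp_deg, self.tonnis_deg)


@dataclass(frozen=True)
class AngleSample:
    """An angle triplet tagged with its hip's identity."""

    triplet: AngleTriplet
    side: str
    sample_id: str


def _check_distinct(*pairs: tuple[Point, Point]) -> None:
    for a, b in pairs:
        if a == b:
            raise DegenerateGeometryError(f"coincident points {a} in angle input")


def ce_angle(head_center: Point, vertical_ref: Point, lateral_edge: Point) -> float:
    """Center-edge angle of Wiberg at the femoral-head center, degrees."""
    _check_distinct((head_center, vertical_ref), (head_center, lateral_edge))
    u = (vertical_ref.x - head_center.x, vertical_ref.y - head_center.y)
    v = (lateral_edge.x - head_center.x, lateral_edge.y - head_center.y)
    return angle_between(u, v)


def sharp_angle(inferior_edge_same: Point, inferior_edge_other: Point,
                lateral_edge: Point) -> float:
    """Sharp angle at the ipsilateral inferior acetabular edge, degrees.

    The baseline vector runs from the contralateral inferior edge to the
    ipsilateral one (the angle's vertex).
    """
    _check_distinct((inferior_edge_same, lateral_edge),
                    (inferior_edge_same, inferior_edge_other))
    u = (lateral_edge.x - inferior_edge_same.x,
         lateral_edge.y - inferior_edge_same.y)
    v = (inferior_edge_same.x - inferior_edge_other.x,
         inferior_edge_same.y - inferior_edge_other.y)
    return angle_between(u, v)


def tonnis_angle(sourcil_point: Point, lateral_edge: Point,
                 inferior_edge_same: Point, inferior_edge_other: Point) -> float:
    """Tönnis (acetabular roof) angle, degrees.

    Angle between the sourcil line (sourcil point → lateral edge) and the
    inter-teardrop baseline directed contralateral → ipsilateral.
    """
    _check_distinct((sourcil_point, lateral_edge),
                    (inferior_edge_same, inferior_edge_other))
    u = (lateral_edge.x - sourcil_point.x, lateral_edge.y - sourcil_point.y)
    v = (inferior_edge_same.x - inferior_edge_other.x,
         inferior_edge_same.y - inferior_edge_other.y)
    return angle_between(u, v)


def measure_hip(hip_fit: FemoralHeadFit, trace: MeasurementTrace,
                hip, other_hip) -> AngleTriplet:
    """Assemble the three angles for one hip from its fit and landmarks."""
    ce = ce_angle(hip_fit.center, trace.vertical_reference_point,
                  hip.lateral_acetabular_edge)
    sharp = sharp_angle(hip.inferior_acetabular_edge,
                        other_hip.inferior_acetabular_edge,
                        hip.lateral_acetabular_edge)
    tonnis = tonnis_angle(hip.sourcil_inferomedial_point,
                          hip.lateral_acetabular_edge,
                          hip.inferior_acetabular_edge,
                          other_hip.inferior_acetabular_edge)
    return AngleTriplet(ce_deg=ce, sharp_deg=sharp, tonnis_deg=tonnis)


def measure_pelvis(
    annotation: PelvisAnnotation, neck_present: bool = False,
) -> tuple[AngleSample, AngleSample, dict[str, MeasurementTrace]]:
    """Measure both hips of one radiograph.

    Fits the femoral-head circle on each side, builds the shared vertical
    reference from the two head centers, and returns one
    :class:`AngleSample` per patient side plus the measurement traces.

    Errors from landmark construction or degenerate geometry are re-raised
    tagged with the failing side.
    """
    fits: dict[str, FemoralHeadFit] = {}
    for side in ("right", "left"):
        try:
            fits[side] = fit_femoral_head(annotation.hip(side), neck_present=neck_present)
        except HipdxError as exc:
            raise type(exc)(f"[{annotation.image_id}/{side}] {exc}") from exc

    samples = {}
    traces = {}
    for side, other in (("right", "left"), ("left", "right")):
        try:
            trace = vertical_reference(fits["right"].center, fits["left"].center,
                                       for_center=fits[side].center)
            triplet = measure_hip(fits[side], trace, annotation.hip(side),
                                  annotation.hip(other))
        except HipdxError as exc:
            raise type(exc)(f"[{annotation.image_id}/{side}] {exc}") from exc
        traces[side] = trace
        samples[side] = AngleSample(
            triplet=triplet, side=side,
            sample_id=f"{annotation.image_id}/{side}",
        )
    return samples["right"], samples["left"], traces
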