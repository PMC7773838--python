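"""Data model and JSON file format for manual pelvis delineations.

A pelvis annotation is the pipeline's input: per-hip contours (acetabulum,
femoral head, optionally proximal femur) plus three landmark points marked
by the clinician during delineation — the lateral (external upper) edge of
the acetabulum, the inferior (lower) edge of the acetabulum, and the
inferomedial end of the sourcil (the weight-bearing roof).

Sides are *patient* sides: on a standard AP radiograph the patient-right
hip appears on the image left, so the lateral direction for the right hip
is decreasing x and for the left hip increasing x.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .errors import AnnotationSchemaError
from .geometry import Contour, Point

__all__ = ["HipAnnotation", "PelvisAnnotation", "read_annotation", "write_annotation",
           "lateral_sign"]

Side = Literal["right", "left"]

LANDMARK_NAMES = (
    "lateral_acetabular_edge",
    "inferior_acetabular_edge",
    "sourcil_inferomedial_point",
)


def lateral_sign(side: Side) -> float:
    """Direction of increasing lateral offset along x for a patient side.

    Patient-right hip sits on the image left: lateral is decreasing x (-1).
    """
    return -1.0 if side == "right" else 1.0


@dataclass
class HipAnnotation:
    """One hip's delineation: contours plus the three marked landmarks."""

    side: Side
    acetabulum_contour: Contour
    femoral_head_contour: Contour
    lateral_acetabular_edge: Point
    inferior_acetabular_edge: Point
    sourcil_inferomedial_point: Point
    proximal_femur_contour: Contour | None = None

    def validate(self, image_id: str = "<unknown>") -> None:
        ctx = f"(image_id={image_id!r}, side={self.side!r})"
        if self.side not in ("right", "left"):
            raise AnnotationSchemaError(f"side must be 'right' or 'left' {ctx}")
        if len(self.femoral_head_contour.vertices) < 8:
            raise AnnotationSchemaError(
                f"femoral_head_contour needs >= 8 vertices, got "
                f"{len(self.femoral_head_contour.vertices)} {ctx}"
            )
        pts = [self.lateral_acetabular_edge, self.inferior_acetabular_edge,
               self.sourcil_inferomedial_point]
        for i in range(3):
            for j in range(i + 1, 3):
                if pts[i] == pts[j]:
                    raise AnnotationSchemaError(
                        f"landmarks {LANDMARK_NAMES[i]} and {LANDMARK_NAMES[j]} "
                        f"coincide {ctx}"
                    )
        if self.lateral_acetabular_edge.y >= self.inferior_acetabular_edge.y:
            raise AnnotationSchemaError(
                f"lateral_acetabular_edge must be superior to "
                f"inferior_acetabular_edge (smaller y) {ctx}"
            )

    def bbox(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) over contours and landmarks."""
        arrs = [self.acetabulum_contour.vertices, self.femoral_head_contour.vertices]
        if self.proximal_femur_contour is not None:
            arrs.append(self.proximal_femur_contour.vertices)
        arrs.append(np.array([self.lateral_acetabular_edge,
                              self.inferior_acetabular_edge,
                              self.sourcil_inferomedial_point], dtype=float))
        allv = np.vstack(arrs)
        xmin, ymin = allv.min(axis=0)
        xmax, ymax = allv.max(axis=0)
        return float(xmin), float(ymin), float(xmax), float(ymax)


@dataclass
class PelvisAnnotation:
    """One radiograph's delineation: the two hips plus metadata."""

    image_id: str
    right_hip: HipAnnotation
    left_hip: HipAnnotation
    pixel_spacing_mm: float | None = None

    def hip(self, side: Side) -> HipAnnotation:
        return self.right_hip if side == "right" else self.left_hip

    def validate(self) -> None:
        if self.right_hip.side != "right" or self.left_hip.side != "left":
            raise AnnotationSchemaError(
                f"hips must carry their own patient side (image_id={self.image_id!r})"
            )
        self.right_hip.validate(self.image_id)
        self.left_hip.validate(self.image_id)
        r, l = self.right_hip.bbox(), self.left_hip.bbox()
        disjoint = r[2] < l[0] or l[2] < r[0] or r[3] < l[1] or l[3] < r[1]
        if not disjoint:
            raise AnnotationSchemaError(
                f"hip bounding boxes overlap (image_id={self.image_id!r})"
            )


# ---------------------------------------------------------------------------
# JSON serialization

def _contour_to_json(c: Contour | None):
    if c is None:
        return None
    return [[float(x), float(y)] for x, y in c.vertices]


def _contour_from_json(obj, name: str, image_id: str, closed: bool) -> Contour | None:
    if obj is None:
        return None
    try:
        v = np.asarray(obj, dtype=float)
        return Contour(v, closed=closed)
    except Exception as exc:
        raise AnnotationSchemaError(
            f"invalid contour {name!r} (image_id={image_id!r}): {exc}"
        ) from exc


def _hip_to_json(h: HipAnnotation) -> dict:
    return {
        "acetabulum_contour": _contour_to_json(h.acetabulum_contour),
        "femoral_head_contour": _contour_to_json(h.femoral_head_contour),
        "proximal_femur_contour": _contour_to_json(h.proximal_femur_contour),
        "contours_closed": {
            "acetabulum_contour": h.acetabulum_contour.closed,
            "femoral_head_contour": h.femoral_head_contour.closed,
            "proximal_femur_contour": (
                h.proximal_femur_contour.closed
                if h.proximal_femur_contour is not None else False
            ),
        },
        "landmarks": {
            name: [float(getattr(h, name).x), float(getattr(h, name).y)]
            for name in LANDMARK_NAMES
        },
    }


def _require(obj: dict, key: str, image_id: str):
    if key not in obj:
        raise AnnotationSchemaError(
            f"missing required field {key!r} (image_id={image_id!r})"
        )
    return obj[key]


def _hip_from_json(obj: dict, side: Side, image_id: str) -> HipAnnotation:
    closed = obj.get("contours_closed", {})
    landmarks = _require(obj, "landmarks", image_id)
    pts = {}
    for name in LANDMARK_NAMES:
        raw = _require(landmarks, name, image_id)
        try:
            pts[name] = Point(float(raw[0]), float(raw[1]))
        except (TypeError, ValueError, IndexError) as exc:
            raise AnnotationSchemaError(
                f"landmark {name!r} is not an [x, y] pair (image_id={image_id!r})"
            ) from exc
    hip = HipAnnotation(
        side=side,
        acetabulum_contour=_contour_from_json(
            _require(obj, "acetabulum_contour", image_id),
            "acetabulum_contour", image_id,
            bool(closed.get("acetabulum_contour", False))),
        femoral_head_contour=_contour_from_json(
            _require(obj, "femoral_head_contour", image_id),
            "femoral_head_contour", image_id,
            bool(closed.get("femoral_head_contour", False))),
        proximal_femur_contour=_contour_from_json(
            obj.get("proximal_femur_contour"),
            "proximal_femur_contour", image_id,
            bool(closed.get("proximal_femur_contour", False))),
        **pts,
    )
    return hip


def write_annotation(annotation: PelvisAnnotation, path: str | Path) -> None:
    """Write a validated pelvis annotation as JSON (lossless round-trip)."""
    annotation.validate()
    doc = {
        "image_id": annotation.image_id,
        "pixel_spacing_mm": annotation.pixel_spacing_mm,
        "hips": {
            "right": _hip_to_json(annotation.right_hip),
            "left": _hip_to_json(annotation.left_hip),
        },
    }
    if annotation.pixel_spacing_mm is None:
        del doc["pixel_spacing_mm"]
    Path(path).write_text(json.dumps(doc, indent=1))


def read_annotation(path: str | Path) -> PelvisAnnotation:
    """Read and validate a pelvis annotation JSON file.

    Raises
    ------
    AnnotationSchemaError
        On any missing field or violated invariant; the message names the
        offending field and the file's image_id.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationSchemaError(f"file {path} is not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise AnnotationSchemaError(f"file {path} does not contain a JSON object")
    image_id = doc.get("image_id")
    if not isinstance(image_id, str):
        raise AnnotationSchemaError(f"missing or non-string 'image_id' in {path}")
    hips = _require(doc, "hips", image_id)
    spacing = doc.get("pixel_spacing_mm")
    ann = PelvisAnnotation(
        image_id=image_id,
        pixel_spacing_mm=None if spacing is None else float(spacing),
        right_hip=_hip_from_json(_require(hips, "right", image_id), "right", image_id),
        left_hip=_hip_from_json(_require(hips, "left", image_id), "left", image_id),
    )
    ann.validate()
    return ann
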