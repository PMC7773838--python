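"""Synthetic inputs at two levels: angle triplets and whole pelvis annotations.

*Triplet level* — draws (θCE, θsharp, θTönnis) samples from a two-component
Gaussian mixture (normal development vs dysplasia) with planted component
labels, for testing the clustering and model stages in isolation.  The
default component parameters are chosen to be clinically plausible: normal
hips around CE 30°, sharp 40°, Tönnis 8° with a few degrees of spread;
dysplastic hips with low CE, high sharp, and an up-tilted roof.

*Pelvis level* — inverse-constructs a full two-hip annotation whose forward
measurement reproduces prescribed ground-truth angles: the femoral-head
contour is a sampled circular arc, and the three acetabular landmarks are
placed by inverting the CE, sharp, and Tönnis constructions around a
horizontal inter-teardrop baseline.  With zero vertex noise the forward
measurement recovers the prescribed angles up to arc-discretization error,
which vanishes as the vertex count grows.

All randomness flows from the single seed in each config.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .angles import AngleSample, AngleTriplet
from .annotations import (HipAnnotation, PelvisAnnotation, lateral_sign,
                          write_annotation)
from .errors import ConfigError, ConstructionError
from .geometry import Contour, Point

__all__ = ["TripletSimConfig", "PelvisSimConfig", "sample_triplets",
           "construct_pelvis", "make_dataset", "samples_to_array"]

logger = logging.getLogger(__name__)

# geometry ratios of the inverse construction, as fractions of head radius:
# radial distance of the lateral acetabular edge from the head center,
_B_RADIUS = 1.3
# allowed medial offset range of the inferior acetabular edge (teardrop),
_G_OFFSET_MIN = 0.3
_G_OFFSET_MAX = 1.9
# horizontal width of the sourcil (lateral edge to inferomedial point),
_SOURCIL_WIDTH = 0.8
# arc margins (degrees) past the lateral point and past f
_ARC_MARGIN_LATERAL = 20.0
_ARC_MARGIN_F = 15.0


def _check_spd(m, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3) or not np.allclose(m, m.T):
        raise ConfigError(f"{name} must be a symmetric 3x3 matrix")
    if np.linalg.eigvalsh(m).min() <= 0:
        raise ConfigError(f"{name} must be positive definite")
    return m


@dataclass
class TripletSimConfig:
    """Two-component Gaussian mixture over angle triplets (degrees)."""

    n_normal: int = 240
    n_dysplastic: int = 60
    mu_normal: tuple = (30.0, 40.0, 8.0)
    mu_dysplastic: tuple = (14.0, 48.0, 18.0)
    sigma_normal: tuple = ((16.0, 0, 0), (0, 9.0, 0), (0, 0, 6.25))
    sigma_dysplastic: tuple = ((16.0, 0, 0), (0, 16.0, 0), (0, 0, 16.0))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_normal < 0 or self.n_dysplastic < 0:
            raise ConfigError("component counts must be nonnegative")
        _check_spd(self.sigma_normal, "sigma_normal")
        _check_spd(self.sigma_dysplastic, "sigma_dysplastic")


def sample_triplets(config: TripletSimConfig) -> tuple[list[AngleSample], np.ndarray]:
    """Draw angle triplets from the mixture, with planted component labels.

    Returns ``(samples, labels)`` where ``labels[i]`` is ``"normal"`` or
    ``"dysplastic"``.  Draws falling outside the valid angle range
    ``[0, 180]`` are redrawn (vanishingly rare at the default parameters).
    """
    rng = np.random.default_rng(config.seed)
    rows: list[AngleSample] = []
    labels: list[str] = []
    for label, n, mu, sigma in (
        ("normal", config.n_normal, config.mu_normal, config.sigma_normal),
        ("dysplastic", config.n_dysplastic, config.mu_dysplastic, config.sigma_dysplastic),
    ):
        mu = np.asarray(mu, dtype=float)
        sigma = np.asarray(sigma, dtype=float)
        for k in range(n):
            for _ in range(100):
                x = rng.multivariate_normal(mu, sigma)
                if ((0.0 <= x) & (x <= 180.0)).all():
                    break
            else:  # pragma: no cover
                raise ConfigError("could not draw a valid triplet in 100 tries")
            rows.append(AngleSample(
                triplet=AngleTriplet(*x), side="right" if k % 2 == 0 else "left",
                sample_id=f"sim_{label}_{k:04d}"))
            labels.append(label)
    return rows, np.array(labels)


def samples_to_array(samples: list[AngleSample]) -> np.ndarray:
    """Stack angle samples into an (n, 3) array of degrees."""
    return np.array([s.triplet.as_tuple() for s in samples], dtype=float)


@dataclass
class PelvisSimConfig:
    """Ground-truth targets and geometry for one synthetic pelvis."""

    target_right: AngleTriplet = AngleTriplet(30.0, 40.0, 5.0)
    target_left: AngleTriplet = AngleTriplet(30.0, 40.0, 5.0)
    head_radius: float = 100.0
    inter_head_distance: float = 400.0
    contour_points: int = 180
    vertex_noise_sd: float = 0.0
    pelvis_rotation: float = 0.0
    seed: int = 0
    image_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.head_radius <= 0:
            raise ConfigError("head_radius must be positive")
        if self.inter_head_distance <= 2 * self.head_radius:
            raise ConfigError("inter_head_distance must exceed the head diameter")
        if self.contour_points < 16:
            raise ConfigError("contour_points must be at least 16")
        if self.vertex_noise_sd < 0:
            raise ConfigError("vertex_noise_sd must be nonnegative")
        for name, t in (("target_right", self.target_right),
                        ("target_left", self.target_left)):
            for comp, lo_open in (("ce_deg", True), ("sharp_deg", True),
                                  ("tonnis_deg", False)):
                v = getattr(t, comp)
                if v >= 90.0 or v < 0.0 or (lo_open and v == 0.0):
                    raise ConfigError(
                        f"{name}.{comp}={v} outside the constructible range "
                        f"({'(' if lo_open else '['}0, 90)")


def _b_point(center: np.ndarray, R: float, ce: float, lat: float) -> np.ndarray:
    """Lateral acetabular edge at the CE rotation from the superior vertical."""
    th = math.radians(ce)
    return center + _B_RADIUS * R * np.array([lat * math.sin(th), -math.cos(th)])


def _y_g_interval(center: np.ndarray, R: float, t: AngleTriplet,
                  lat: float, g_max: float) -> tuple[float, float]:
    """Feasible common teardrop-line heights for one hip."""
    b = _b_point(center, R, t.ce_deg, lat)
    tan_sharp = math.tan(math.radians(t.sharp_deg))
    base = _B_RADIUS * R * math.sin(math.radians(t.ce_deg))
    lo = b[1] + (_G_OFFSET_MIN * R + base) * tan_sharp
    hi = b[1] + (g_max * R + base) * tan_sharp
    return lo, hi


def _unwrap_deg(t: float, lo: float) -> float:
    """Angle t (degrees) shifted by multiples of 360 into [lo, lo + 360)."""
    return lo + (t - lo) % 360.0


def _construct_hip(center: np.ndarray, R: float, target: AngleTriplet,
                   side: str, y_g: float, contour_points: int) -> HipAnnotation:
    lat = lateral_sign(side)
    b = _b_point(center, R, target.ce_deg, lat)

    # invert the sharp angle: horizontal run from b to g on the teardrop line
    dy = y_g - b[1]
    dx = dy / math.tan(math.radians(target.sharp_deg))
    if dx <= 0:
        raise ConstructionError("teardrop line lies above the lateral edge")
    g = np.array([b[0] - lat * dx, y_g])

    # invert the Tönnis angle: sourcil point medial of b on the roof line
    dxs = _SOURCIL_WIDTH * R
    dys = dxs * math.tan(math.radians(target.tonnis_deg))
    s = np.array([b[0] - lat * dxs, b[1] + dys])

    # head contour: circular arc through the apex and lateral point, extended
    # past f (the e-g line's far crossing) so the forward fit can find it
    e = center + R * np.array([lat, 0.0])
    u = g - e
    un = np.linalg.norm(u)
    if un == 0:
        raise ConstructionError("teardrop coincides with the lateral head point")
    u = u / un
    s_chord = -2.0 * float((e - center) @ u)
    if s_chord <= 1e-9 * R:
        raise ConstructionError(
            "the line from the lateral head point to the teardrop does not "
            "re-enter the head circle")
    f = e + s_chord * u
    t_f = math.degrees(math.atan2(f[1] - center[1], f[0] - center[0]))
    if side == "right":
        t_start = 180.0 - _ARC_MARGIN_LATERAL
        t_end = _unwrap_deg(t_f, 180.0) + _ARC_MARGIN_F
    else:
        t_start = 360.0 + _ARC_MARGIN_LATERAL
        t_end = _unwrap_deg(t_f, 0.0) - _ARC_MARGIN_F
    if abs(t_end - t_start) >= 340.0:
        raise ConstructionError("head arc span would exceed 340 degrees")
    ts = np.radians(np.linspace(t_start, t_end, contour_points))
    head = center + R * np.column_stack([np.cos(ts), np.sin(ts)])

    # acetabulum contour: simple roof polyline from above b through the
    # sourcil down to the teardrop (not used by any measurement)
    roof_top = b + np.array([lat * 0.2 * R, -0.3 * R])
    ace = np.vstack([
        np.linspace(roof_top, b, 6),
        np.linspace(b, s, 6)[1:],
        np.linspace(s, g, 8)[1:],
    ])

    return HipAnnotation(
        side=side,
        acetabulum_contour=Contour(ace),
        femoral_head_contour=Contour(head),
        lateral_acetabular_edge=Point(*b),
        inferior_acetabular_edge=Point(*g),
        sourcil_inferomedial_point=Point(*s),
    )


def _transform_hip(hip: HipAnnotation, rotate_deg: float, pivot: np.ndarray,
                   noise_sd: float, rng: np.random.Generator) -> HipAnnotation:
    """Apply vertex noise to contours, then a global rotation to everything."""
    th = math.radians(rotate_deg)
    rot = np.array([[math.cos(th), -math.sin(th)],
                    [math.sin(th), math.cos(th)]])

    def tf_points(pts: np.ndarray, noisy: bool) -> np.ndarray:
        out = np.asarray(pts, dtype=float)
        if noisy and noise_sd > 0:
            out = out + rng.normal(0.0, noise_sd, size=out.shape)
        return (out - pivot) @ rot.T + pivot

    def tf_contour(c: Contour | None, noisy: bool = True) -> Contour | None:
        if c is None:
            return None
        return Contour(tf_points(c.vertices, noisy), closed=c.closed)

    def tf_point(p: Point) -> Point:
        return Point(*tf_points(np.array([p], dtype=float), False)[0])

    return HipAnnotation(
        side=hip.side,
        acetabulum_contour=tf_contour(hip.acetabulum_contour),
        femoral_head_contour=tf_contour(hip.femoral_head_contour),
        proximal_femur_contour=tf_contour(hip.proximal_femur_contour),
        lateral_acetabular_edge=tf_point(hip.lateral_acetabular_edge),
        inferior_acetabular_edge=tf_point(hip.inferior_acetabular_edge),
        sourcil_inferomedial_point=tf_point(hip.sourcil_inferomedial_point),
    )


def construct_pelvis(config: PelvisSimConfig) -> tuple[PelvisAnnotation,
                                                       tuple[AngleSample, AngleSample]]:
    """Inverse-construct one pelvis annotation with known ground-truth angles.

    Both hips share a horizontal inter-teardrop baseline (before the global
    rotation), chosen inside the feasibility interval of both sides'
    sharp-angle constructions.

    Raises
    ------
    ConstructionError
        When the requested angle combination admits no common teardrop
        line or pushes a landmark into an invalid position; the message
        names the violated constraint.
    """
    R = config.head_radius
    D = config.inter_head_distance
    c_right = np.array([3.0 * R, 5.0 * R])
    c_left = c_right + np.array([D, 0.0])
    g_max = min(_G_OFFSET_MAX, 0.47 * D / R)

    lo_r, hi_r = _y_g_interval(c_right, R, config.target_right, lateral_sign("right"), g_max)
    lo_l, hi_l = _y_g_interval(c_left, R, config.target_left, lateral_sign("left"), g_max)
    lo, hi = max(lo_r, lo_l), min(hi_r, hi_l)
    if lo > hi:
        raise ConstructionError(
            "no common teardrop line satisfies both sides' CE/sharp targets "
            f"(right interval [{lo_r:.1f}, {hi_r:.1f}], left [{lo_l:.1f}, {hi_l:.1f}])")
    y_g = 0.5 * (lo + hi)

    right = _construct_hip(c_right, R, config.target_right, "right", y_g,
                           config.contour_points)
    left = _construct_hip(c_left, R, config.target_left, "left", y_g,
                          config.contour_points)

    rng = np.random.default_rng(config.seed)
    pivot = 0.5 * (c_right + c_left)
    right = _transform_hip(right, config.pelvis_rotation, pivot,
                           config.vertex_noise_sd, rng)
    left = _transform_hip(left, config.pelvis_rotation, pivot,
                          config.vertex_noise_sd, rng)

    ann = PelvisAnnotation(image_id=config.image_id, right_hip=right, left_hip=left)
    try:
        ann.validate()
    except Exception as exc:
        raise ConstructionError(f"constructed annotation violates invariants: {exc}") from exc
    truth = (
        AngleSample(config.target_right, "right", f"{config.image_id}/right"),
        AngleSample(config.target_left, "left", f"{config.image_id}/left"),
    )
    return ann, truth


@dataclass
class GeometryDefaults:
    """Pelvis-level geometry shared by all pelves of a generated dataset."""

    head_radius: float = 100.0
    inter_head_distance: float = 400.0
    contour_points: int = 180
    vertex_noise_sd: float = 0.0
    pelvis_rotation_sd: float = 3.0  # per-pelvis in-plane tilt, degrees


def make_dataset(
    n_pelves: int,
    out_dir: str | Path,
    triplet_config: TripletSimConfig | None = None,
    geometry: GeometryDefaults | None = None,
    seed: int = 0,
    max_retries: int = 50,
) -> pd.DataFrame:
    """Write a dataset of annotation files with a ground-truth manifest.

    Each pelvis gets two ground-truth triplets drawn independently from the
    mixture (each hip is its own sample, as on a real film where sides can
    differ).  Infeasible draws are rejected and redrawn up to
    ``max_retries`` times, keeping the planted distributions clean.

    Returns the manifest as a DataFrame (also written to
    ``out_dir/manifest.csv``) with one row per hip: file, side,
    planted_label, ce_true, sharp_true, tonnis_true.
    """
    tcfg = triplet_config or TripletSimConfig()
    geo = geometry or GeometryDefaults()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    total = tcfg.n_normal + tcfg.n_dysplastic
    if total <= 0:
        raise ConfigError("mixture has no components to draw from")
    p_normal = tcfg.n_normal / total

    def draw_one() -> tuple[AngleTriplet, str]:
        for _ in range(100):
            if rng.random() < p_normal:
                mu, sigma, label = tcfg.mu_normal, tcfg.sigma_normal, "normal"
            else:
                mu, sigma, label = tcfg.mu_dysplastic, tcfg.sigma_dysplastic, "dysplastic"
            x = rng.multivariate_normal(np.asarray(mu, float), np.asarray(sigma, float))
            if (0.0 < x[0] < 90.0) and (0.0 < x[1] < 90.0) and (0.0 <= x[2] < 90.0):
                return AngleTriplet(*x), label
        raise ConfigError("could not draw a constructible triplet in 100 tries")

    rows = []
    for i in range(n_pelves):
        name = f"pelvis_{i:04d}.json"
        for attempt in range(max_retries):
            (t_r, lab_r), (t_l, lab_l) = draw_one(), draw_one()
            cfg = PelvisSimConfig(
                target_right=t_r, target_left=t_l,
                head_radius=geo.head_radius,
                inter_head_distance=geo.inter_head_distance,
                contour_points=geo.contour_points,
                vertex_noise_sd=geo.vertex_noise_sd,
                pelvis_rotation=float(rng.normal(0.0, geo.pelvis_rotation_sd)),
                seed=int(rng.integers(0, 2**31 - 1)),
                image_id=f"pelvis_{i:04d}",
            )
            try:
                ann, _ = construct_pelvis(cfg)
            except ConstructionError as exc:
                logger.info("pelvis %d attempt %d infeasible, redrawing: %s",
                            i, attempt, exc)
                continue
            break
        else:
            raise ConstructionError(
                f"pelvis {i}: no feasible draw in {max_retries} retries")
        write_annotation(ann, out / name)
        for side, t, lab in (("right", t_r, lab_r), ("left", t_l, lab_l)):
            rows.append({"file": name, "side": side, "planted_label": lab,
                         "ce_true": round(t.ce_deg, 6),
                         "sharp_true": round(t.sharp_deg, 6),
                         "tonnis_true": round(t.tonnis_deg, 6)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
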