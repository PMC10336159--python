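"""Stage geometry: locating the beaker center and the sampling points.

The beaker sits on an aluminum plate carrying two geometric markers, Point A
and Point B, whose plate-frame coordinates are known from the plate design.
During setup the operator records the stage coordinates of both markers; the
unique planar rigid transform (rotation + translation, no scaling) mapping
the plate frame onto the stage frame then gives the stage positions of the
plate center C_o and the beaker center C_0. The laser samples the water
surface at C0 (the center) and at 1 mm (C1) and 2 mm (C2) offsets.

All coordinates are in micrometres.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "StagePoint",
    "PlateLayout",
    "SamplingPoints",
    "GeometryError",
    "GeometryWarning",
    "locate_centers",
    "check_relative_positions",
    "sampling_points",
    "angular_speed_rpm",
]


class GeometryError(ValueError):
    """Degenerate or inconsistent geometric configuration."""


class GeometryWarning(UserWarning):
    """The measured marker pair is not rigid-motion-consistent with the
    plate layout (scale residual beyond tolerance)."""


@dataclass(frozen=True)
class StagePoint:
    """A stage coordinate (µm); z is the focus axis and optional."""

    x: float
    y: float
    z: float | None = None

    def __post_init__(self):
        vals = (self.x, self.y) + (() if self.z is None else (self.z,))
        if not all(math.isfinite(v) for v in vals):
            raise GeometryError("stage coordinates must be finite")

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y], float)


@dataclass(frozen=True)
class PlateLayout:
    """Plate-frame coordinates (µm) of the markers and centers.

    The default values are design placeholders consistent with the plate's
    legible dimensions (inner hole radius 13 mm, beaker inner radius
    11.25 mm) and with the required ordering: the plate center lies between
    marker B and the beaker center.
    """

    marker_a: tuple[float, float] = (-15000.0, 9000.0)
    marker_b: tuple[float, float] = (0.0, 13000.0)
    plate_center: tuple[float, float] = (0.0, 0.0)
    beaker_center: tuple[float, float] = (0.0, -6000.0)
    plate_hole_radius: float = 13000.0
    beaker_inner_radius: float = 11250.0

    def __post_init__(self):
        if self.plate_hole_radius <= 0 or self.beaker_inner_radius <= 0:
            raise GeometryError("radii must be positive")
        if np.allclose(self.marker_a, self.marker_b):
            raise GeometryError("markers A and B must be distinct")


@dataclass(frozen=True)
class SamplingPoints:
    """The three laser points on the water surface, sharing one focus z."""

    c0: StagePoint
    c1: StagePoint
    c2: StagePoint


def _rigid_from_two_points(src_a, src_b, dst_a, dst_b):
    """Rotation angle + translation mapping (src_a, src_b) onto
    (dst_a, dst_b) in the least-squares sense (midpoints coincide; rotation
    aligns the A->B directions; no scaling)."""
    zs = complex(*(src_b - src_a))
    zd = complex(*(dst_b - dst_a))
    if zs == 0 or zd == 0:
        raise GeometryError("coincident markers; rigid transform undefined")
    theta = math.atan2((zd * zs.conjugate()).imag, (zd * zs.conjugate()).real)
    R = np.array([[math.cos(theta), -math.sin(theta)],
                  [math.sin(theta), math.cos(theta)]])
    src_mid = (src_a + src_b) / 2
    dst_mid = (dst_a + dst_b) / 2
    t = dst_mid - R @ src_mid
    return R, t


def locate_centers(a_meas: StagePoint, b_meas: StagePoint,
                   layout: PlateLayout = PlateLayout(),
                   distance_rtol: float = 0.05) -> tuple[StagePoint, StagePoint]:
    """Stage coordinates of the plate center C_o and beaker center C_0.

    Solves the planar rigid transform taking the layout's marker positions to
    the measured ones and applies it to both centers. If the measured A-B
    distance deviates from the layout distance by more than ``distance_rtol``
    (markers misidentified, plate deformed...), a :class:`GeometryWarning`
    carrying the relative scale residual is emitted; the transform is still
    the least-squares rigid one.
    """
    src_a = np.asarray(layout.marker_a, float)
    src_b = np.asarray(layout.marker_b, float)
    dst_a, dst_b = a_meas.xy, b_meas.xy
    if np.allclose(dst_a, dst_b):
        raise GeometryError("measured markers coincide")
    d_layout = float(np.linalg.norm(src_b - src_a))
    d_meas = float(np.linalg.norm(dst_b - dst_a))
    resid = abs(d_meas - d_layout) / d_layout
    if resid > distance_rtol:
        warnings.warn(
            f"measured marker distance {d_meas:.0f} µm differs from layout "
            f"{d_layout:.0f} µm (relative residual {resid:.3f})",
            GeometryWarning, stacklevel=2)
    R, t = _rigid_from_two_points(src_a, src_b, dst_a, dst_b)
    co = R @ np.asarray(layout.plate_center, float) + t
    c0 = R @ np.asarray(layout.beaker_center, float) + t
    return StagePoint(*co), StagePoint(*c0)


def check_relative_positions(a: StagePoint, b: StagePoint,
                             c_o: StagePoint, c_0: StagePoint,
                             offset_rtol: float = 0.10) -> bool:
    """Sanity check: the plate center must sit between marker B and the
    beaker center. True iff the projection of C_o onto segment B->C_0 lies
    strictly inside it and the perpendicular offset is below ``offset_rtol``
    of |B - C_0|."""
    seg = c_0.xy - b.xy
    seg_len = float(np.linalg.norm(seg))
    if seg_len == 0:
        raise GeometryError("B and C_0 coincide; ordering undefined")
    rel = c_o.xy - b.xy
    t = float(rel @ seg) / seg_len**2
    perp = float(np.linalg.norm(rel - t * seg))
    return 0.0 < t < 1.0 and perp < offset_rtol * seg_len


def sampling_points(c0_meas: StagePoint,
                    offsets: tuple[float, ...] = (1000.0, 2000.0),
                    direction: tuple[float, float] = (1.0, 0.0),
                    beaker_inner_radius: float = 11250.0) -> SamplingPoints:
    """Place C1 and C2 at the stated distances from the measured center C0.

    The points lie along ``direction`` (renormalised internally; default +x
    of the stage) and share C0's focus height. Offsets must be positive,
    strictly increasing and inside the beaker.
    """
    offs = tuple(float(o) for o in offsets)
    if len(offs) != 2 or offs[0] <= 0 or offs[1] <= offs[0]:
        raise GeometryError("offsets must be positive and strictly increasing")
    if offs[-1] >= beaker_inner_radius:
        raise GeometryError(
            f"offset {offs[-1]} µm places the laser outside the beaker "
            f"(inner radius {beaker_inner_radius} µm)")
    d = np.asarray(direction, float)
    norm = float(np.linalg.norm(d))
    if norm == 0:
        raise GeometryError("direction vector must be nonzero")
    d = d / norm
    z = c0_meas.z
    pts = [StagePoint(c0_meas.x + o * d[0], c0_meas.y + o * d[1], z)
           for o in offs]
    return SamplingPoints(replace(c0_meas), pts[0], pts[1])


def angular_speed_rpm(omega: float) -> float:
    """Convert an angular speed in rad/s to revolutions per minute."""
    if not math.isfinite(omega):
        raise ValueError("angular speed must be finite")
    return omega * 60.0 / (2.0 * math.pi)
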