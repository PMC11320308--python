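"""Closed-form Archimedes-spiral mathematics.

An Archimedes spiral with scale ``b`` (pixels per radian) rotated by
``theta_r`` about its origin satisfies ``r = b * (theta + theta_r)``.
Because the radius grows linearly with angle, knowing the polar
coordinates of any two points on the curve (with their polar angles
unwrapped to account for full turns) determines both parameters in
closed form.  This module provides that representation, the two-point
fit, point evaluation, and the arc length along the curve.

All angles are in radians and all lengths in pixels.  Angles follow the
mathematical convention: measured counter-clockwise from the positive
x-axis with the y-axis pointing up.  Image-row (y-down) coordinates are
converted at the I/O boundary, never here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import (
    DegenerateFitError,
    DegeneratePointError,
    InvalidSelectionError,
    OutOfDomainError,
)

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class SpiralParams:
    """Fitted Archimedes spiral: ``r = b * (theta + theta_r)``.

    Attributes
    ----------
    b:
        Spiral scale in pixels per radian; strictly positive by
        convention, so the spiral unwinds counter-clockwise with
        growing radius.
    theta_r:
        Rotation angle of the spiral about its origin, radians.
    origin:
        ``(x0, y0)`` pixel coordinates of the spiral center in the
        source image (y-up).
    """

    b: float
    theta_r: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (self.b > 0.0):
            raise InvalidSelectionError(f"spiral scale b must be > 0, got {self.b}")
        if not math.isfinite(self.theta_r):
            raise InvalidSelectionError("theta_r must be finite")


@dataclass(frozen=True)
class PolarPoint:
    """A point in polar coordinates about the spiral origin.

    ``theta`` is the plain polar angle in ``[0, 2*pi)`` unless it has
    been zone-unwrapped (see :func:`unwrap_angle`), in which case it may
    exceed ``2*pi``.
    """

    r: float
    theta: float

    def __post_init__(self) -> None:
        if self.r < 0.0:
            raise ValueError(f"radius must be >= 0, got {self.r}")


def polar_from_cartesian(
    point: tuple[float, float], origin: tuple[float, float]
) -> PolarPoint:
    """Convert a pixel coordinate to polar coordinates about ``origin``.

    Returns ``r`` as the Euclidean distance and ``theta`` in
    ``[0, 2*pi)`` measured counter-clockwise from the positive x-axis
    (y-up convention).

    Raises
    ------
    DegeneratePointError
        If ``point`` equals ``origin``: the angle is undefined there.
    """
    dx = point[0] - origin[0]
    dy = point[1] - origin[1]
    r = math.hypot(dx, dy)
    if r == 0.0:
        raise DegeneratePointError("point coincides with the spiral origin")
    theta = math.atan2(dy, dx) % TWO_PI
    return PolarPoint(r=r, theta=theta)


def unwrap_angle(theta_prime: float, zone: int, zone_offset: int = 1) -> float:
    """Unwrap a polar angle given the turn index (zone) of its point.

    Zone ``k`` contributes ``theta = theta_prime + 2*pi*(k - zone_offset)``
    with ``theta_prime`` in ``[0, 2*pi)``.  With the default offset of 1
    a point on the first turn keeps its plain polar angle, so "zone one"
    and "zone two" fit points one turn apart differ by exactly ``2*pi``.
    """
    return theta_prime + TWO_PI * (zone - zone_offset)


def fit_from_two_points(
    p1: PolarPoint,
    p2: PolarPoint,
    zones: tuple[int, int] = (1, 2),
    origin: tuple[float, float] = (0.0, 0.0),
    zone_offset: int = 1,
) -> SpiralParams:
    """Determine spiral scale and rotation from two on-spiral points.

    The points' angles are first unwrapped with their zone indices:
    ``theta_i = p_i.theta + 2*pi*(zone_i - zone_offset)``.  Substituting
    both points into ``r = b*(theta + theta_r)`` and solving gives

        theta_r = (r2*theta1 - r1*theta2) / (r1 - r2)
        b       = (r1 - r2) / (theta1 - theta2)

    Raises
    ------
    DegenerateFitError
        If the points share a radius or an unwrapped angle.
    InvalidSelectionError
        If the solution has ``b <= 0`` (points selected inconsistently
        with a counter-clockwise outward spiral).
    """
    t1 = unwrap_angle(p1.theta, zones[0], zone_offset)
    t2 = unwrap_angle(p2.theta, zones[1], zone_offset)
    r1, r2 = p1.r, p2.r
    if r1 == r2 or t1 == t2:
        raise DegenerateFitError(
            "fit points must have distinct radii and distinct unwrapped angles"
        )
    b = (r1 - r2) / (t1 - t2)
    theta_r = (r2 * t1 - r1 * t2) / (r1 - r2)
    if b <= 0.0:
        raise InvalidSelectionError(
            f"two-point fit gave b={b:.6g} <= 0; check point order and zones"
        )
    return SpiralParams(b=b, theta_r=theta_r, origin=origin)


def spiral_radius(params: SpiralParams, theta: float) -> float:
    """Radius of the spiral at unwrapped angle ``theta``: ``b*(theta+theta_r)``."""
    if theta <= -params.theta_r:
        raise OutOfDomainError(
            f"theta={theta} is outside the spiral domain (> {-params.theta_r})"
        )
    return params.b * (theta + params.theta_r)


def spiral_xy(params: SpiralParams, theta: float) -> tuple[float, float]:
    """Cartesian point on the spiral, relative to its origin.

    ``x = b*(theta+theta_r)*cos(theta)``, ``y = b*(theta+theta_r)*sin(theta)``.
    """
    r = spiral_radius(params, theta)
    return (r * math.cos(theta), r * math.sin(theta))


def arc_length(params: SpiralParams, phi: float) -> float:
    """Arc length from the spiral origin to flattened abscissa ``phi``.

    ``phi = theta + theta_r`` is the flattened x-coordinate.  From
    ``ds = r dtheta`` with ``r = b*phi`` the cumulative distance is
    ``s = b * phi**2 / 2``, strictly increasing in ``phi``.
    """
    if phi < 0.0:
        raise OutOfDomainError(f"phi must be >= 0, got {phi}")
    return 0.5 * params.b * phi * phi
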