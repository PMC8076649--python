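"""Planar charts and enclosed areas for the corridor base polygon.

Once the extrema points have been translated onto the (normalized) base
plane they form a closed irregular polygon.  This module maps those 3D
points onto a 2D orthonormal chart of the plane and computes the enclosed
area with the shoelace formula, which is exact for any simple polygon,
convex or not.

It also implements the legacy "surgical freedom" area: the sum of Heron
triangle areas over a fan triangulation of the *raw* (non-coplanar) points.
That method is deliberately preserved with its known defects — the fan
choice can double-count area outside a non-convex outline, and non-coplanar
vertices tilt the triangles so the summed area overestimates the true
perpendicular cross-section.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import (
    DegenerateBasisError,
    InvalidTriangleError,
    NotOnPlaneError,
    SelfIntersectionError,
)
from .geometry import as_point, as_points

__all__ = [
    "PlaneBasis",
    "build_plane_basis",
    "to_plane_coords",
    "shoelace_area",
    "heron_triangle_area",
    "fan_triangulation_area",
    "is_simple_polygon",
]

logger = logging.getLogger(__name__)

#: Points are considered "on" a plane when within this distance (mm).
#: Projection itself is float-exact to ~1e-12; the margin avoids masking bugs.
COPLANARITY_ATOL = 1e-6


@dataclass(frozen=True)
class PlaneBasis:
    """Orthonormal 2D chart of a plane: centroid origin plus in-plane axes.

    ``u_hat`` and ``v_hat`` are unit 3-vectors spanning the plane; 2D
    coordinates are the dot products of ``point - origin`` with each axis,
    an isometry of the plane (areas and distances are chart-invariant).
    """

    origin: np.ndarray
    u_hat: np.ndarray
    v_hat: np.ndarray

    def __post_init__(self):
        for name in ("origin", "u_hat", "v_hat"):
            object.__setattr__(self, name, as_point(getattr(self, name)))
        if abs(np.linalg.norm(self.u_hat) - 1) > 1e-9 or abs(
            np.linalg.norm(self.v_hat) - 1
        ) > 1e-9:
            raise ValueError("basis axes must be unit length")
        if abs(self.u_hat @ self.v_hat) > 1e-9:
            raise ValueError("basis axes must be orthogonal")

    @property
    def normal(self) -> np.ndarray:
        """Unit normal of the chart plane (u x v)."""
        n = np.cross(self.u_hat, self.v_hat)
        return n / np.linalg.norm(n)

    def to_3d(self, coords2d) -> np.ndarray:
        """Map ``(n, 2)`` chart coordinates back to 3D points on the plane."""
        xy = np.atleast_2d(np.asarray(coords2d, dtype=float))
        return self.origin + np.outer(xy[:, 0], self.u_hat) + np.outer(xy[:, 1], self.v_hat)


def build_plane_basis(points_on_plane) -> PlaneBasis:
    """Build a centroid-origin orthonormal chart from coplanar points.

    Following the classical construction: with centroid ``O``, take
    ``v = P1 - O`` and ``u = P2 - O``, form the plane normal ``w = u x v``,
    then ``u' = v x w`` which is perpendicular to ``v`` and in-plane; the
    normalized ``u'`` and ``v`` are the chart axes.

    Raises
    ------
    DegenerateBasisError
        If ``P1`` or ``P2`` coincides with the centroid, or ``O, P1, P2``
        are collinear.
    NotOnPlaneError
        If the points are not coplanar within ``COPLANARITY_ATOL``.
    """
    pts = as_points(points_on_plane)
    if len(pts) < 3:
        raise DegenerateBasisError("need at least 3 points to build a plane basis")
    origin = pts.mean(axis=0)
    v = pts[0] - origin
    u = pts[1] - origin
    if np.linalg.norm(v) < 1e-12 or np.linalg.norm(u) < 1e-12:
        raise DegenerateBasisError("a basis point coincides with the centroid")
    w = np.cross(u, v)
    if np.linalg.norm(w) <= 1e-12 * np.linalg.norm(u) * np.linalg.norm(v):
        raise DegenerateBasisError(
            "centroid and first two points are collinear; axes are undefined"
        )
    u_prime = np.cross(v, w)
    basis = PlaneBasis(
        origin=origin,
        u_hat=u_prime / np.linalg.norm(u_prime),
        v_hat=v / np.linalg.norm(v),
    )
    offsets = (pts - origin) @ basis.normal
    if np.max(np.abs(offsets)) > COPLANARITY_ATOL:
        raise NotOnPlaneError(
            f"points deviate from a common plane by up to "
            f"{np.max(np.abs(offsets)):.3g} mm (> {COPLANARITY_ATOL} mm)"
        )
    return basis


def to_plane_coords(points, basis: PlaneBasis, strict: bool = False) -> np.ndarray:
    """Map 3D points on the basis plane to ``(n, 2)`` chart coordinates.

    The chart is an isometry: all pairwise distances are preserved.  In
    strict mode, points farther than ``COPLANARITY_ATOL`` from the plane
    raise :class:`NotOnPlaneError`.
    """
    pts = as_points(points)
    rel = pts - basis.origin
    if strict:
        offsets = rel @ basis.normal
        bad = np.abs(offsets) > COPLANARITY_ATOL
        if np.any(bad):
            raise NotOnPlaneError(
                f"{int(bad.sum())} point(s) off the plane by up to "
                f"{np.max(np.abs(offsets)):.3g} mm"
            )
    return np.column_stack([rel @ basis.u_hat, rel @ basis.v_hat])


def is_simple_polygon(vertices2d) -> bool:
    """True when the ordered 2D vertices form a simple (non-self-intersecting) polygon."""
    xy = np.atleast_2d(np.asarray(vertices2d, dtype=float))
    if len(xy) < 3:
        return False
    return bool(_ShapelyPolygon(xy).is_valid)


def shoelace_area(vertices2d, strict: bool = False) -> float:
    """Enclosed area of an ordered simple polygon via the shoelace formula.

    Returns ``|½ Σ (xₙ yₙ₊₁ − yₙ xₙ₊₁)|``; the absolute value makes the
    result independent of the winding direction.  Correct for any simple
    polygon, including non-convex outlines — the reason it replaces the
    Heron fan in the cone-volume computation.

    Raises
    ------
    SelfIntersectionError
        In strict mode, when the polygon is not simple.
    """
    xy = np.atleast_2d(np.asarray(vertices2d, dtype=float))
    if xy.ndim != 2 or xy.shape[1] != 2 or len(xy) < 3:
        raise ValueError("polygon needs at least 3 vertices of shape (n, 2)")
    if strict and not is_simple_polygon(xy):
        raise SelfIntersectionError("polygon is self-intersecting")
    x, y = xy[:, 0], xy[:, 1]
    return float(abs(np.sum(x * np.roll(y, -1) - y * np.roll(x, -1))) / 2.0)


def heron_triangle_area(a: float, b: float, c: float, rtol: float = 1e-9) -> float:
    """Triangle area from side lengths via Heron's formula.

    Degenerate triangles (inequality tight within tolerance) return 0.

    Raises
    ------
    InvalidTriangleError
        If a side is negative or exceeds the sum of the others beyond
        ``rtol`` times the perimeter.
    """
    sides = sorted((float(a), float(b), float(c)))
    if sides[0] < 0:
        raise InvalidTriangleError(f"negative side length in ({a}, {b}, {c})")
    perimeter = sum(sides)
    tol = rtol * perimeter + 1e-300
    if sides[2] > sides[0] + sides[1] + tol:
        raise InvalidTriangleError(
            f"side lengths ({a}, {b}, {c}) violate the triangle inequality"
        )
    s = perimeter / 2.0
    prod = s * (s - sides[0]) * (s - sides[1]) * (s - sides[2])
    if prod <= 0.0:
        return 0.0
    return float(np.sqrt(prod))


def fan_triangulation_area(points, anchor_index: int = 0) -> float:
    """Legacy surgical-freedom area: Heron fan over (possibly 3D) vertices.

    The ordered ring is divided into triangles ``(anchor, i, i+1)`` over
    consecutive non-anchor vertices and the Heron areas are summed.  This
    reproduces the historical method *including* its biases: for a
    non-convex outline the fan can count area outside the polygon twice,
    and for non-coplanar vertices the tilted triangles sum to more than the
    perpendicular cross-section.  It never raises on such geometry (a
    warning is logged when the vertices are non-coplanar beyond
    ``COPLANARITY_ATOL``); use :func:`shoelace_area` on plane-translated
    points for the unbiased area.
    """
    pts = as_points(points)
    n = len(pts)
    if n < 3:
        raise ValueError("need at least 3 points for a fan triangulation")
    if not 0 <= anchor_index < n:
        raise ValueError(f"anchor_index {anchor_index} out of range for {n} points")
    if n > 3:
        centered = pts - pts.mean(axis=0)
        sv = np.linalg.svd(centered, compute_uv=False)
        if sv[2] > COPLANARITY_ATOL:
            logger.warning(
                "fan triangulation over non-coplanar points (out-of-plane extent "
                "%.3g mm); the summed Heron area overestimates the perpendicular "
                "cross-section",
                sv[2],
            )
    order = [(anchor_index + k) % n for k in range(1, n)]
    anchor = pts[anchor_index]
    total = 0.0
    for i, j in zip(order[:-1], order[1:]):
        pa, pb = pts[i], pts[j]
        total += heron_triangle_area(
            np.linalg.norm(pa - anchor),
            np.linalg.norm(pb - anchor),
            np.linalg.norm(pb - pa),
        )
    return float(total)
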