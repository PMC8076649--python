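"""Plane fitting and apex-ray projection: the spatial core of the cone model.

A surgical corridor is modeled as a cone whose apex sits on the surgical
target structure and whose base is the ring of instrument-extrema points.
Because the measured extrema are never exactly coplanar, the base plane is
the total-least-squares (TLS) best fit — the plane minimizing the sum of
squared *perpendicular* distances to the points.  This module provides:

* exact plane construction from three points,
* the "average plane" over all three-point subsets (the classical starting
  guess for the nonlinear fit),
* the nonlinear optimizer route and the closed-form TLS solution,
* translation of a plane to a fixed perpendicular distance from the apex
  (height normalization), and
* central projection of points onto a plane along apex rays, which preserves
  the cross-sectional profile of the cone.

All coordinates are in millimeters in an arbitrary fixed Cartesian frame
(e.g. neuronavigation stereotactic coordinates); every scalar this package
derives is invariant under rigid motions of that frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    AmbiguousSideError,
    CollinearPointsError,
    ConvergenceError,
    DegenerateConfigurationError,
    DegeneratePointError,
    RayParallelToPlaneError,
)

__all__ = [
    "Plane",
    "FitDiagnostics",
    "as_point",
    "as_points",
    "plane_from_three_points",
    "average_plane",
    "fit_plane_tls",
    "fit_plane_least_squares",
    "point_plane_distance",
    "perpendicular_height",
    "parallel_plane_at_height",
    "project_point_along_apex_ray",
    "project_points_along_apex_rays",
]

#: Scale-relative tolerance used to flag collinear point triples.
COLLINEARITY_RTOL = 1e-9

_UNIT_NORMAL_ATOL = 1e-12


def as_point(p) -> np.ndarray:
    """Coerce ``p`` to a finite float ``(3,)`` array (millimeters)."""
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"point has non-finite components: {a}")
    return a


def as_points(pts) -> np.ndarray:
    """Coerce ``pts`` to a finite float ``(n, 3)`` array."""
    a = np.atleast_2d(np.asarray(pts, dtype=float))
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"expected an (n, 3) array of points, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("point array has non-finite components")
    return a


@dataclass(frozen=True)
class Plane:
    """Implicit plane ``a*x + b*y + c*z + d = 0`` with a unit normal.

    ``(a, b, c)`` is the unit normal (dimensionless); ``d`` is the signed
    offset in millimeters.  With a unit normal, ``a*x + b*y + c*z + d`` is
    directly the signed perpendicular distance from ``(x, y, z)``.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        n = np.array([self.a, self.b, self.c], dtype=float)
        if not np.all(np.isfinite(n)) or not np.isfinite(self.d):
            raise ValueError("plane coefficients must be finite")
        if abs(n @ n - 1.0) > 1e-9:
            raise ValueError(
                "plane normal must be unit length; use Plane.from_normal_offset"
            )

    @classmethod
    def from_normal_offset(cls, normal, d: float) -> "Plane":
        """Build a plane from an arbitrary-length normal, renormalizing."""
        n = np.asarray(normal, dtype=float)
        norm = np.linalg.norm(n)
        if norm == 0.0 or not np.isfinite(norm):
            raise ValueError("plane normal must be nonzero and finite")
        n = n / norm
        return cls(float(n[0]), float(n[1]), float(n[2]), float(d / norm))

    @property
    def normal(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d])

    def signed_distance(self, p) -> float:
        """Signed perpendicular distance (mm); positive on the normal side."""
        p = as_point(p)
        return float(self.normal @ p + self.d)

    def signed_distances(self, pts) -> np.ndarray:
        return as_points(pts) @ self.normal + self.d

    def flipped(self) -> "Plane":
        """The same plane with the opposite normal orientation."""
        return Plane(-self.a, -self.b, -self.c, -self.d)


@dataclass(frozen=True)
class FitDiagnostics:
    """Diagnostics of a least-squares plane fit.

    ``sum_sq_perp_dist`` is the minimized objective Σ d_p² in mm²;
    ``n_triples_used`` counts the non-degenerate three-point subsets that
    contributed to the averaged initial plane (0 when the initial plane was
    supplied by the caller).
    """

    sum_sq_perp_dist: float
    n_points: int
    converged: bool
    n_triples_used: int


def plane_from_three_points(p1, p2, p3) -> Plane:
    """Plane through three points via the cross product of two edge vectors.

    The normal is ``(p2 - p1) x (p3 - p1)`` normalized; the offset follows
    from substituting ``p1`` into the plane equation.

    Raises
    ------
    CollinearPointsError
        If the cross-product norm is below ``COLLINEARITY_RTOL`` times the
        product of the two edge lengths (scale-aware degeneracy test).
    """
    p1, p2, p3 = as_point(p1), as_point(p2), as_point(p3)
    e1 = p2 - p1
    e2 = p3 - p1
    n = np.cross(e1, e2)
    scale = np.linalg.norm(e1) * np.linalg.norm(e2)
    if np.linalg.norm(n) <= COLLINEARITY_RTOL * scale or scale == 0.0:
        raise CollinearPointsError(
            f"points are collinear within tolerance: {p1}, {p2}, {p3}"
        )
    return Plane.from_normal_offset(n, -float(n @ p1))


def _triple_planes(points: np.ndarray):
    """Unit-normalized planes of every non-collinear 3-point combination."""
    planes = []
    for i, j, k in combinations(range(len(points)), 3):
        try:
            planes.append(plane_from_three_points(points[i], points[j], points[k]))
        except CollinearPointsError:
            continue
    return planes


def average_plane(points, apex=None, return_count: bool = False):
    """Average of the planes through all three-point subsets of ``points``.

    Each triple plane is unit-normalized and orientation-aligned before
    averaging: naive averaging would cancel normals of opposite sign, since
    the cross product of a triple is sign-ambiguous.  When ``apex`` is given,
    normals are flipped to point from the apex toward the centroid of the
    points; otherwise they are aligned with the first non-degenerate triple.
    The averaged coefficients are renormalized to a unit normal.

    This is the classical starting guess for the nonlinear perpendicular
    least-squares fit (see :func:`fit_plane_least_squares`).
    """
    pts = as_points(points)
    if len(pts) < 3:
        raise DegenerateConfigurationError("need at least 3 points to average planes")
    planes = _triple_planes(pts)
    if not planes:
        raise DegenerateConfigurationError("every 3-point subset is collinear")

    if apex is not None:
        ref = pts.mean(axis=0) - as_point(apex)
        if np.linalg.norm(ref) < 1e-12:
            ref = planes[0].normal
    else:
        ref = planes[0].normal

    coeffs = np.empty((len(planes), 4))
    for row, pl in enumerate(planes):
        c = pl.coefficients
        if c[:3] @ ref < 0:
            c = -c
        coeffs[row] = c
    mean = coeffs.mean(axis=0)
    if np.linalg.norm(mean[:3]) < 1e-12:
        raise DegenerateConfigurationError(
            "averaged plane normal vanished; point configuration is degenerate"
        )
    plane = Plane.from_normal_offset(mean[:3], mean[3])
    if return_count:
        return plane, len(planes)
    return plane


def _check_not_collinear_cloud(pts: np.ndarray) -> np.ndarray:
    """Singular values of the centered cloud; reject collinear clouds."""
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[0] == 0.0 or s[1] <= 1e-9 * s[0]:
        raise DegenerateConfigurationError(
            "points are collinear: the best-fit plane is not unique"
        )
    return s


def fit_plane_tls(points) -> tuple[Plane, float]:
    """Closed-form total-least-squares plane of a point cloud.

    The optimal plane passes through the centroid with normal along the
    smallest principal direction of the centered scatter matrix; the
    minimized objective equals the squared smallest singular value.

    Returns ``(plane, sum_sq_perp_dist)``.
    """
    pts = as_points(points)
    if len(pts) < 3:
        raise DegenerateConfigurationError("need at least 3 points to fit a plane")
    _check_not_collinear_cloud(pts)
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[2]
    plane = Plane.from_normal_offset(normal, -float(normal @ centroid))
    return plane, float(s[2] ** 2)


def _rotation_to_x_axis(n: np.ndarray) -> np.ndarray:
    """Rotation matrix Q with Q @ n = (1, 0, 0) for a unit vector ``n``."""
    helper = np.array([0.0, 0.0, 1.0])
    if abs(n @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e2 = np.cross(n, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(n, e2)
    return np.vstack([n, e2, e3])


def _angles_to_normal(theta: float, phi: float) -> np.ndarray:
    st = np.sin(theta)
    return np.array([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])


def fit_plane_least_squares(
    points, init: Plane | None = None, rtol: float = 1e-9
) -> tuple[Plane, FitDiagnostics]:
    """Best-fit plane by nonlinear minimization of Σ (perpendicular distance)².

    The plane is parameterized on a 3-parameter chart — spherical angles of
    the unit normal plus the signed offset — and optimized with a
    Levenberg–Marquardt-style least-squares solver seeded from ``init`` (or
    from :func:`average_plane` when ``init`` is omitted).  The result is
    accepted only if its objective matches the closed-form TLS optimum
    (:func:`fit_plane_tls`) within ``rtol`` relative; otherwise
    :class:`ConvergenceError` is raised.  The returned normal is oriented to
    agree with the initial plane's normal.

    Raises
    ------
    DegenerateConfigurationError
        If the cloud is collinear (the optimum plane is not unique).
    ConvergenceError
        If the optimizer misses the closed-form optimum beyond tolerance.
    """
    pts = as_points(points)
    if len(pts) < 3:
        raise DegenerateConfigurationError("need at least 3 points to fit a plane")
    s = _check_not_collinear_cloud(pts)

    n_triples = 0
    if init is None:
        init, n_triples = average_plane(pts, return_count=True)

    # Work in a rotated frame where the initial normal sits at the equator of
    # the spherical chart (theta = pi/2, phi = 0), far from the chart's polar
    # degeneracy; the offset d is rotation-invariant.
    chart = _rotation_to_x_axis(init.normal)
    pts_rot = pts @ chart.T
    x0 = np.array([np.pi / 2, 0.0, init.d])

    def residuals(x):
        n = _angles_to_normal(x[0], x[1])
        return pts_rot @ n + x[2]

    def jacobian(x):
        theta, phi = x[0], x[1]
        dn_dtheta = np.array(
            [np.cos(theta) * np.cos(phi), np.cos(theta) * np.sin(phi), -np.sin(theta)]
        )
        dn_dphi = np.array(
            [-np.sin(theta) * np.sin(phi), np.sin(theta) * np.cos(phi), 0.0]
        )
        return np.column_stack(
            [pts_rot @ dn_dtheta, pts_rot @ dn_dphi, np.ones(len(pts_rot))]
        )

    opts = dict(jac=jacobian, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15,
                max_nfev=5000)
    sol = least_squares(residuals, x0, **opts)
    # One polish restart: resets the trust-region scaling, which helps on
    # nearly isotropic clouds where the objective valley is very flat.
    sol = least_squares(residuals, sol.x, **opts)
    normal = chart.T @ _angles_to_normal(sol.x[0], sol.x[1])
    d = float(sol.x[2])
    if normal @ init.normal < 0:
        normal, d = -normal, -d
    plane = Plane.from_normal_offset(normal, d)

    objective = float(np.sum(plane.signed_distances(pts) ** 2))
    _, optimum = fit_plane_tls(pts)
    # Absolute floor covers exactly coplanar clouds, where the optimum is zero
    # up to rounding of coordinates of magnitude s[0].
    slack = rtol * optimum + 1e3 * len(pts) * (np.finfo(float).eps * s[0]) ** 2
    if objective > optimum + slack:
        raise ConvergenceError(
            f"optimizer objective {objective:.6e} mm² exceeds the closed-form "
            f"total-least-squares optimum {optimum:.6e} mm² beyond tolerance"
        )
    diag = FitDiagnostics(
        sum_sq_perp_dist=objective,
        n_points=len(pts),
        converged=True,
        n_triples_used=n_triples,
    )
    return plane, diag


def point_plane_distance(p, plane: Plane) -> float:
    """Unsigned perpendicular distance from ``p`` to ``plane`` in mm."""
    return abs(plane.signed_distance(p))


def perpendicular_height(base: Plane, apex) -> float:
    """Perpendicular height of the cone: apex-to-base-plane distance (mm)."""
    return point_plane_distance(apex, base)


def parallel_plane_at_height(base: Plane, apex, h_norm: float) -> Plane:
    """Translate ``base`` parallel to itself to distance ``h_norm`` from ``apex``.

    The translated plane keeps the base's normal and lies on the same side of
    the apex as the base plane, so the normalized base stays toward the
    measured extrema.  This is the height-normalization step: the cone's
    cross-section is then taken at a fixed perpendicular distance from the
    apex regardless of the probe length used during measurement.

    Raises
    ------
    AmbiguousSideError
        If the base plane passes through the apex (no side is defined).
    """
    if not h_norm > 0:
        raise ValueError(f"normalized height must be positive, got {h_norm}")
    apex = as_point(apex)
    sd = base.signed_distance(apex)
    if abs(sd) < 1e-12:
        raise AmbiguousSideError(
            "base plane passes through the apex; translation side is undefined"
        )
    side = np.sign(sd)
    d_norm = float(side * h_norm - base.normal @ apex)
    return Plane(base.a, base.b, base.c, d_norm)


def project_point_along_apex_ray(p, apex, target: Plane) -> np.ndarray:
    """Translate ``p`` onto ``target`` along the ray from ``apex`` through ``p``.

    The intersection parameter solves the ray–plane equation
    ``s = -(n·apex + d) / (n·(p - apex))`` and the image is
    ``apex + s (p - apex)``.  Central projection from the apex preserves the
    cross-sectional profile of the cone, which is why the corridor base can
    be re-cut at any normalized height without distorting its shape.
    """
    p, apex = as_point(p), as_point(apex)
    ray = p - apex
    ray_norm = np.linalg.norm(ray)
    if ray_norm < 1e-12:
        raise DegeneratePointError("point coincides with the apex")
    denom = float(target.normal @ ray)
    if abs(denom) <= 1e-12 * ray_norm:
        raise RayParallelToPlaneError(
            "apex ray is parallel to the target plane; no intersection"
        )
    s = -(float(target.normal @ apex) + target.d) / denom
    return apex + s * ray


def project_points_along_apex_rays(points, apex, target: Plane) -> np.ndarray:
    """Vectorized :func:`project_point_along_apex_ray` over an ``(n, 3)`` array."""
    pts = as_points(points)
    apex = as_point(apex)
    rays = pts - apex
    norms = np.linalg.norm(rays, axis=1)
    if np.any(norms < 1e-12):
        raise DegeneratePointError("a point coincides with the apex")
    denom = rays @ target.normal
    if np.any(np.abs(denom) <= 1e-12 * norms):
        raise RayParallelToPlaneError(
            "an apex ray is parallel to the target plane; no intersection"
        )
    s = -(float(target.normal @ apex) + target.d) / denom
    return apex + s[:, None] * rays
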