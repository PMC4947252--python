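"""Exact 3-D primitives used by every measurement.

Planes, axis lines, angles, signed distances, and the least-squares cylinder
fit that defines the humeral shaft axis.  Everything works in millimetres in
an arbitrary right-handed frame; all operations are equivariant under rigid
motion (rotations/translations of the inputs rotate/translate the outputs,
scalar outputs are unchanged).

``Point3`` is simply a length-3 ``numpy.ndarray`` of finite floats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import ConvergenceError, CylinderFitError, DegenerateGeometryError

__all__ = [
    "Point3",
    "AxisLine",
    "Plane",
    "CylinderFit",
    "plane_from_three_points",
    "point_plane_signed_distance",
    "line_plane_angle",
    "fit_cylinder_axis",
    "plane_plane_intersection",
    "axial_coordinate",
    "canonical_direction",
]

#: degeneracy threshold in mm-scaled coordinates
EPS = 1e-9

Point3 = np.ndarray


def as_point(p) -> np.ndarray:
    """Coerce to a finite (3,) float array."""
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise DegenerateGeometryError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise DegenerateGeometryError("non-finite coordinates")
    return a


def unit(v) -> np.ndarray:
    v = as_point(v)
    n = float(np.linalg.norm(v))
    if n < EPS:
        raise DegenerateGeometryError("zero-length direction vector")
    return v / n


def canonical_direction(d: np.ndarray) -> np.ndarray:
    """Flip ``d`` so its largest-magnitude component is positive.

    Pure geometry has no notion of "toward the head"; this deterministic sign
    rule makes fits reproducible.  The morphometry layer re-orients axes
    head-ward using the articular region.
    """
    d = unit(d)
    k = int(np.argmax(np.abs(d)))
    return -d if d[k] < 0 else d


@dataclass(frozen=True)
class AxisLine:
    """A line through ``origin`` with unit ``direction`` (the shaft axis)."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", as_point(self.origin))
        d = as_point(self.direction)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            d = unit(d)
        object.__setattr__(self, "direction", d)

    @classmethod
    def through(cls, a, b) -> "AxisLine":
        a, b = as_point(a), as_point(b)
        return cls(a, unit(b - a))

    def point_at(self, t: float) -> np.ndarray:
        return self.origin + float(t) * self.direction

    def distance_to(self, points) -> np.ndarray:
        """Radial distance(s) from point(s) to the line."""
        p = np.atleast_2d(np.asarray(points, dtype=float)) - self.origin
        t = p @ self.direction
        radial = p - np.outer(t, self.direction)
        d = np.linalg.norm(radial, axis=1)
        return d if d.size > 1 else float(d[0])


@dataclass(frozen=True)
class Plane:
    """A plane through ``point`` with unit ``normal``."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", as_point(self.point))
        n = as_point(self.normal)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            n = unit(n)
        object.__setattr__(self, "normal", n)

    def flipped(self) -> "Plane":
        return Plane(self.point, -self.normal)


@dataclass(frozen=True)
class CylinderFit:
    """Result of the least-squares cylinder fit."""

    axis: AxisLine
    radius: float
    rms_residual: float
    n_points: int

    def __post_init__(self):
        if not self.radius > 0:
            raise CylinderFitError(f"non-positive fitted radius {self.radius}")
        if self.rms_residual < 0:
            raise CylinderFitError("negative rms residual")


def plane_from_three_points(p1, p2, p3) -> Plane:
    """Plane through three non-collinear points (e.g. landmarks C, D, E)."""
    p1, p2, p3 = as_point(p1), as_point(p2), as_point(p3)
    n = np.cross(p2 - p1, p3 - p1)
    # |n| = twice the triangle area
    if np.linalg.norm(n) < 2e-9:
        raise DegenerateGeometryError(
            "collinear or coincident points cannot define a plane"
        )
    return Plane(p1, unit(n))


def point_plane_signed_distance(p, plane: Plane) -> float:
    """(p - plane.point) . normal; sign follows the plane normal."""
    return float((as_point(p) - plane.point) @ plane.normal)


def points_plane_signed_distance(points, plane: Plane) -> np.ndarray:
    """Vectorised signed distances for an (n, 3) array."""
    pts = np.asarray(points, dtype=float)
    return (pts - plane.point) @ plane.normal


def line_plane_angle(line: AxisLine, plane: Plane) -> float:
    """Acute angle between a line and a plane, in degrees within [0, 90]."""
    s = abs(float(line.direction @ plane.normal))
    return float(np.degrees(np.arcsin(min(1.0, s))))


def plane_plane_intersection(a: Plane, b: Plane) -> AxisLine:
    """Intersection line of two non-parallel planes."""
    d = np.cross(a.normal, b.normal)
    nd = np.linalg.norm(d)
    if nd < EPS:
        raise DegenerateGeometryError("parallel planes do not intersect in a line")
    d = d / nd
    # closed-form point: combination of the two normals satisfying both offsets
    da = float(a.normal @ a.point)
    db = float(b.normal @ b.point)
    c = float(a.normal @ b.normal)
    denom = 1.0 - c * c
    ka = (da - c * db) / denom
    kb = (db - c * da) / denom
    origin = ka * a.normal + kb * b.normal
    return AxisLine(origin, d)


def axial_coordinate(p, axis: AxisLine) -> float:
    """Height of a point along an axis: (p - origin) . direction, in mm."""
    return float((as_point(p) - axis.origin) @ axis.direction)


def axial_coordinates(points, axis: AxisLine) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    return (pts - axis.origin) @ axis.direction


# ---------------------------------------------------------------------------
# least-squares cylinder fit
# ---------------------------------------------------------------------------


def _principal_direction(points: np.ndarray) -> np.ndarray:
    c = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - c, full_matrices=False)
    return vt[0]


def _orthobasis(d: np.ndarray):
    """Two unit vectors spanning the plane perpendicular to ``d``."""
    a = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = unit(np.cross(d, a))
    e2 = np.cross(d, e1)
    return e1, e2


def fit_cylinder_axis(
    points,
    initial_axis=None,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> CylinderFit:
    """Fit an infinite circular cylinder to a point cloud.

    Minimises the sum of squared radial residuals
    ``sum_i (dist_to_axis(p_i) - r)**2`` over the five cylinder parameters
    (two for orientation, two for axis position, one radius), starting from
    the principal component of the cloud (the shaft is elongated).  The
    returned axis origin is the centroid projected onto the fitted axis and
    the direction sign is canonicalised (largest component positive).

    Raises
    ------
    CylinderFitError
        Fewer than 6 points, or a degenerate (flat / short) cloud.
    ConvergenceError
        Solver failure; carries the last iterate.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise CylinderFitError(f"expected an (n, 3) point array, got {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise CylinderFitError("non-finite coordinates in point cloud")
    n = pts.shape[0]
    if n < 6:
        raise CylinderFitError(f"need at least 6 points for a cylinder fit, got {n}")

    centroid = pts.mean(axis=0)
    sv = np.linalg.svd(pts - centroid, compute_uv=False)
    if sv[2] < 1e-9 * max(sv[0], 1.0):
        raise CylinderFitError(
            "point cloud is coplanar; a cylinder axis is not identifiable"
        )
    d0 = unit(initial_axis) if initial_axis is not None else _principal_direction(pts)
    e1, e2 = _orthobasis(d0)

    axis0 = AxisLine(centroid, d0)
    r0 = float(np.mean(axis0.distance_to(pts)))
    if r0 < EPS:
        raise CylinderFitError("points are collinear along the initial axis")
    extent = float(np.ptp((pts - centroid) @ d0))
    if extent <= 0.5 * r0:
        raise CylinderFitError(
            f"axial extent {extent:.3g} mm too short relative to radius {r0:.3g} mm"
        )

    def unpack(x):
        a, b, u, v, r = x
        d = unit(d0 + a * e1 + b * e2)
        c = centroid + u * e1 + v * e2
        return c, d, r

    def residuals(x):
        c, d, r = unpack(x)
        q = pts - c
        t = q @ d
        radial = np.linalg.norm(q - np.outer(t, d), axis=1)
        return radial - r

    x0 = np.array([0.0, 0.0, 0.0, 0.0, r0])
    sol = least_squares(
        residuals,
        x0,
        method="lm",
        xtol=tol,
        ftol=tol,
        gtol=tol,
        max_nfev=max_iter * 6,
    )
    if not sol.success and not np.all(np.isfinite(sol.x)):
        raise ConvergenceError(
            f"cylinder fit did not converge: {sol.message}", last_iterate=sol.x
        )

    c, d, r = unpack(sol.x)
    if r <= 0:
        raise ConvergenceError(
            f"cylinder fit collapsed to non-positive radius {r}", last_iterate=sol.x
        )
    d = canonical_direction(d)
    # park the origin at the centroid's foot on the axis
    c = c + ((centroid - c) @ d) * d
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return CylinderFit(axis=AxisLine(c, d), radius=float(r), rms_residual=rms, n_points=n)
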