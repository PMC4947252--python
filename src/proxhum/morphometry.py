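"""Three-dimensional measurement of the proximal humerus.

Implements the landmark/plane measurement scheme end-to-end.  The inputs
are a labelled surface mesh and the three manually placed landmarks:

* ``C`` — most superior point of the articular surface,
* ``D`` — most inferior point of the articular surface,
* ``E`` — a point on the concave portion of the articular surface.

From these the pipeline constructs the anatomic neck plane (plane 1,
through C/D/E, normal toward the articular centroid), the humeral shaft
axis (least-squares cylinder fit of the shaft region, oriented head-ward),
plane 2 (through the most superior articular point G, perpendicular to the
shaft axis) and plane 3 (through the midpoint of CD, normal parallel to
CD).  Derived landmarks:

* ``F`` — articular point furthest above plane 1,
* ``G`` / ``H`` — most superior articular / greater-tuberosity points,
* ``I`` / ``J`` — intersection of planes 1 and 3 with the articular rim.

and the five anatomic parameters:

* NSA = alpha + 90 deg, alpha the angle between plane 1 and the shaft axis,
* HHT = perpendicular distance F -> plane 1,
* TSH = axial offset between G and H (positive when the head is proud),
* cASD = |C - D| (coronal articular diameter),
* aASD = |I - J| (axial articular diameter).

All measurements are pose-invariant: no global coordinate convention is
assumed beyond millimetre units.
"""

from __future__ import annotations

import contextlib
from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
import trimesh as _trimesh

from .errors import (
    DegenerateGeometryError,
    MissingRegionError,
    NoIntersectionError,
    OrientationError,
    ProxhumError,
)
from .geometry import (
    AxisLine,
    CylinderFit,
    Plane,
    as_point,
    axial_coordinate,
    axial_coordinates,
    fit_cylinder_axis,
    plane_from_three_points,
    plane_plane_intersection,
    line_plane_angle,
    point_plane_signed_distance,
    points_plane_signed_distance,
    unit,
)
from .mesh import LandmarkSet, TriangleMesh

__all__ = [
    "MorphometryResult",
    "derive_shaft_axis",
    "neck_plane",
    "locate_point_F",
    "neck_shaft_angle",
    "head_thickness",
    "locate_points_G_H",
    "tuberosity_height",
    "coronal_diameter",
    "axial_diameter",
    "measure_proximal_humerus",
]


@dataclass(frozen=True)
class MorphometryResult:
    """The five 3-D parameters plus intermediates of one specimen."""

    nsa_deg: float
    alpha_deg: float
    hht_mm: float
    tsh_mm: float
    casd_mm: float
    aasd_mm: float
    shaft_axis: AxisLine
    shaft_fit: CylinderFit
    neck_plane: Plane
    landmarks: LandmarkSet

    def __post_init__(self):
        assert abs(self.nsa_deg - (self.alpha_deg + 90.0)) < 1e-12
        if not 90.0 <= self.nsa_deg <= 180.0:
            raise OrientationError(f"NSA {self.nsa_deg:.2f} outside [90, 180] deg")
        if self.hht_mm < 0 or self.casd_mm <= 0 or self.aasd_mm <= 0:
            raise OrientationError("negative head thickness or diameter")

    def as_dict(self) -> dict:
        lm = self.landmarks
        out = {
            "nsa_deg": self.nsa_deg,
            "alpha_deg": self.alpha_deg,
            "hht_mm": self.hht_mm,
            "tsh_mm": self.tsh_mm,
            "casd_mm": self.casd_mm,
            "aasd_mm": self.aasd_mm,
            "shaft_radius_mm": self.shaft_fit.radius,
            "shaft_fit_rms_mm": self.shaft_fit.rms_residual,
            "shaft_fit_n_points": self.shaft_fit.n_points,
        }
        for axis_part, vec in (
            ("shaft_origin", self.shaft_axis.origin),
            ("shaft_dir", self.shaft_axis.direction),
        ):
            for c, v in zip("xyz", vec):
                out[f"{axis_part}_{c}"] = float(v)
        for name in "CDEFGHIJ":
            p = getattr(lm, name, None)
            if p is not None:
                for c, v in zip("xyz", p):
                    out[f"{name}_{c}"] = float(v)
        return out


@contextlib.contextmanager
def _stage(name: str):
    """Annotate errors with the measurement stage that raised them."""
    try:
        yield
    except ProxhumError as e:
        try:
            exc = type(e)(f"stage '{name}': {e}")
        except TypeError:  # exceptions with extra constructor args
            exc = e
        raise exc from e


def derive_shaft_axis(
    mesh: TriangleMesh,
    axial_window: Optional[Tuple[float, float]] = None,
) -> CylinderFit:
    """Cylinder-fit the shaft region; axis oriented toward the head.

    If the mesh has no ``shaft`` labels, ``axial_window`` (mm along the
    principal axis of the whole bone, measured from the centroid) selects
    the shaft band instead.
    """
    shaft_idx = mesh.region_indices("shaft")
    if shaft_idx.size:
        pts = mesh.vertices[shaft_idx]
        if axial_window is not None:
            pts = _window(pts, axial_window)
    elif axial_window is not None:
        pts = _window(mesh.vertices, axial_window)
    else:
        raise MissingRegionError(
            "region 'shaft' has no labelled vertices and no axial_window given"
        )
    fit = fit_cylinder_axis(pts)

    artic_idx = mesh.region_indices("articular_surface")
    if artic_idx.size:
        head_centroid = mesh.vertices[artic_idx].mean(axis=0)
        if axial_coordinate(head_centroid, fit.axis) < 0:
            fit = replace(
                fit, axis=AxisLine(fit.axis.origin, -fit.axis.direction)
            )
    return fit


def _window(points: np.ndarray, window: Tuple[float, float]) -> np.ndarray:
    """Select points by coordinate (mm, from the centroid) along the
    canonicalised principal axis of the cloud."""
    from .geometry import canonical_direction

    lo, hi = window
    c = points.mean(axis=0)
    centred = points - c
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    t = centred @ canonical_direction(vt[0])
    sel = (t >= lo) & (t <= hi)
    return points[sel]


def neck_plane(landmarks: LandmarkSet, mesh: Optional[TriangleMesh] = None) -> Plane:
    """Anatomic neck plane through C, D, E, normal toward the head.

    When a labelled mesh is supplied the normal is oriented toward the
    articular centroid so head-side distances come out positive.
    """
    plane = plane_from_three_points(landmarks.C, landmarks.D, landmarks.E)
    if mesh is not None:
        centroid = mesh.region_vertices(
            "articular_surface", required_by="neck_plane orientation"
        ).mean(axis=0)
        if point_plane_signed_distance(centroid, plane) < 0:
            plane = plane.flipped()
    return plane


def locate_point_F(mesh: TriangleMesh, plane1: Plane) -> np.ndarray:
    """Articular vertex furthest above plane 1 (ties: lowest vertex index)."""
    idx = mesh.region_indices("articular_surface")
    if idx.size == 0:
        raise MissingRegionError(
            "region 'articular_surface' has no labelled vertices (required by point F)"
        )
    d = points_plane_signed_distance(mesh.vertices[idx], plane1)
    best = int(np.argmax(d))
    if d[best] < 0:
        raise OrientationError(
            "all articular vertices lie below plane 1; is the neck plane "
            "oriented toward the head?"
        )
    return mesh.vertices[idx[best]].copy()


def neck_shaft_angle(plane1: Plane, shaft_axis: AxisLine) -> Tuple[float, float]:
    """Head inclination alpha and NSA = alpha + 90 (degrees)."""
    alpha = line_plane_angle(shaft_axis, plane1)
    return alpha, alpha + 90.0


def head_thickness(mesh: TriangleMesh, plane1: Plane) -> float:
    """HHT: perpendicular distance from point F to plane 1 (mm, >= 0)."""
    F = locate_point_F(mesh, plane1)
    return point_plane_signed_distance(F, plane1)


def locate_points_G_H(
    mesh: TriangleMesh, shaft_axis: AxisLine
) -> Tuple[np.ndarray, np.ndarray]:
    """Most superior articular point (G) and greater-tuberosity point (H).

    "Superior" means the largest axial coordinate along the head-ward
    shaft axis; ties resolve to the lowest vertex index.
    """
    out = []
    for region, label in (
        ("articular_surface", "point G"),
        ("greater_tuberosity", "point H"),
    ):
        idx = mesh.region_indices(region)
        if idx.size == 0:
            raise MissingRegionError(
                f"region '{region}' has no labelled vertices (required by {label})"
            )
        t = axial_coordinates(mesh.vertices[idx], shaft_axis)
        out.append(mesh.vertices[idx[int(np.argmax(t))]].copy())
    return out[0], out[1]


def tuberosity_height(G, H, shaft_axis: AxisLine) -> float:
    """TSH: axial offset of G above H, signed (mm).

    Plane 2 is taken perpendicular to the shaft axis through G, so the
    perpendicular distance from H to plane 2 is the difference of axial
    coordinates; positive when the articular surface is proud of the
    tuberosity.
    """
    return axial_coordinate(as_point(G), shaft_axis) - axial_coordinate(
        as_point(H), shaft_axis
    )


def coronal_diameter(C, D) -> float:
    """cASD: Euclidean distance between landmarks C and D (mm)."""
    C, D = as_point(C), as_point(D)
    dist = float(np.linalg.norm(C - D))
    if dist < 1e-9:
        raise DegenerateGeometryError("landmarks C and D coincide")
    return dist


def axial_diameter(
    mesh: TriangleMesh, plane1: Plane, C, D
) -> Tuple[float, np.ndarray, np.ndarray]:
    """aASD: diameter of the articular rim in the axial plane.

    Plane 3 passes through the midpoint of CD with normal parallel to CD;
    its intersection line with plane 1 crosses the articular surface at
    the rim.  The crossing points are found by sectioning the
    articular-labelled faces with plane 3 and taking the extreme section
    points along the intersection line; returns (aASD, I, J).
    """
    C, D = as_point(C), as_point(D)
    mid = 0.5 * (C + D)
    plane3 = Plane(mid, unit(D - C))
    line = plane_plane_intersection(plane1, plane3)

    faces = mesh.region_faces("articular_surface")
    if faces.size == 0:
        raise MissingRegionError(
            "no faces fully inside region 'articular_surface' (required by aASD)"
        )
    sub = _trimesh.Trimesh(vertices=mesh.vertices, faces=faces, process=False)
    segments = _trimesh.intersections.mesh_plane(
        sub, plane_normal=plane3.normal, plane_origin=plane3.point
    )
    if len(segments) == 0:
        raise NoIntersectionError(
            "plane 3 does not intersect the articular surface"
        )
    pts = np.asarray(segments, dtype=float).reshape(-1, 3)
    t = (pts - line.origin) @ line.direction
    I = pts[int(np.argmin(t))].copy()
    J = pts[int(np.argmax(t))].copy()
    aasd = float(np.linalg.norm(I - J))
    if aasd < 1e-9:
        raise NoIntersectionError(
            "plane 1/plane 3 intersection only grazes the articular surface"
        )
    return aasd, I, J


def measure_proximal_humerus(
    mesh: TriangleMesh,
    landmarks: LandmarkSet,
    axial_window: Optional[Tuple[float, float]] = None,
) -> MorphometryResult:
    """Run the complete 3-D measurement on one labelled specimen."""
    with _stage("shaft_axis"):
        fit = derive_shaft_axis(mesh, axial_window=axial_window)
    axis = fit.axis
    with _stage("neck_plane"):
        plane1 = neck_plane(landmarks, mesh)
    alpha, nsa = neck_shaft_angle(plane1, axis)
    with _stage("point_F"):
        F = locate_point_F(mesh, plane1)
    hht = point_plane_signed_distance(F, plane1)
    with _stage("points_G_H"):
        G, H = locate_points_G_H(mesh, axis)
    tsh = tuberosity_height(G, H, axis)
    with _stage("coronal_diameter"):
        casd = coronal_diameter(landmarks.C, landmarks.D)
    with _stage("axial_diameter"):
        aasd, I, J = axial_diameter(mesh, plane1, landmarks.C, landmarks.D)

    lm = replace(landmarks, F=F, G=G, H=H, I=I, J=J)
    return MorphometryResult(
        nsa_deg=nsa,
        alpha_deg=alpha,
        hht_mm=hht,
        tsh_mm=tsh,
        casd_mm=casd,
        aasd_mm=aasd,
        shaft_axis=axis,
        shaft_fit=fit,
        neck_plane=plane1,
        landmarks=lm,
    )
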