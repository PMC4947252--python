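"""Simulated anteroposterior radiographs and their 2-D measurements.

A radiograph is modelled as an orthographic projection of the bone onto
the coronal plane followed by a uniform film-magnification factor
(default 1.10, typical of shoulder AP films, where the humerus sits well
in front of the detector).  Divergence/obliquity of the beam is not
modelled, so projected angles are unchanged while every projected
distance is scaled by the magnification — which is exactly the size bias
radiographic measurements show against 3-D CT.

The 2-D re-measurements mirror the film conventions:

* line 2 (2-D shaft axis) — least-squares midline of the left/right
  shaft silhouette edges,
* the anatomic neck — the projected C--D segment,
* NSA2 — 90 deg plus the acute angle between the neck segment and line 2,
* HHT2 — largest perpendicular distance from the projected head surface
  to the neck segment,
* TSH2 — axial gap between the tangents at the projected G and H,
* cASD2 — length of the projected neck segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import shapely

from .errors import (
    DegenerateGeometryError,
    MissingRegionError,
    ProxhumError,
)
from .geometry import unit
from .mesh import LandmarkSet, TriangleMesh

__all__ = ["Silhouette2D", "RadiographResult", "project_to_coronal", "measure_radiographic"]


@dataclass
class Silhouette2D:
    """Projection of a bone onto a 2-D image plane (mm, magnified).

    ``polygon`` is the simple boundary polygon of the union of projected
    front-facing triangles; ``points`` are all projected vertices with
    their region labels, and ``landmarks`` the projected anatomic points.
    """

    polygon: "shapely.Polygon"
    points: np.ndarray
    labels: np.ndarray
    landmarks: dict
    view_direction: np.ndarray
    u_h: np.ndarray
    u_v: np.ndarray
    magnification: float = 1.0

    def __post_init__(self):
        if self.polygon is not None:
            if (
                not self.polygon.is_valid
                or len(self.polygon.exterior.coords) < 4
            ):
                raise DegenerateGeometryError("silhouette polygon is degenerate")

    def region_points(self, name: str) -> np.ndarray:
        pts = self.points[self.labels == name]
        if len(pts) == 0:
            raise MissingRegionError(
                f"region '{name}' has no projected vertices"
            )
        return pts


@dataclass(frozen=True)
class RadiographResult:
    """The four radiographic parameters of one simulated AP film."""

    nsa2_deg: float
    hht2_mm: float
    tsh2_mm: float
    casd2_mm: float
    shaft_point: np.ndarray = field(default=None, repr=False)
    shaft_direction: np.ndarray = field(default=None, repr=False)

    def as_dict(self) -> dict:
        return {
            "nsa2_deg": self.nsa2_deg,
            "hht2_mm": self.hht2_mm,
            "tsh2_mm": self.tsh2_mm,
            "casd2_mm": self.casd2_mm,
        }


def anteroposterior_view(mesh: TriangleMesh, landmarks: LandmarkSet) -> np.ndarray:
    """Intrinsic AP viewing direction: perpendicular to the shaft axis and
    to the C--D (superoinferior neck) direction."""
    shaft = mesh.region_vertices("shaft", required_by="AP view")
    c = shaft.mean(axis=0)
    _, _, vt = np.linalg.svd(shaft - c, full_matrices=False)
    axis = vt[0]
    return unit(np.cross(axis, landmarks.C - landmarks.D))


def project_to_coronal(
    mesh: TriangleMesh,
    view_direction=None,
    landmarks: Optional[LandmarkSet] = None,
    up=None,
    magnification: float = 1.10,
    build_polygon: bool = True,
) -> Silhouette2D:
    """Orthographic projection of the bone onto the plane normal to
    ``view_direction``, scaled by the film magnification.

    ``up`` fixes the image vertical (defaults to the principal axis of
    the shaft region, oriented head-ward); ``view_direction`` defaults to
    the intrinsic AP view and must not be parallel to the shaft axis.
    """
    if view_direction is None:
        if landmarks is None:
            raise DegenerateGeometryError(
                "view_direction or landmarks (for the AP default) required"
            )
        view = anteroposterior_view(mesh, landmarks)
    else:
        view = unit(view_direction)

    if up is None:
        shaft = mesh.region_vertices("shaft", required_by="projection vertical")
        c = shaft.mean(axis=0)
        _, _, vt = np.linalg.svd(shaft - c, full_matrices=False)
        up = vt[0]
        artic = mesh.region_indices("articular_surface")
        if artic.size and (mesh.vertices[artic].mean(axis=0) - c) @ up < 0:
            up = -up
    up = unit(up)
    s = np.linalg.norm(np.cross(view, up))
    if s < 1e-3:
        raise DegenerateGeometryError(
            "view direction is (nearly) parallel to the shaft axis"
        )
    u_v = unit(up - (up @ view) * view)
    u_h = np.cross(u_v, view)

    if magnification <= 0:
        raise DegenerateGeometryError("magnification must be positive")
    basis = np.column_stack([u_h, u_v])
    pts2 = magnification * (mesh.vertices @ basis)

    lms = {}
    if landmarks is not None:
        for name in "CDEFGHIJ":
            p = getattr(landmarks, name, None)
            if p is not None:
                lms[name] = magnification * (np.asarray(p) @ basis)

    polygon = _silhouette_polygon(mesh, view, basis, magnification) if build_polygon else None

    return Silhouette2D(
        polygon=polygon,
        points=pts2,
        labels=mesh.region_labels.copy(),
        landmarks=lms,
        view_direction=view,
        u_h=u_h,
        u_v=u_v,
        magnification=magnification,
    )


def _silhouette_polygon(mesh, view, basis, magnification):
    """Union of the projected front-facing triangles; outer boundary only."""
    tri = mesh.vertices[mesh.faces]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    front = normals @ view > 0
    if not np.any(front):
        front = ~front  # open or inconsistently wound mesh: use everything
    coords = magnification * (tri[front] @ basis)
    # drop degenerate (projected-edge-on) triangles
    a = coords[:, 1] - coords[:, 0]
    b = coords[:, 2] - coords[:, 0]
    area2 = np.abs(a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0])
    coords = coords[area2 > 1e-12]
    if len(coords) == 0:
        raise DegenerateGeometryError("projection collapsed every triangle")
    rings = shapely.linearrings(coords)
    union = shapely.union_all(shapely.polygons(rings))
    union = shapely.make_valid(union)
    if union.geom_type == "MultiPolygon":
        union = max(union.geoms, key=lambda g: g.area)
    if union.geom_type != "Polygon" or union.is_empty:
        raise DegenerateGeometryError("silhouette union is not a polygon")
    return shapely.Polygon(union.exterior)


def _shaft_midline(sil: Silhouette2D):
    """Least-squares midline of the two shaft silhouette edges."""
    pts = sil.region_points("shaft")
    c = pts.mean(axis=0)
    centred = pts - c
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    d0 = vt[0]
    try:
        head = sil.region_points("articular_surface").mean(axis=0)
        if (head - c) @ d0 < 0:
            d0 = -d0
    except MissingRegionError:
        pass
    perp = np.array([-d0[1], d0[0]])
    t = centred @ d0
    l = centred @ perp
    lo, hi = np.quantile(t, [0.02, 0.95])
    nb = 20
    edges = np.linspace(lo, hi, nb + 1)
    mids_t, mids_l = [], []
    for i in range(nb):
        sel = (t >= edges[i]) & (t <= edges[i + 1])
        if sel.sum() >= 3:
            mids_t.append(0.5 * (edges[i] + edges[i + 1]))
            mids_l.append(0.5 * (l[sel].min() + l[sel].max()))
    if len(mids_t) < 2:
        raise DegenerateGeometryError("too few shaft samples for a 2-D midline")
    slope, intercept = np.polyfit(mids_t, mids_l, 1)
    direction = unit(np.append(d0 + slope * perp, 0.0))[:2]
    if direction @ d0 < 0:
        direction = -direction
    point = c + intercept * perp
    return point, direction


def measure_radiographic(sil: Silhouette2D) -> RadiographResult:
    """Re-measure the four parameters on a simulated AP film."""
    for name in ("C", "D"):
        if name not in sil.landmarks:
            raise ProxhumError(
                f"projected landmark {name} missing from the silhouette"
            )
    C2 = np.asarray(sil.landmarks["C"], dtype=float)
    D2 = np.asarray(sil.landmarks["D"], dtype=float)

    p0, a2 = _shaft_midline(sil)

    neck = C2 - D2
    nlen = np.linalg.norm(neck)
    if nlen < 1e-9:
        raise DegenerateGeometryError("projected C and D coincide")
    neck_dir = neck / nlen
    casd2 = float(nlen)

    psi = math.degrees(math.acos(min(1.0, abs(float(neck_dir @ a2)))))
    nsa2 = 90.0 + psi

    artic = sil.region_points("articular_surface")
    n2 = np.array([-neck_dir[1], neck_dir[0]])
    if (artic.mean(axis=0) - C2) @ n2 < 0:
        n2 = -n2
    hht2 = float(np.max((artic - C2) @ n2))

    tub = sil.region_points("greater_tuberosity")
    tsh2 = float(np.max(artic @ a2) - np.max(tub @ a2))

    return RadiographResult(
        nsa2_deg=nsa2,
        hht2_mm=hht2,
        tsh2_mm=tsh2,
        casd2_mm=casd2,
        shaft_point=p0,
        shaft_direction=a2,
    )
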