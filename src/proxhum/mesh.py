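"""Containers for labelled surface meshes and anatomic landmarks.

A :class:`TriangleMesh` is a triangulated, millimetre-unit surface of a
segmented proximal humerus with a per-vertex anatomic region label
(``articular_surface``, ``greater_tuberosity``, ``shaft`` or ``other``).
A :class:`LandmarkSet` holds the manually placed anatomic points C, D, E
(superior articular margin, inferior articular margin, concave articular
point) plus any derived points.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import trimesh as _trimesh

from .errors import MissingRegionError, ValidationError
from .geometry import as_point

REGIONS = ("articular_surface", "greater_tuberosity", "shaft", "other")


@dataclass
class TriangleMesh:
    """Vertices + triangle indices + per-vertex region labels (mm units)."""

    vertices: np.ndarray
    faces: np.ndarray
    region_labels: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.region_labels = np.asarray(self.region_labels, dtype=object)
        problems = []
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            problems.append(f"vertices must be (n, 3), got {self.vertices.shape}")
        elif self.vertices.shape[0] < 4:
            problems.append("a surface mesh needs at least 4 vertices")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            problems.append(f"faces must be (m, 3), got {self.faces.shape}")
        elif self.vertices.ndim == 2 and (
            self.faces.min(initial=0) < 0
            or self.faces.max(initial=-1) >= len(self.vertices)
        ):
            problems.append("face indices out of range")
        if len(self.region_labels) != len(self.vertices):
            problems.append("region_labels must have one entry per vertex")
        unknown = set(np.unique(self.region_labels)) - set(REGIONS)
        if unknown:
            problems.append(f"unknown region labels: {sorted(unknown)}")
        if problems:
            raise ValidationError(problems)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def region_mask(self, name: str) -> np.ndarray:
        return self.region_labels == name

    def region_indices(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.region_mask(name))

    def region_vertices(self, name: str, *, required_by: str = "") -> np.ndarray:
        idx = self.region_indices(name)
        if idx.size == 0:
            stage = f" (required by {required_by})" if required_by else ""
            raise MissingRegionError(f"region '{name}' has no labelled vertices{stage}")
        return self.vertices[idx]

    def region_faces(self, name: str) -> np.ndarray:
        """Faces whose three corners all carry the given label."""
        mask = self.region_mask(name)
        return self.faces[np.all(mask[self.faces], axis=1)]

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    def transformed(self, rotation: np.ndarray, translation) -> "TriangleMesh":
        """Rigidly move the mesh: ``v -> R v + t``."""
        R = np.asarray(rotation, dtype=float)
        t = as_point(translation)
        return TriangleMesh(
            vertices=self.vertices @ R.T + t,
            faces=self.faces.copy(),
            region_labels=self.region_labels.copy(),
        )


@dataclass
class LandmarkSet:
    """Anatomic landmarks: C, D, E are inputs; the rest are derived."""

    C: np.ndarray
    D: np.ndarray
    E: np.ndarray
    A: Optional[np.ndarray] = None
    B: Optional[np.ndarray] = None
    F: Optional[np.ndarray] = None
    G: Optional[np.ndarray] = None
    H: Optional[np.ndarray] = None
    I: Optional[np.ndarray] = None
    J: Optional[np.ndarray] = None
    derived: dict = field(default_factory=dict)

    def __post_init__(self):
        self.C, self.D, self.E = as_point(self.C), as_point(self.D), as_point(self.E)
        if np.linalg.norm(self.C - self.D) < 1e-9:
            raise ValidationError("landmarks C and D coincide")
        area2 = np.linalg.norm(np.cross(self.D - self.C, self.E - self.C))
        if area2 < 2e-9:
            raise ValidationError("landmarks C, D, E are collinear")

    def transformed(self, rotation: np.ndarray, translation) -> "LandmarkSet":
        R = np.asarray(rotation, dtype=float)
        t = as_point(translation)

        def mv(p):
            return None if p is None else R @ p + t

        return replace(
            self,
            C=mv(self.C), D=mv(self.D), E=mv(self.E),
            A=mv(self.A), B=mv(self.B), F=mv(self.F),
            G=mv(self.G), H=mv(self.H), I=mv(self.I), J=mv(self.J),
            derived={},
        )
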