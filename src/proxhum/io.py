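"""Mesh, annotation and table I/O.

Meshes travel as STL/PLY/OBJ (millimetre units); landmarks and region
labels travel in a JSON sidecar::

    {"landmarks": {"C": [x, y, z], "D": [...], "E": [...]},
     "regions": {"articular_surface": [vertex indices], ...}}

Vertex indices are 0-based and refer to the vertex order produced by
:func:`read_mesh`.  PLY/OBJ preserve the vertex order of the writer; STL
stores an unindexed triangle soup, so STL meshes are canonicalised on
load (duplicate vertices merged, then sorted lexicographically by
coordinate) — annotations written next to an STL by this package use
that same canonical order, which makes ASCII and binary dialects of the
same bone interchangeable.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import trimesh as _trimesh

from .errors import FormatError, SchemaError
from .mesh import REGIONS, LandmarkSet, TriangleMesh

__all__ = [
    "read_mesh",
    "write_mesh",
    "read_annotation",
    "write_annotation",
    "annotation_path",
    "canonicalize_mesh",
]

_FORMATS = {".stl", ".ply", ".obj"}


def annotation_path(mesh_path) -> Path:
    """Default sidecar location: ``<stem>.landmarks.json`` next to the mesh."""
    p = Path(mesh_path)
    return p.with_name(p.stem + ".landmarks.json")


def _canonical_arrays(vertices: np.ndarray, faces: np.ndarray):
    """Deterministic vertex order for soup formats.

    Coordinates are snapped to float32 (STL's native precision, so ASCII
    and binary dialects agree), exact duplicates merged, and the vertex
    list sorted lexicographically by (x, y, z)."""
    key = np.asarray(vertices, dtype=float).astype(np.float32).astype(np.float64)
    uniq, index, inverse = np.unique(
        key, axis=0, return_index=True, return_inverse=True
    )
    return uniq, inverse[faces], index


def canonicalize_mesh(mesh: TriangleMesh) -> TriangleMesh:
    """The mesh as it will come back from an STL round trip (float32
    coordinates, canonical vertex order); labels follow the permutation."""
    vertices, faces, index = _canonical_arrays(mesh.vertices, mesh.faces)
    return TriangleMesh(
        vertices=vertices, faces=faces, region_labels=mesh.region_labels[index]
    )


def read_mesh(path, annotation: Optional[str] = None) -> Tuple[TriangleMesh, Optional[LandmarkSet]]:
    """Load a surface mesh (+ sidecar landmarks/regions when present).

    Returns ``(mesh, landmarks)``; ``landmarks`` is None when no
    annotation file exists.  Region labels default to ``other``.
    """
    p = Path(path)
    ext = p.suffix.lower()
    if ext not in _FORMATS:
        raise FormatError(f"unsupported mesh format '{ext}' (want STL/PLY/OBJ): {p}")
    if not p.exists():
        raise FormatError(f"mesh file not found: {p}")
    try:
        tm = _trimesh.load(str(p), file_type=ext[1:], force="mesh", process=False)
    except Exception as e:  # noqa: BLE001 - wrap any parser failure
        raise FormatError(f"cannot parse {p}: {e}") from e
    if tm is None or tm.vertices is None or len(tm.vertices) == 0 or len(tm.faces) == 0:
        raise FormatError(f"no triangles found in {p} (truncated or corrupt file?)")
    vertices = np.asarray(tm.vertices, dtype=float)
    faces = np.asarray(tm.faces, dtype=np.int64)
    if ext == ".stl":
        vertices, faces, _ = _canonical_arrays(vertices, faces)

    labels = np.array(["other"] * len(vertices), dtype=object)
    ann = Path(annotation) if annotation is not None else annotation_path(p)
    landmarks = None
    if ann.exists():
        landmarks, regions = read_annotation(ann)
        for name, idx in regions.items():
            idx = np.asarray(idx, dtype=np.int64)
            if idx.size and (idx.min() < 0 or idx.max() >= len(vertices)):
                raise SchemaError(
                    f"region '{name}' indices out of range for {len(vertices)} vertices"
                )
            labels[idx] = name
    elif annotation is not None:
        raise FormatError(f"annotation file not found: {ann}")
    mesh = TriangleMesh(vertices=vertices, faces=faces, region_labels=labels)
    return mesh, landmarks


def write_mesh(mesh: TriangleMesh, path, ascii_stl: bool = False) -> TriangleMesh:
    """Write the mesh geometry and return the mesh as a reader will see it.

    For STL that is the canonical form (float32, merged/sorted vertices);
    annotations for an STL mesh must be written against the returned mesh.
    """
    p = Path(path)
    ext = p.suffix.lower()
    if ext not in _FORMATS:
        raise FormatError(f"unsupported mesh format '{ext}' (want STL/PLY/OBJ): {p}")
    out = canonicalize_mesh(mesh) if ext == ".stl" else mesh
    tm = out.to_trimesh()
    p.parent.mkdir(parents=True, exist_ok=True)
    if ext == ".stl" and ascii_stl:
        p.write_text(_trimesh.exchange.stl.export_stl_ascii(tm))
    else:
        tm.export(str(p))
    return out


def read_annotation(path) -> Tuple[LandmarkSet, dict]:
    """Load the landmark/region JSON sidecar."""
    p = Path(path)
    try:
        payload = json.loads(p.read_text())
    except (OSError, json.JSONDecodeError) as e:
        raise FormatError(f"cannot parse annotation {p}: {e}") from e
    lms = payload.get("landmarks", {})
    for req in ("C", "D", "E"):
        if req not in lms:
            raise SchemaError(
                f"annotation {p} must provide landmarks C, D and E; missing {req}"
            )
    kwargs = {k: np.asarray(v, dtype=float) for k, v in lms.items() if k in "ABCDEFGHIJ"}
    landmarks = LandmarkSet(**kwargs)
    regions = payload.get("regions", {})
    unknown = set(regions) - set(REGIONS)
    if unknown:
        raise SchemaError(f"unknown regions in {p}: {sorted(unknown)}")
    return landmarks, regions


def write_annotation(path, landmarks: LandmarkSet, mesh: Optional[TriangleMesh] = None) -> Path:
    """Write landmarks (and the mesh's region labels, if given) as JSON."""
    p = Path(path)
    payload = {"landmarks": {}, "regions": {}}
    for name in "ABCDEFGHIJ":
        v = getattr(landmarks, name, None)
        if v is not None:
            payload["landmarks"][name] = [float(x) for x in v]
    if mesh is not None:
        for region in REGIONS:
            if region == "other":
                continue
            payload["regions"][region] = [int(i) for i in mesh.region_indices(region)]
    p.parent.mkdir(parents=True, exist_ok=True)
    p.write_text(json.dumps(payload))
    return p
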