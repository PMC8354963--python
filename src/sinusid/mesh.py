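"""Mesh container, I/O and frontal-sinus size measurements.

Meshes are :class:`trimesh.Trimesh` objects with coordinates in millimetres.
The measurement conventions assume the canonical anatomical frame used
throughout the package:

* x — left-right (maximum breadth is the x extent),
* y — posterior-anterior,
* z — inferior-superior (maximum height is the z extent).

Real meshes must be pre-oriented into this frame before breadth/height are
meaningful; synthetic meshes are generated in it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "MeshFormatError",
    "SizeMeasurements",
    "load_mesh",
    "save_mesh",
    "validate_mesh",
    "mesh_volume",
    "max_breadth",
    "max_height",
    "measure",
]

_SUPPORTED = {"ply", "stl", "obj"}


class MeshFormatError(ValueError):
    """Raised when a mesh file cannot be parsed or a mesh is structurally invalid."""


@dataclass(frozen=True)
class SizeMeasurements:
    """The three frontal-sinus size descriptors.

    breadth and height in mm, volume in cm^3; all strictly positive for a
    valid sinus model.
    """

    breadth: float
    height: float
    volume: float


def _check_format(fmt: str) -> str:
    fmt = fmt.lower().lstrip(".")
    if fmt not in _SUPPORTED:
        raise MeshFormatError(f"unsupported mesh format {fmt!r}; expected one of {sorted(_SUPPORTED)}")
    return fmt


def validate_mesh(mesh: trimesh.Trimesh, *, require_watertight: bool = False) -> trimesh.Trimesh:
    """Validate structural invariants of a triangle mesh.

    Checks face indices, removes degenerate (zero-area) faces, and, when
    ``require_watertight``, demands a closed consistently-oriented surface.
    Non-watertight meshes are accepted with a warning otherwise (they can be
    registered and measured for distance, but not for volume).
    """
    if mesh.vertices.shape[0] == 0 or mesh.faces.shape[0] == 0:
        raise MeshFormatError("empty mesh (no vertices or faces)")
    if mesh.faces.min() < 0 or mesh.faces.max() >= len(mesh.vertices):
        raise MeshFormatError("face indices out of range")
    areas = mesh.area_faces
    if np.any(areas <= 0):
        mesh.update_faces(areas > 0)
    if not mesh.is_watertight:
        if require_watertight:
            n_open = len(_open_edges(mesh))
            raise MeshFormatError(f"mesh is not watertight ({n_open} open edges)")
        warnings.warn("mesh is not watertight; volume will be unavailable", stacklevel=3)
    return mesh


def _open_edges(mesh: trimesh.Trimesh) -> np.ndarray:
    edges = mesh.edges_sorted
    unique, counts = np.unique(edges, axis=0, return_counts=True)
    return unique[counts != 2]


def load_mesh(path: str | Path, fmt: str | None = None) -> trimesh.Trimesh:
    """Load a surface mesh (PLY, STL or OBJ), in mm units.

    Parameters
    ----------
    path : path to the mesh file.
    fmt : optional explicit format; inferred from the suffix otherwise.

    Returns a validated :class:`trimesh.Trimesh`. A non-watertight result
    carries a warning, not an error.
    """
    path = Path(path)
    fmt = _check_format(fmt if fmt is not None else path.suffix)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        loaded = trimesh.load(path, file_type=fmt, force="mesh", process=False)
    except Exception as exc:  # trimesh raises heterogeneous parse errors
        raise MeshFormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    if not isinstance(loaded, trimesh.Trimesh) or len(loaded.faces) == 0:
        raise MeshFormatError(f"{path} contains no triangulated surface")
    mesh = trimesh.Trimesh(
        vertices=np.asarray(loaded.vertices, dtype=float),
        faces=np.asarray(loaded.faces, dtype=np.int64),
        vertex_colors=loaded.visual.vertex_colors if loaded.visual.kind == "vertex" else None,
        process=False,
    )
    # formats like STL store loose triangles; re-index coincident vertices
    mesh.merge_vertices()
    return validate_mesh(mesh)


def save_mesh(mesh: trimesh.Trimesh, path: str | Path, fmt: str | None = None) -> None:
    """Write a mesh to PLY/STL/OBJ. PLY preserves per-vertex RGB colors."""
    if mesh.vertices.shape[0] == 0 or mesh.faces.shape[0] == 0:
        raise MeshFormatError("refusing to write an empty mesh")
    path = Path(path)
    fmt = _check_format(fmt if fmt is not None else path.suffix)
    path.parent.mkdir(parents=True, exist_ok=True)
    mesh.export(path, file_type=fmt)


def mesh_volume(mesh: trimesh.Trimesh) -> float:
    """Enclosed volume in cm^3 by the divergence theorem (signed tetrahedra).

    Requires a watertight mesh; orientation is repaired if needed so the
    result is positive. Coordinates are mm, so mm^3 are divided by 1000.
    """
    if not mesh.is_watertight:
        n_open = len(_open_edges(mesh))
        raise MeshFormatError(f"volume requires a watertight mesh ({n_open} open edges)")
    if not mesh.is_winding_consistent:
        mesh = mesh.copy()
        mesh.fix_normals()
    return abs(mesh.volume) / 1000.0


def max_breadth(mesh: trimesh.Trimesh) -> float:
    """Maximum breadth (mm): vertex extent along x, between the outermost
    borders of the right and left sinus, in the canonical frame."""
    if len(mesh.vertices) == 0:
        raise MeshFormatError("empty mesh")
    x = mesh.vertices[:, 0]
    return float(x.max() - x.min())


def max_height(mesh: trimesh.Trimesh) -> float:
    """Maximum height (mm): vertex extent along z, between the upper and
    lower borders of the sinus, in the canonical frame."""
    if len(mesh.vertices) == 0:
        raise MeshFormatError("empty mesh")
    z = mesh.vertices[:, 2]
    return float(z.max() - z.min())


def measure(mesh: trimesh.Trimesh) -> SizeMeasurements:
    """Breadth, height (mm) and volume (cm^3) of one sinus model."""
    return SizeMeasurements(
        breadth=max_breadth(mesh),
        height=max_height(mesh),
        volume=mesh_volume(mesh),
    )
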