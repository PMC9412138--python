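"""Triangle-mesh data model, file I/O and geometric transforms.

All coordinates are in millimetres. Meshes are plain vertex/face arrays;
:class:`trimesh.Trimesh` is used behind the scenes for format parsing and
topology diagnostics, but vertex coordinates are never resampled or merged
on load (``process=False``), so stored coordinates round-trip exactly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "TriangleMesh",
    "MeshDiagnostics",
    "load_mesh",
    "save_mesh",
    "validate_mesh",
    "clean_mesh",
    "scale_mesh",
    "stretch_mesh",
    "triangle_areas",
]

log = logging.getLogger(__name__)

#: faces with area below this (mm^2) are considered degenerate slivers
DEGENERATE_AREA = 1e-12

_FORMATS = {"obj", "ply", "stl"}


@dataclass
class TriangleMesh:
    """A triangle mesh of a specimen or reference surface (units: mm).

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in millimetres.
    faces : (m, 3) int array
        Vertex-index triples; every index must be a valid row of ``vertices``.
    name : str
        Identifier used in reports and error messages.
    metadata : dict
        Free-form sidecar data (the shell generator stores its surface
        parametrisation here).
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.faces.size and (self.faces.ndim != 2 or self.faces.shape[1] != 3):
            raise ValueError("faces must be an (m, 3) array of vertex indices")
        if self.faces.size == 0:
            self.faces = self.faces.reshape(0, 3)
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(), self.faces.copy(), self.name, dict(self.metadata)
        )

    def to_trimesh(self) -> trimesh.Trimesh:
        """View as a :class:`trimesh.Trimesh` without vertex merging."""
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh, name: str = "") -> "TriangleMesh":
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces), name=name)


@dataclass
class MeshDiagnostics:
    """Topology/quality report for a mesh; produced by :func:`validate_mesh`.

    ``is_manifold`` uses the edge-manifold definition: every undirected edge
    is shared by at most two faces.  A watertight mesh (every edge shared by
    exactly two faces, winding consistent) is therefore always manifold.
    """

    is_watertight: bool
    is_manifold: bool
    n_components: int
    n_degenerate_faces: int
    bbox_min: np.ndarray
    bbox_max: np.ndarray


def triangle_areas(mesh: TriangleMesh) -> np.ndarray:
    """Per-face areas (mm^2) as half cross-product magnitudes."""
    v = mesh.vertices
    f = mesh.faces
    if len(f) == 0:
        return np.zeros(0)
    e1 = v[f[:, 1]] - v[f[:, 0]]
    e2 = v[f[:, 2]] - v[f[:, 0]]
    return 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)


def _infer_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        if fmt not in _FORMATS:
            raise ValueError(f"unsupported mesh format {fmt!r}")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix not in _FORMATS:
        raise ValueError(f"cannot infer mesh format from suffix {path.suffix!r}")
    return suffix


def load_mesh(path, fmt: str = "auto") -> TriangleMesh:
    """Load a triangle mesh from OBJ / PLY / STL.

    Polygonal faces with more than three vertices are fan-triangulated by the
    parser.  Vertex coordinates are preserved exactly as stored; units are
    assumed to be millimetres.  Degenerate (zero-area) faces are dropped with
    a logged count.

    Raises
    ------
    IOError
        If the file does not exist or cannot be parsed.
    ValueError
        If the parsed mesh has no faces.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if not path.is_file():
        raise IOError(f"mesh file not found: {path}")
    try:
        loaded = trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # noqa: BLE001 - re-raise as I/O failure
        raise IOError(f"could not parse {path} as {fmt}: {exc}") from exc
    if not isinstance(loaded, trimesh.Trimesh) or len(loaded.faces) == 0:
        raise ValueError(f"{path}: empty mesh (no faces)")
    mesh = TriangleMesh.from_trimesh(loaded, name=path.stem)
    return clean_mesh(mesh)


def save_mesh(mesh: TriangleMesh, path, fmt: str = "auto", precision: int = 9) -> Path:
    """Write a mesh to OBJ (text, ``precision`` significant digits), PLY or
    STL (binary).  Only geometry is written; normals and texture coordinates
    are omitted."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "obj":
        with open(path, "w") as fh:
            if mesh.name:
                fh.write(f"o {mesh.name}\n")
            for v in mesh.vertices:
                fh.write(f"v {v[0]:.{precision}g} {v[1]:.{precision}g} {v[2]:.{precision}g}\n")
            for f in mesh.faces:
                fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
    else:
        mesh.to_trimesh().export(str(path), file_type=fmt)
    return path


def clean_mesh(mesh: TriangleMesh) -> TriangleMesh:
    """Return a copy with degenerate faces (area < 1e-12 mm^2) removed.

    Scanned meshes routinely contain sliver faces; these contribute nothing
    to area or volume but break orientation checks, so they are dropped with
    a logged count rather than treated as an error.
    """
    areas = triangle_areas(mesh)
    keep = areas >= DEGENERATE_AREA
    n_bad = int((~keep).sum())
    if n_bad == 0:
        return mesh
    log.info("%s: dropping %d degenerate faces", mesh.name or "<mesh>", n_bad)
    return TriangleMesh(mesh.vertices, mesh.faces[keep], mesh.name, dict(mesh.metadata))


def validate_mesh(mesh: TriangleMesh) -> MeshDiagnostics:
    """Report watertightness, manifoldness, component count and bounds.

    Never mutates the input.  Multi-component meshes are legal (metrics then
    operate on the union) but are worth a warning upstream.
    """
    raw = mesh.to_trimesh()
    merged = mesh.to_trimesh()
    merged.merge_vertices()
    n_degenerate = int((triangle_areas(mesh) < DEGENERATE_AREA).sum())
    if len(raw.faces):
        # prefer the raw indexed topology; fall back to merged vertices for
        # formats (STL) that duplicate vertices per face.  Merging can fuse
        # legitimately coincident surface points (e.g. whorls in contact),
        # so a mesh closed in either representation counts as closed.
        tm = raw if raw.is_watertight or not merged.is_watertight else merged
        edges = tm.edges_sorted
        _, counts = np.unique(edges, axis=0, return_counts=True)
        manifold = bool(counts.max(initial=0) <= 2)
        watertight = bool(tm.is_watertight)
        n_components = max(1, len(merged.split(only_watertight=False)))
    else:
        manifold = True
        watertight = False
        n_components = 1 if len(mesh.vertices) else 0
    if len(mesh.vertices):
        bbox_min = mesh.vertices.min(axis=0)
        bbox_max = mesh.vertices.max(axis=0)
    else:
        bbox_min = bbox_max = np.full(3, np.nan)
    return MeshDiagnostics(
        is_watertight=watertight,
        is_manifold=manifold,
        n_components=n_components,
        n_degenerate_faces=n_degenerate,
        bbox_min=bbox_min,
        bbox_max=bbox_max,
    )


def scale_mesh(mesh: TriangleMesh, factor: float) -> TriangleMesh:
    """Isotropic scaling about the coordinate origin.

    Areas scale by ``factor**2`` and volumes by ``factor**3``.  Callers that
    need centroid-anchored scaling should translate first.
    """
    if not factor > 0:
        raise ValueError(f"scale factor must be positive, got {factor}")
    out = mesh.copy()
    out.vertices = mesh.vertices * float(factor)
    return out


def stretch_mesh(mesh: TriangleMesh, axis, factor: float) -> TriangleMesh:
    """Anisotropic scaling along ``axis``; directions orthogonal to the axis
    are unchanged."""
    if not factor > 0:
        raise ValueError(f"stretch factor must be positive, got {factor}")
    axis = np.asarray(axis, dtype=np.float64)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("stretch axis must be a nonzero vector")
    u = axis / norm
    out = mesh.copy()
    parallel = mesh.vertices @ u
    out.vertices = mesh.vertices + np.outer(parallel * (float(factor) - 1.0), u)
    return out
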