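"""Surface-complexity metrics for shell meshes.

The headline quantity is the ornamentation index

    OI = S / S' - 1

where ``S`` is the surface area of an ornamented specimen mesh and ``S'``
the surface area of a smooth reference model with the same conch geometry.
OI isolates the extra surface folding contributed by ornament (ribs, nodes,
spines, keels) and is invariant to isometric scaling, unlike the
surface-to-volume ratio, and insensitive to conch shape, unlike rugosity.

Also provided: enclosed volume, S/V ratio, projected (silhouette) area and
rugosity S/Sp.  For closed meshes rugosity uses the full two-sided surface
over the one-sided silhouette (a sphere therefore scores 4); unilateral
half-models, the usual convention for planispiral ammonites, are already
one-sided and a flat patch scores exactly 1.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage.draw import polygon as _raster_polygon

from .mesh_core import TriangleMesh, triangle_areas, validate_mesh

__all__ = [
    "MetricsRecord",
    "surface_area",
    "enclosed_volume",
    "sv_ratio",
    "projected_area",
    "rugosity",
    "ornamentation_index",
    "oi_from_meshes",
    "estimate_symmetry_plane",
]

log = logging.getLogger(__name__)

#: default silhouette pixel size, mm
DEFAULT_PIXEL = 0.05
#: OI below this triggers a mismatched-reference warning
OI_WARN_BELOW = -0.05
#: hard cap on silhouette raster size
_MAX_RASTER_PIXELS = 200_000_000


@dataclass
class MetricsRecord:
    """Per-specimen bundle of surface-complexity metrics.

    Areas in mm^2, volume in mm^3, ``sv_ratio`` in 1/mm; OI stored as a
    dimensionless fraction (report layers render percent).  Fields whose
    preconditions fail for a given mesh (e.g. volume of an open mesh) are
    ``None``.
    """

    specimen_id: str = ""
    S: Optional[float] = None
    S_ref: Optional[float] = None
    V: Optional[float] = None
    Sp: Optional[float] = None
    OI: Optional[float] = None
    sv_ratio: Optional[float] = None
    rugosity: Optional[float] = None
    fd: Optional[float] = None
    U_D: Optional[float] = None
    W_H: Optional[float] = None
    W_D: Optional[float] = None
    notes: dict = field(default_factory=dict)

    @property
    def area_excess(self) -> Optional[float]:
        """Convenience: the extra area S - S' contributed by ornament (mm^2)."""
        if self.S is None or self.S_ref is None:
            return None
        return self.S - self.S_ref

    @property
    def OI_percent(self) -> Optional[float]:
        return None if self.OI is None else 100.0 * self.OI

    def to_dict(self) -> dict:
        return {
            "specimen_id": self.specimen_id,
            "S_mm2": self.S,
            "Sref_mm2": self.S_ref,
            "V_mm3": self.V,
            "Sp_mm2": self.Sp,
            "OI_fraction": self.OI,
            "OI_percent": self.OI_percent,
            "SV_per_mm": self.sv_ratio,
            "rugosity": self.rugosity,
            "MFD_D": self.fd,
            "U_D": self.U_D,
            "W_H": self.W_H,
            "W_D": self.W_D,
        }


def surface_area(mesh: TriangleMesh) -> float:
    """Total surface area (mm^2): sum of half cross-product magnitudes."""
    if mesh.n_faces == 0:
        raise ValueError("surface_area: empty mesh")
    return float(triangle_areas(mesh).sum())


def enclosed_volume(mesh: TriangleMesh) -> float:
    """Enclosed volume (mm^3) by the divergence theorem.

    Sums signed tetrahedron volumes against the origin and returns the
    absolute value, so the result is insensitive to a globally flipped
    orientation.  Open meshes are refused: the volume (and hence S/V) is
    undefined for the unilateral half-models used for ammonites.
    """
    if mesh.n_faces == 0:
        raise ValueError("enclosed_volume: empty mesh")
    diag = validate_mesh(mesh)
    if not diag.is_watertight:
        raise ValueError(
            "enclosed_volume: mesh is not watertight; volume is undefined "
            "for open meshes (holes or inconsistent winding)"
        )
    v = mesh.vertices
    f = mesh.faces
    signed = np.einsum("ij,ij->i", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]]))
    return float(abs(signed.sum()) / 6.0)


def sv_ratio(mesh: TriangleMesh) -> float:
    """Surface-to-volume ratio (1/mm); scale-dependent by construction."""
    return surface_area(mesh) / enclosed_volume(mesh)


def _plane_basis(normal) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = np.asarray(normal, dtype=np.float64)
    norm = np.linalg.norm(n)
    if norm == 0:
        raise ValueError("plane normal must be a nonzero vector")
    n = n / norm
    helper = np.array([1.0, 0.0, 0.0])
    if abs(n[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, helper)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v, n


def projected_area(
    mesh: TriangleMesh,
    plane_normal,
    resolution: float = DEFAULT_PIXEL,
    method: str = "raster",
) -> float:
    """Silhouette area (mm^2) of the mesh projected along ``plane_normal``.

    Overlapping triangles (front/back of a closed shell) are counted once.
    ``method='raster'`` rasterises projected triangles on a grid of pixel
    size ``resolution`` and counts covered pixels — robust to the
    self-overlapping projections of scanned meshes.  ``method='exact'``
    unions the projected triangles as polygons (slow; used as an oracle).
    """
    if mesh.n_faces == 0:
        raise ValueError("projected_area: empty mesh")
    if not resolution > 0:
        raise ValueError("resolution must be positive")
    u, v, _ = _plane_basis(plane_normal)
    pts = np.column_stack([mesh.vertices @ u, mesh.vertices @ v])

    if method == "exact":
        from shapely.geometry import Polygon
        from shapely.ops import unary_union

        polys = []
        for tri in pts[mesh.faces]:
            p = Polygon(tri)
            if p.area > 0:
                polys.append(p if p.is_valid else p.buffer(0))
        if not polys:
            raise ValueError("projected_area: degenerate projection (zero area)")
        return float(unary_union(polys).area)
    if method != "raster":
        raise ValueError(f"unknown projection method {method!r}")

    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = hi - lo
    nx = int(np.ceil(span[0] / resolution)) + 1
    ny = int(np.ceil(span[1] / resolution)) + 1
    if nx * ny > _MAX_RASTER_PIXELS:
        raise ValueError(
            f"projected_area: raster {nx}x{ny} exceeds budget; "
            "increase resolution (pixel size)"
        )
    # pixel (i, j) center sits at lo + (i + 0.5, j + 0.5) * resolution, so an
    # axis-aligned rectangle spanning whole pixels rasterises exactly
    coords = (pts - lo) / resolution - 0.5
    mask = np.zeros((ny, nx), dtype=bool)
    tris = coords[mesh.faces]
    for tri in tris:
        rr, cc = _raster_polygon(tri[:, 1], tri[:, 0], shape=mask.shape)
        mask[rr, cc] = True
    covered = int(mask.sum())
    if covered == 0:
        raise ValueError("projected_area: degenerate projection (edge-on plane?)")
    return covered * resolution * resolution


def rugosity(
    mesh: TriangleMesh,
    plane_normal,
    resolution: float = DEFAULT_PIXEL,
    method: str = "raster",
) -> float:
    """Roughness per unit footprint: surface area over silhouette area.

    For ammonites the convention is the unilateral (half) model's area over
    the area of its plane of symmetry; for a closed mesh both sides of the
    surface project onto one silhouette, so a sphere scores ~4 and any flat
    one-sided patch scores 1.
    """
    area = surface_area(mesh)
    sp = projected_area(mesh, plane_normal, resolution=resolution, method=method)
    if sp < resolution * resolution:
        raise ValueError("rugosity: projected area below one pixel (degenerate)")
    return area / sp


def ornamentation_index(S: float, S_ref: float) -> float:
    """Ornamentation index OI = S / S' - 1.

    ``S`` is the ornamented surface area, ``S_ref`` the smooth reference
    area (same conch geometry, same trim).  Slightly negative values are
    legitimate — a polished shell can be smoother than its virtual
    reference — but values below -5% usually mean a mismatched reference
    and trigger a warning.
    """
    if not S_ref > 0:
        raise ValueError(f"reference area must be positive, got {S_ref}")
    oi = S / S_ref - 1.0
    if oi < OI_WARN_BELOW:
        log.warning(
            "OI = %.4f is strongly negative; check that the reference model "
            "matches the specimen's side and trim",
            oi,
        )
    return oi


def oi_from_meshes(mesh: TriangleMesh, reference: TriangleMesh) -> MetricsRecord:
    """OI record for a specimen mesh against its smooth reference.

    Both meshes must represent the same specimen side and trim (for
    planispiral ammonites: the unilateral, aperture-opened convention).
    Volume is populated only when the specimen mesh is watertight.
    """
    S = surface_area(mesh)
    S_ref = surface_area(reference)
    rec = MetricsRecord(
        specimen_id=mesh.name or "specimen",
        S=S,
        S_ref=S_ref,
        OI=ornamentation_index(S, S_ref),
    )
    try:
        rec.V = enclosed_volume(mesh)
        rec.sv_ratio = S / rec.V
    except ValueError as exc:
        rec.notes["volume"] = str(exc)
    return rec


def estimate_symmetry_plane(mesh: TriangleMesh) -> np.ndarray:
    """Estimate the symmetry-plane normal as the direction of least spread.

    Uses the smallest principal axis of the area-weighted covariance of face
    centroids.  For a planispiral shell this is the coiling axis (normal of
    the plane of symmetry).  Deterministic up to sign; the sign is fixed
    toward the positive-z hemisphere (then +y, then +x on ties).

    Raises
    ------
    ValueError
        If the two smallest principal variances are degenerate (isotropic
        spread); supply the normal explicitly in that case.
    """
    if mesh.n_faces == 0:
        raise ValueError("estimate_symmetry_plane: empty mesh")
    areas = triangle_areas(mesh)
    centroids = mesh.vertices[mesh.faces].mean(axis=1)
    w = areas / areas.sum()
    mu = w @ centroids
    d = centroids - mu
    cov = (d * w[:, None]).T @ d
    evals, evecs = np.linalg.eigh(cov)  # ascending
    scale = max(evals[-1], 1e-300)
    if (evals[1] - evals[0]) / scale <= 1e-9:
        raise ValueError(
            "estimate_symmetry_plane: degenerate principal directions; "
            "supply the projection normal explicitly"
        )
    n = evecs[:, 0]
    for k in (2, 1, 0):
        if abs(n[k]) > 1e-12:
            if n[k] < 0:
                n = -n
            break
    return n
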