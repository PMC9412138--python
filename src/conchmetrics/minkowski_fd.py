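"""Bouligand-Minkowski multiscale fractal dimension of a mesh surface.

The surface is voxelised, every occupied voxel is dilated by spheres of
increasing radius r (in voxel units), and the influence volume V(r) — the
number of voxels within Euclidean distance r of the surface — is recorded.
The fractal dimension is

    D = 3 - d log V(r) / d log r

estimated by a least-squares fit of log V against log r over a radius
window (default 3..20 voxels, voxel edge 0.2 mm).  A multiscale curve of
local log-log derivatives at the inter-radius midpoints accompanies every
scalar estimate.

V(r) is computed with an exact Euclidean distance transform and agrees
integer-for-integer with brute-force sphere stamping.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .mesh_core import TriangleMesh

__all__ = [
    "VoxelGrid",
    "DilationProfile",
    "FDResult",
    "voxelize_surface",
    "dilation_volume_profile",
    "fractal_dimension",
    "mfd_for_mesh",
    "DEFAULT_SPACING",
    "DEFAULT_RADII",
]

log = logging.getLogger(__name__)

#: default voxel edge length (mm), matching a 0.2 mm scan resolution
DEFAULT_SPACING = 0.2
#: default dilation radii in voxel units
DEFAULT_RADII = tuple(range(3, 21))
#: default cap on total grid size
DEFAULT_VOXEL_BUDGET = 512**3


@dataclass
class VoxelGrid:
    """Boolean occupancy grid marking surface voxels.

    ``origin`` is the corner of voxel (0,0,0); voxel ``(i,j,k)`` covers the
    half-open cube ``origin + [i, i+1) * spacing`` etc.  ``padding`` empty
    voxels surround the occupied bounding box on all sides so dilation up to
    that radius never clips.
    """

    origin: np.ndarray
    spacing: float
    occupancy: np.ndarray
    padding: int

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=np.float64)
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        if self.occupancy.ndim != 3:
            raise ValueError("occupancy must be a 3D boolean lattice")
        if not self.occupancy.any():
            raise ValueError("voxel grid has no occupied voxels")

    @property
    def n_occupied(self) -> int:
        return int(self.occupancy.sum())


@dataclass
class DilationProfile:
    """Influence-volume curve V(r): voxel counts at increasing radii."""

    radii: np.ndarray
    volumes: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=np.float64)
        self.volumes = np.asarray(self.volumes, dtype=np.int64)
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly increasing")


@dataclass
class FDResult:
    """Fractal dimension estimate plus the multiscale derivative curve.

    ``multiscale`` holds ``(log r midpoint, d log V / d log r)`` pairs from
    successive finite differences — one per consecutive radius pair, so its
    length is ``len(radii) - 1``.  ``D = 3 - slope`` exactly.
    """

    D: float
    slope: float
    fit_window: tuple
    multiscale: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))


def _surface_points(mesh: TriangleMesh, max_edge: float) -> np.ndarray:
    """Deterministic face-aware point coverage: subdivide until every edge
    is shorter than ``max_edge`` and return the vertices."""
    import trimesh.remesh

    v, f = mesh.vertices, mesh.faces
    if len(f) == 0:
        return v
    edges = v[f[:, [0, 1, 2]]] - v[f[:, [1, 2, 0]]]
    if np.linalg.norm(edges, axis=2).max() <= max_edge:
        return v
    sv, _ = trimesh.remesh.subdivide_to_size(v, f, max_edge=max_edge)
    return np.asarray(sv)


def voxelize_surface(
    mesh: TriangleMesh,
    spacing: float = DEFAULT_SPACING,
    padding: int = max(DEFAULT_RADII) + 1,
    mode: str = "surface",
    max_voxels: int = DEFAULT_VOXEL_BUDGET,
) -> VoxelGrid:
    """Mark the voxels covered by the mesh surface.

    ``mode='surface'`` (default) refines the tessellation until every edge
    is at most ``spacing / 2`` and marks the voxel containing each refined
    vertex — a surface-coverage rule that is insensitive to how coarsely the
    input happens to be triangulated.  ``mode='vertex'`` marks only the
    voxels containing the original mesh vertices (strict replication of
    vertex-seeded dilation; sensible only when the mesh resolution already
    matches ``spacing``).
    """
    if not spacing > 0:
        raise ValueError("spacing must be positive")
    if padding < 1:
        raise ValueError("padding must be at least 1 voxel")
    if mesh.n_vertices == 0:
        raise ValueError("voxelize_surface: empty mesh")
    if mode == "surface":
        pts = _surface_points(mesh, max_edge=spacing / 2.0)
    elif mode == "vertex":
        pts = mesh.vertices
    else:
        raise ValueError(f"unknown voxelisation mode {mode!r}")

    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    origin = lo - padding * spacing
    shape = np.floor((hi - origin) / spacing).astype(int) + 1 + padding
    if int(np.prod(shape)) > max_voxels:
        raise ValueError(
            f"voxel grid {tuple(shape)} exceeds budget of {max_voxels} voxels; "
            "use a coarser spacing"
        )
    idx = np.floor((pts - origin) / spacing).astype(int)
    idx = np.clip(idx, 0, shape - 1)  # guard points exactly on the max face
    occ = np.zeros(shape, dtype=bool)
    occ[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return VoxelGrid(origin=origin, spacing=spacing, occupancy=occ, padding=padding)


def dilation_volume_profile(grid: VoxelGrid, radii: Sequence[float]) -> DilationProfile:
    """Influence volumes V(r) for each dilation radius (voxel units).

    V(r) counts voxels whose exact Euclidean distance to the nearest
    occupied voxel is <= r; occupied voxels are at distance 0, so V(0) is
    the seed count.  Equivalent to stamping a digital sphere of radius r on
    every seed and counting the union.
    """
    radii = np.asarray(list(radii), dtype=np.float64)
    if radii.size == 0:
        raise ValueError("need at least one radius")
    if np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be strictly increasing")
    if radii.min() < 0:
        raise ValueError("radii must be non-negative")
    if radii.max() > grid.padding:
        raise ValueError(
            f"max radius {radii.max():g} exceeds grid padding {grid.padding}; "
            "re-voxelise with more padding"
        )
    dist = ndimage.distance_transform_edt(~grid.occupancy)
    volumes = np.array([(dist <= r).sum() for r in radii], dtype=np.int64)
    return DilationProfile(radii=radii, volumes=volumes, spacing=grid.spacing)


def fractal_dimension(
    profile: DilationProfile, fit_window: Optional[tuple] = None
) -> FDResult:
    """Fit D = 3 - slope of log V(r) vs log r over ``fit_window``.

    The multiscale curve attaches the local derivative between every
    consecutive radius pair in the *fit window*, evaluated at the log-radius
    midpoint.  D outside [0, 3] by more than 0.2 is reported but logged as a
    likely fit-window artifact.
    """
    r = profile.radii
    v = profile.volumes.astype(np.float64)
    if fit_window is None:
        fit_window = (float(r.min()), float(r.max()))
    lo, hi = fit_window
    sel = (r >= lo) & (r <= hi)
    if sel.sum() < 3:
        raise ValueError("fractal_dimension: fewer than 3 radii in fit window")
    if np.any(r[sel] <= 0):
        raise ValueError("fractal_dimension: fit window must exclude r = 0")
    logr = np.log(r[sel])
    logv = np.log(v[sel])
    slope, _ = np.polyfit(logr, logv, 1)
    D = 3.0 - float(slope)
    local = np.diff(logv) / np.diff(logr)
    mids = 0.5 * (logr[:-1] + logr[1:])
    if not (-0.2 <= D <= 3.2):
        log.warning("fractal dimension D = %.3f outside [0, 3]; check fit window", D)
    return FDResult(
        D=D,
        slope=float(slope),
        fit_window=(float(lo), float(hi)),
        multiscale=np.column_stack([mids, local]),
    )


def mfd_for_mesh(
    mesh: TriangleMesh,
    spacing: float = DEFAULT_SPACING,
    radii: Sequence[float] = DEFAULT_RADII,
    mode: str = "surface",
    max_voxels: int = DEFAULT_VOXEL_BUDGET,
) -> FDResult:
    """Multiscale fractal dimension of a mesh at the default scan settings
    (0.2 mm voxels, dilation radii 3-20)."""
    radii = np.asarray(list(radii), dtype=np.float64)
    padding = int(np.ceil(radii.max())) + 1
    grid = voxelize_surface(
        mesh, spacing=spacing, padding=padding, mode=mode, max_voxels=max_voxels
    )
    profile = dilation_volume_profile(grid, radii)
    return fractal_dimension(profile)
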