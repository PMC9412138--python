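"""Parametric generator of matched ornamented/smooth shell pairs.

A smooth conch is swept as a logarithmic spiral of elliptical apertures
(classic coiling descriptors: whorl expansion rate, umbilical ratio, axial
translation), then an ornament displacement field — ribs, spiral ridges and
seeded node bumps — pushes vertices outward along their section normals.
The smooth and ornamented meshes share vertex count and face topology, so a
pair realises exactly the S (ornamented) versus S' (smooth reference)
comparison the ornamentation index is built on, with a known ground-truth
ornament amplitude.

Analytic primitives (cube, icosphere, hemisphere, flat patch, ...) with
closed-form areas and volumes are provided as test fixtures.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import trimesh

from .mesh_core import TriangleMesh

__all__ = [
    "CoilParams",
    "OrnamentParams",
    "ShellPair",
    "generate_conch",
    "apply_ornament",
    "generate_pair",
    "make_primitive",
]

_TAU = 2.0 * np.pi


@dataclass
class CoilParams:
    """Coiling parameters of a planispiral (or trochospiral) conch.

    ``whorl_expansion`` is the per-revolution growth factor of the aperture
    (> 1); ``umbilical_ratio`` the fraction of the outer radius left open at
    the umbilicus (at 1/whorl_expansion successive whorls exactly touch);
    ``translation`` the per-revolution drift along the coiling axis (0 gives
    a planispiral, bilaterally symmetric shell).  Aperture semi-axes are in
    mm at the final whorl; earlier whorls scale down geometrically.
    """

    whorl_expansion: float = 2.0
    umbilical_ratio: float = 0.55
    translation: float = 0.0
    aperture_width: float = 2.0
    aperture_height: float = 5.0
    n_whorls: float = 3.0
    steps_per_whorl: int = 256
    sections: int = 64

    def __post_init__(self) -> None:
        if not self.whorl_expansion > 1:
            raise ValueError("whorl_expansion must be > 1")
        if not 0 <= self.umbilical_ratio < 1:
            raise ValueError("umbilical_ratio must be in [0, 1)")
        if not self.n_whorls > 0:
            raise ValueError("n_whorls must be positive")
        if self.aperture_width <= 0 or self.aperture_height <= 0:
            raise ValueError("aperture semi-axes must be positive")
        if int(self.steps_per_whorl) != self.steps_per_whorl or self.steps_per_whorl < 64:
            raise ValueError("steps_per_whorl must be an integer >= 64")
        if (
            int(self.sections) != self.sections
            or self.sections < 32
            or self.sections % 2
        ):
            raise ValueError("sections must be an even integer >= 32")


@dataclass
class OrnamentParams:
    """Ornament displacement field: ribs, spiral ridges, node bumps.

    Amplitudes are in mm (all >= 0; all zero leaves the mesh untouched).
    ``rib_frequency`` is ribs per whorl, ``spiral_count`` ridges around the
    aperture, ``node_density`` nodes per whorl placed by a seeded RNG with
    Gaussian footprint ``node_width`` (mm).  The seed is mandatory so every
    generated fixture is bit-reproducible.
    """

    seed: int
    rib_amplitude: float = 0.0
    rib_frequency: float = 16.0
    spiral_amplitude: float = 0.0
    spiral_count: int = 8
    node_amplitude: float = 0.0
    node_density: float = 0.0
    node_width: float = 1.0

    def __post_init__(self) -> None:
        for name in ("rib_amplitude", "spiral_amplitude", "node_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.node_width <= 0:
            raise ValueError("node_width must be positive")


@dataclass
class ShellPair:
    """Matched ornamented/smooth meshes with identical topology."""

    ornamented: TriangleMesh
    smooth: TriangleMesh
    coil: CoilParams
    ornament: OrnamentParams
    true_amplitude_summary: float = 0.0


def _center_radius_final(coil: CoilParams) -> float:
    # umbilical_ratio u = (r_c - h) / (r_c + h)  =>  r_c = h (1 + u) / (1 - u)
    u, h = coil.umbilical_ratio, coil.aperture_height
    return h * (1.0 + u) / (1.0 - u)


def generate_conch(coil: CoilParams, name: str = "conch") -> TriangleMesh:
    """Sweep a smooth conch: logarithmic spiral of elliptical apertures.

    The coiling axis is z; with zero translation the mesh is symmetric about
    the z = 0 coiling plane.  Ends are capped with triangle fans, producing
    a watertight tube.  The (theta, phi) surface parametrisation and the
    per-vertex section normals are stored in the mesh metadata so that
    ornament can be applied without normal-estimation noise.
    """
    W = coil.whorl_expansion
    T = max(2, int(round(coil.n_whorls * coil.steps_per_whorl)))
    S = int(coil.sections)
    theta = _TAU * np.arange(T + 1) / coil.steps_per_whorl
    theta_max = theta[-1]
    growth = W ** ((theta - theta_max) / _TAU)  # (T+1,)
    rc = _center_radius_final(coil) * growth
    cz = coil.translation * (theta - theta_max) / _TAU

    phi = _TAU * np.arange(S) / S  # (S,)
    cosph, sinph = np.cos(phi), np.sin(phi)
    radial = np.column_stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)])
    centers = radial * rc[:, None]
    centers[:, 2] = cz

    h = coil.aperture_height * growth  # (T+1,) semi-axis in the radial direction
    w = coil.aperture_width * growth  # semi-axis along the coiling axis

    # tube vertices: rings (T+1) x sections
    vr = h[:, None] * cosph[None, :]  # radial offset
    vz = w[:, None] * sinph[None, :]  # axial offset
    verts = (
        centers[:, None, :]
        + radial[:, None, :] * vr[:, :, None]
        + np.array([0.0, 0.0, 1.0]) * vz[:, :, None]
    ).reshape(-1, 3)

    # outward normals of the elliptical section, in the section plane
    n2 = np.stack(
        [cosph[None, :] / h[:, None], sinph[None, :] / w[:, None]], axis=-1
    )
    n2 /= np.linalg.norm(n2, axis=-1, keepdims=True)
    normals = (
        radial[:, None, :] * n2[:, :, 0:1] + np.array([0.0, 0.0, 1.0]) * n2[:, :, 1:2]
    ).reshape(-1, 3)

    theta_v = np.repeat(theta, S)
    phi_v = np.tile(phi, T + 1)

    def vid(t: int, s: int) -> int:
        return t * S + s % S

    faces = []
    for t in range(T):
        base0, base1 = t * S, (t + 1) * S
        for s in range(S):
            a = base0 + s
            b = base0 + (s + 1) % S
            c = base1 + (s + 1) % S
            d = base1 + s
            faces.append((a, b, c))
            faces.append((a, c, d))
    apex0 = (T + 1) * S
    apex1 = apex0 + 1
    for s in range(S):
        faces.append((apex0, vid(0, s + 1), vid(0, s)))
        faces.append((apex1, vid(T, s), vid(T, s + 1)))
    faces = np.asarray(faces, dtype=np.int64)

    verts = np.vstack([verts, centers[0], centers[-1]])
    theta_v = np.concatenate([theta_v, [theta[0], theta[-1]]])
    phi_v = np.concatenate([phi_v, [np.nan, np.nan]])
    normals = np.vstack([normals, np.zeros((2, 3))])  # caps are never displaced

    mesh = TriangleMesh(verts, faces, name=name)
    # enforce outward orientation: flip all faces if the signed volume is negative
    v = mesh.vertices
    f = mesh.faces
    signed = np.einsum(
        "ij,ij->i", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]])
    ).sum()
    if signed < 0:
        mesh.faces = mesh.faces[:, ::-1].copy()
    mesh.metadata.update(
        {
            "parametrization": {"theta": theta_v, "phi": phi_v, "normals": normals},
            "coiling_axis": np.array([0.0, 0.0, 1.0]),
            "coil_params": asdict(coil),
            "generator": "conch",
        }
    )
    return mesh


def _node_field(
    theta: np.ndarray,
    phi: np.ndarray,
    coil: CoilParams,
    orn: OrnamentParams,
    theta_span: tuple,
) -> np.ndarray:
    """Sum of seeded Gaussian bumps, in mm, evaluated on (theta, phi)."""
    n_nodes = int(round(orn.node_density * coil.n_whorls))
    if n_nodes == 0 or orn.node_amplitude == 0:
        return np.zeros_like(theta)
    rng = np.random.default_rng(orn.seed)
    t0, t1 = theta_span
    node_theta = rng.uniform(t0, t1, n_nodes)
    node_phi = rng.uniform(0.0, _TAU, n_nodes)
    rc_final = _center_radius_final(coil)
    W = coil.whorl_expansion
    out = np.zeros_like(theta)
    sect = np.sqrt(coil.aperture_width * coil.aperture_height)
    for nt, nphi in zip(node_theta, node_phi):
        g = W ** ((nt - t1) / _TAU)
        # arc-length distances (mm) around the spiral and around the aperture
        du = (theta - nt) * rc_final * g
        dv_ang = (phi - nphi + np.pi) % _TAU - np.pi
        dv = dv_ang * sect * g
        out += np.exp(-(du**2 + dv**2) / (2.0 * orn.node_width**2))
    return orn.node_amplitude * out


def apply_ornament(smooth: TriangleMesh, ornament: OrnamentParams) -> TriangleMesh:
    """Displace a generated conch outward along its section normals.

    The displacement field is everywhere >= 0 (half-wave rectified and
    squared sinusoids plus Gaussian bumps), so ornament only adds material
    and the ornamented area is never below the smooth area.  Requires the
    (theta, phi) parametrisation stored by :func:`generate_conch`.
    """
    par = smooth.metadata.get("parametrization")
    if par is None:
        raise ValueError(
            "apply_ornament: mesh lacks parametrization metadata; "
            "only meshes from generate_conch can be ornamented"
        )
    theta = par["theta"]
    phi = np.where(np.isnan(par["phi"]), 0.0, par["phi"])
    normals = par["normals"]
    coil = CoilParams(**smooth.metadata["coil_params"])

    ribs = ornament.rib_amplitude * np.maximum(
        0.0, np.sin(ornament.rib_frequency * theta)
    ) ** 2
    spirals = ornament.spiral_amplitude * np.maximum(
        0.0, np.sin(ornament.spiral_count * phi)
    ) ** 2
    nodes = _node_field(
        theta, phi, coil, ornament, (float(theta.min()), float(theta.max()))
    )
    disp = ribs + spirals + nodes

    out = smooth.copy()
    out.vertices = smooth.vertices + normals * disp[:, None]
    out.name = (smooth.name or "conch") + "_ornamented"
    out.metadata["ornament_params"] = asdict(ornament)
    out.metadata["max_displacement"] = float(disp.max())
    return out


def generate_pair(
    coil: Optional[CoilParams] = None,
    ornament: Optional[OrnamentParams] = None,
    name: str = "conch",
) -> ShellPair:
    """Generate a matched (ornamented, smooth) conch pair."""
    coil = coil or CoilParams()
    ornament = ornament if ornament is not None else OrnamentParams(seed=0)
    smooth = generate_conch(coil, name=name)
    ornamented = apply_ornament(smooth, ornament)
    return ShellPair(
        ornamented=ornamented,
        smooth=smooth,
        coil=coil,
        ornament=ornament,
        true_amplitude_summary=ornamented.metadata["max_displacement"],
    )


def _hemisphere(radius: float, n_lat: int = 64, n_lon: int = 128) -> TriangleMesh:
    """Open upper hemisphere (lat-long grid), area -> 2 pi r^2."""
    lat = np.linspace(0.0, np.pi / 2.0, n_lat + 1)  # 0 at pole
    lon = _TAU * np.arange(n_lon) / n_lon
    verts = [np.array([0.0, 0.0, radius])]  # pole
    for la in lat[1:]:
        z = radius * np.cos(la)
        rr = radius * np.sin(la)
        for lo in lon:
            verts.append(np.array([rr * np.cos(lo), rr * np.sin(lo), z]))
    verts = np.array(verts)
    faces = []
    for j in range(n_lon):
        faces.append((0, 1 + j, 1 + (j + 1) % n_lon))
    for i in range(n_lat - 1):
        b0 = 1 + i * n_lon
        b1 = 1 + (i + 1) * n_lon
        for j in range(n_lon):
            a, b = b0 + j, b0 + (j + 1) % n_lon
            c, d = b1 + (j + 1) % n_lon, b1 + j
            faces.append((a, b, c))
            faces.append((a, c, d))
    return TriangleMesh(verts, np.asarray(faces), name="hemisphere")


def _flat_patch(size_x: float, size_y: float, n: int = 8) -> TriangleMesh:
    xs = np.linspace(0.0, size_x, n + 1)
    ys = np.linspace(0.0, size_y, n + 1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
    faces = []
    for i in range(n):
        for j in range(n):
            a = i * (n + 1) + j
            b = a + 1
            c = a + (n + 1) + 1
            d = a + (n + 1)
            faces.append((a, b, c))
            faces.append((a, c, d))
    return TriangleMesh(verts, np.asarray(faces), name="flat_patch")


def make_primitive(kind: str, **params) -> TriangleMesh:
    """Deterministic canonical meshes with closed-form area/volume.

    Kinds: ``cube`` (edge), ``box`` (extents), ``icosphere`` (radius,
    subdivisions), ``hemisphere`` (radius; open), ``flat_patch`` (size_x,
    size_y; open), ``line_tube`` (length, radius; a thin capped cylinder).
    """
    if kind == "cube":
        edge = float(params.get("edge", 1.0))
        if edge <= 0:
            raise ValueError("edge must be positive")
        tm = trimesh.creation.box(extents=(edge, edge, edge))
    elif kind == "box":
        extents = np.asarray(params.get("extents", (1.0, 1.0, 1.0)), dtype=float)
        if np.any(extents <= 0):
            raise ValueError("extents must be positive")
        tm = trimesh.creation.box(extents=extents)
    elif kind == "icosphere":
        radius = float(params.get("radius", 1.0))
        subdivisions = int(params.get("subdivisions", 4))
        if radius <= 0:
            raise ValueError("radius must be positive")
        if subdivisions > 7:
            raise ValueError("icosphere subdivisions capped at 7")
        tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    elif kind == "hemisphere":
        return _hemisphere(
            float(params.get("radius", 1.0)),
            int(params.get("n_lat", 64)),
            int(params.get("n_lon", 128)),
        )
    elif kind == "flat_patch":
        return _flat_patch(
            float(params.get("size_x", 1.0)),
            float(params.get("size_y", 1.0)),
            int(params.get("n", 8)),
        )
    elif kind == "line_tube":
        length = float(params.get("length", 10.0))
        radius = float(params.get("radius", 0.1))
        if length <= 0 or radius <= 0:
            raise ValueError("length and radius must be positive")
        tm = trimesh.creation.cylinder(radius=radius, height=length, sections=32)
    else:
        raise ValueError(f"unknown primitive kind {kind!r}")
    mesh = TriangleMesh.from_trimesh(tm, name=kind)
    return mesh
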