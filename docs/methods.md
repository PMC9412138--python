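# Methods

## The ornamentation index

The ornamentation index of a shell is `OI = S/S′ − 1`, the fractional extra
surface area of the ornamented surface `S` over a smooth reference surface
`S′` with the same conch geometry. The package treats the ratio form as
normative; the raw area difference `S − S′` is exposed only as a derived
convenience field (`MetricsRecord.area_excess`). Both meshes must represent
the same side and trim of the same specimen — for planispiral ammonites the
usual convention is a unilateral model cut along the plane of symmetry with
the aperture opened. OI is stored as a dimensionless fraction; report
layers render percent with two decimals. Slightly negative values are
legitimate (a polished shell can be marginally smoother than its
reference); values below −5% trigger a logged warning because they almost
always indicate a mismatched reference.

Surface area is the sum of half cross-product magnitudes per triangle;
enclosed volume is the absolute value of the signed-tetrahedron
(divergence-theorem) sum, so a globally inverted orientation is harmless.
Volume — and therefore S/V — is refused for non-watertight meshes rather
than silently capped: the unilateral half-models used for ammonites are
open by construction and have no defined volume.

## Silhouette area and rugosity

Rugosity is `S / Sp` with `Sp` the silhouette (projected) area on a plane.
The silhouette is rasterised: projected triangles are drawn on a grid
(default pixel 0.05 mm, pixel centers at half-pixel offsets so axis-aligned
rectangles rasterise exactly) and covered pixels are counted once. Scanned
meshes self-overlap heavily in projection, which makes rasterisation the
robust default; an exact shapely polygon-union mode exists as a slow oracle
and agrees with the raster to better than 1% at the default pixel size.
Closed meshes project both sides onto one silhouette, so a sphere scores
~4 and a closed conch roughly its two-sided area over the side view; a
one-sided flat patch scores exactly 1. The projection normal is either
supplied or estimated as the smallest principal axis of the area-weighted
face-centroid covariance — for a planispiral shell this recovers the
coiling axis to well under a degree. The estimate refuses near-isotropic
meshes (relative eigenvalue gap below 1e−9) instead of returning an
arbitrary direction.

Rugosity is scale-free only if the raster pixel scales with the mesh; the
scale-invariance tests therefore scale the pixel size together with the
geometry.

## Bouligand–Minkowski fractal dimension

The surface is voxelised at a spacing of 0.2 mm by default — the mesh
resolution of a typical structured-light scan, so one dilation radius unit
equals one voxel. The default seeding rule refines the tessellation until
every edge is at most half a voxel and marks the voxel containing every
refined vertex; this covers the surface independently of how coarsely the
input happens to be triangulated. A strict vertex-only seeding mode is kept
for replicating vertex-seeded dilation on meshes whose vertex density
already matches the voxel pitch.

Influence volumes `V(r)` — the number of voxels within Euclidean distance
`r` of any seed — are computed from an exact Euclidean distance transform
and agree integer-for-integer with brute-force stamping of digital spheres
(`x² + y² + z² ≤ r²`). The grid is padded by at least the largest radius so
dilation never clips; a configurable voxel budget (default 512³) guards
against accidental huge grids.

The scalar dimension is `D = 3 − slope` of a least-squares fit of
`log V(r)` against `log r` over radii 3–20. A multiscale curve always
accompanies it: the derivative `d log V / d log r` between every
consecutive radius pair, evaluated at the log-radius midpoint (length
`len(radii) − 1`). These successive-difference quotients are the centered
finite-difference estimate at the midpoints; the scalar fit and the curve
are reported together so users can see whether a single slope is adequate.
`D` outside `[0, 3] ± 0.2` is reported but logged as a likely fit-window
artifact. The estimate is resolution-dependent by nature (halving the
spacing on the same mesh shifts `D`); the package reports, and does not
hide, that sensitivity.

Reference behaviours at radii 3–20: a single voxel gives `D ≈ 0.01`
(`V ∝ r³`), a 400-voxel line `D ≈ 0.98`, a 200×200 sheet `D ≈ 1.93`
(finite-sheet edge terms push the slope slightly above 1), and a smooth
sphere of radius 100 voxels `D ≈ 2.05`. Ornament raises `D` on otherwise
identical conchs.

## Synthetic conch pairs

The generator sweeps an elliptical aperture along a logarithmic spiral:
whorl expansion rate `W` (> 1 per revolution), umbilical ratio `u`
(aperture center radius `r_c = h(1+u)/(1−u)` for radial semi-axis `h`;
successive whorls touch exactly at `u = 1/W`, so the default 0.55 with
`W = 2` keeps a small gap and a clean manifold), axial translation (0 gives
a planispiral, bilaterally symmetric shell), and aperture semi-axes in mm
at the final whorl. Ends are capped with fans; the result is watertight
with globally outward orientation. Defaults (256 steps per whorl, 64
sections, 3 whorls) stay under 100k faces so full property sweeps run in
seconds; coarse test pairs use 64 × 32.

Ornament displaces tube vertices along their elliptical-section normals by

```
d(θ, φ) = A_rib · max(0, sin(f_rib θ))² + A_spiral · max(0, sin(k φ))²
          + Σ nodes A_node · exp(−(Δu² + Δv²) / 2σ²)
```

with θ the whorl angle, φ the aperture angle, and node centers placed by a
seeded RNG (the seed is a mandatory parameter; identical parameters are
bitwise-reproducible). The field is rectified, so ornament only adds
material outward and `S ≥ S′` holds by construction; smooth and ornamented
meshes share their face arrays exactly. Cap apex vertices are never
displaced, which keeps the ends closed.

What the generator emulates: matched specimen/reference pairs with
controllable ornament type, amplitude and frequency on a realistic coiled
geometry. What it does not emulate: scanning noise, restoration damage,
reference-modelling error (the reference is exact here, whereas manually
modelled references carry sub-1% error), allometric ornament growth, and
heteromorph or septate shells. Passing tests therefore validate the
measurement machinery, not the fidelity of any particular reconstruction
workflow.

A caveat discovered with this generator: OI is strictly size-invariant but
not strictly shape-invariant when the ornament amplitude is held fixed in
mm. Elongating the aperture (or affinely stretching a finished pair)
changes the ornament's slope relative to the local surface scale and can
shift OI by tens of percent relative. The shape-insensitivity of OI is
therefore an approximation that is excellent for ornament scaling with the
shell and for comparisons across specimens of similar proportion; the test
suite asserts the robust qualitative facts (rugosity responds strongly to
shape while OI keeps its order of magnitude and its ordering across
ornament levels) rather than a sharp invariance bound.

## Numerical choices

- Units are millimetres throughout; input meshes are assumed to be in mm.
- Degenerate faces (area < 1e−12 mm²) are dropped on load with a logged
  count; multi-component meshes are accepted with a warning and measured
  as a union.
- Watertightness is checked on the raw indexed topology first, falling
  back to merged vertices for formats that duplicate vertices per face
  (STL); merging alone can spuriously fuse legitimately coincident surface
  points, e.g. whorls in contact. Manifoldness means every edge is shared
  by at most two faces.
- Text mesh output (OBJ) uses 9 significant digits; STL/PLY are written
  binary and are single-precision by format.
- Scaling is about the coordinate origin; centroid-anchored scaling is the
  caller's translation away.
- Pearson correlations use pairwise-complete observations with the
  per-pair n reported; p-values are the two-sided t transform with n − 2
  degrees of freedom. Constant variables yield flagged undefined entries,
  not zeros. No multiple-testing correction by default (Holm optional).
- Test problem sizes: coarse conch pairs (64 steps/whorl × 32 sections,
  ~12k faces), a subdivision-4 icosphere, dilation grids up to ~8M voxels.
  These sizes put every analytic oracle well inside its stated tolerance
  while keeping the full suite under a minute of compute per module.

## Known limitations

- No automated construction of a smooth reference from an ornamented scan;
  deriving the reference is a modelling problem deliberately kept outside
  the metric (an automatic smoother would conflate measurement with
  reconstruction).
- Shape ratios U/D, W/H, W/D are caller-supplied, not measured from
  meshes.
- Rugosity for non-planispiral taxa has no canonical projection plane; a
  supplied normal is honoured but the result should be interpreted with
  care.
- The fractal dimension depends on scan resolution and voxel spacing;
  cross-study comparisons require matched settings.
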