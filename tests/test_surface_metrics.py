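"""Surface area, volume, silhouette, rugosity and the ornamentation index."""
import numpy as np
import pytest

from conchmetrics import (
    TriangleMesh,
    enclosed_volume,
    estimate_symmetry_plane,
    generate_conch,
    generate_pair,
    make_primitive,
    oi_from_meshes,
    ornamentation_index,
    projected_area,
    rugosity,
    scale_mesh,
    surface_area,
    sv_ratio,
)
from conchmetrics.shell_synth import CoilParams, OrnamentParams


class TestAreaVolume:
    def test_cube_exact(self, cube):
        assert surface_area(cube) == pytest.approx(6.0, rel=1e-12)
        assert enclosed_volume(cube) == pytest.approx(1.0, rel=1e-12)
        assert sv_ratio(cube) == pytest.approx(6.0, rel=1e-12)

    def test_icosphere_converges_to_sphere(self, icosphere):
        """Inscribed polyhedron area/volume sit below and converge to 4*pi
        and 4*pi/3."""
        area = surface_area(icosphere)
        vol = enclosed_volume(icosphere)
        assert area < 4 * np.pi
        assert area == pytest.approx(4 * np.pi, rel=3e-3)
        assert vol < 4 * np.pi / 3
        assert vol == pytest.approx(4 * np.pi / 3, rel=3e-3)
        errs = [
            abs(surface_area(make_primitive("icosphere", radius=1.0, subdivisions=s))
                / (4 * np.pi) - 1)
            for s in (2, 3, 4)
        ]
        assert errs[0] > errs[1] > errs[2]

    def test_sphere_sv_ratio_is_3_over_r(self):
        for r in (1.0, 2.5):
            sphere = make_primitive("icosphere", radius=r, subdivisions=4)
            assert sv_ratio(sphere) == pytest.approx(3.0 / r, rel=5e-3)

    def test_agrees_with_independent_oracle(self, icosphere, ribbed_pair):
        """Cross-check against trimesh's area and signed-volume routines."""
        for mesh in (icosphere, ribbed_pair.ornamented):
            tm = mesh.to_trimesh()
            assert surface_area(mesh) == pytest.approx(float(tm.area), rel=1e-12)
            assert enclosed_volume(mesh) == pytest.approx(
                abs(float(tm.volume)), rel=1e-12
            )

    def test_volume_orientation_insensitive(self, cube):
        flipped = TriangleMesh(cube.vertices, cube.faces[:, ::-1])
        assert enclosed_volume(flipped) == pytest.approx(1.0, rel=1e-12)

    def test_open_mesh_volume_refused(self, flat_patch):
        with pytest.raises(ValueError, match="watertight"):
            enclosed_volume(flat_patch)

    def test_empty_mesh_rejected(self):
        empty = TriangleMesh(np.zeros((3, 3)), np.zeros((0, 3), int))
        with pytest.raises(ValueError):
            surface_area(empty)


class TestProjection:
    def test_unit_square_silhouette(self, flat_patch):
        assert projected_area(flat_patch, (0, 0, 1), resolution=0.01) == pytest.approx(
            1.0, abs=0.05
        )

    def test_sphere_and_hemisphere_silhouette_is_disk(self, icosphere, hemisphere):
        for mesh in (icosphere, hemisphere):
            sp = projected_area(mesh, (0, 0, 1), resolution=0.02)
            assert sp == pytest.approx(np.pi, rel=0.01)

    def test_raster_matches_exact_union(self, ribbed_pair):
        """Rasterised silhouette agrees with the polygon-union oracle."""
        mesh = ribbed_pair.ornamented
        exact = projected_area(mesh, (0, 0, 1), method="exact")
        raster = projected_area(mesh, (0, 0, 1), resolution=0.05)
        assert raster == pytest.approx(exact, rel=0.01)

    def test_zero_normal_rejected(self, cube):
        with pytest.raises(ValueError):
            projected_area(cube, (0, 0, 0))


class TestRugosity:
    def test_flat_patch_is_one(self, flat_patch):
        assert rugosity(flat_patch, (0, 0, 1), resolution=0.01) == pytest.approx(
            1.0, abs=0.02
        )

    def test_hemisphere_is_two(self, hemisphere):
        assert rugosity(hemisphere, (0, 0, 1), resolution=0.02) == pytest.approx(
            2.0, rel=0.01
        )

    def test_closed_sphere_is_four(self, icosphere):
        """Closed-surface convention: both sides over a one-sided silhouette."""
        assert rugosity(icosphere, (0, 0, 1), resolution=0.02) == pytest.approx(
            4.0, rel=0.01
        )

    def test_nonflat_deformation_exceeds_one(self, flat_patch):
        bumped = flat_patch.copy()
        x, y = bumped.vertices[:, 0], bumped.vertices[:, 1]
        bumped.vertices[:, 2] = 0.2 * np.sin(2 * np.pi * x) * np.sin(2 * np.pi * y)
        assert rugosity(bumped, (0, 0, 1), resolution=0.01) > 1.0

    def test_edge_on_projection_rejected(self, flat_patch):
        with pytest.raises(ValueError):
            rugosity(flat_patch, (1, 0, 0), resolution=0.01)


class TestOrnamentationIndex:
    def test_smooth_against_itself_is_zero(self):
        assert ornamentation_index(4.2, 4.2) == 0.0

    def test_doubled_area_is_one(self):
        assert ornamentation_index(2.0, 1.0) == pytest.approx(1.0, rel=1e-15)

    def test_negative_allowed(self):
        # a polished shell can be slightly smoother than its reference
        assert ornamentation_index(0.9997, 1.0) < 0.0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            ornamentation_index(1.0, 0.0)

    def test_identical_meshes_give_zero(self, icosphere):
        assert oi_from_meshes(icosphere, icosphere).OI == 0.0

    def test_zero_amplitude_pair_gives_zero(self, small_coil):
        pair = generate_pair(small_coil, OrnamentParams(seed=2))
        assert abs(oi_from_meshes(pair.ornamented, pair.smooth).OI) < 1e-6

    def test_record_fields_consistent(self, ribbed_pair):
        rec = oi_from_meshes(ribbed_pair.ornamented, ribbed_pair.smooth)
        assert rec.S > rec.S_ref > 0
        assert rec.OI == pytest.approx(rec.S / rec.S_ref - 1, rel=1e-15)
        assert rec.area_excess == pytest.approx(rec.S - rec.S_ref)
        assert rec.V is not None and rec.sv_ratio is not None


class TestOIAlgebra:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    areas = st.floats(min_value=1e-6, max_value=1e9, allow_nan=False)

    @given(S=areas, S_ref=areas, c=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_ratio_invariant_under_common_area_factor(self, S, S_ref, c):
        """OI depends only on the area ratio: scaling both areas by the
        same factor (as isometric scaling does) leaves it unchanged."""
        base = ornamentation_index(S, S_ref)
        scaled = ornamentation_index(c * S, c * S_ref)
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-12)
        assert base >= -1.0


class TestScaleInvariance:
    """The headline property: OI and rugosity are size-free, S/V is not."""

    @pytest.mark.parametrize("k", [0.5, 2.0, 10.0])
    def test_oi_rugosity_invariant_sv_scales(self, ribbed_pair, k):
        orn, smooth = ribbed_pair.ornamented, ribbed_pair.smooth
        oi = oi_from_meshes(orn, smooth).OI
        normal = (0, 0, 1)
        rug = rugosity(orn, normal, resolution=0.1)
        sv = sv_ratio(orn)
        orn_k = scale_mesh(orn, k)
        smooth_k = scale_mesh(smooth, k)
        assert oi_from_meshes(orn_k, smooth_k).OI == pytest.approx(oi, rel=1e-9)
        assert rugosity(orn_k, normal, resolution=0.1 * k) == pytest.approx(
            rug, rel=1e-9
        )
        assert sv_ratio(orn_k) * k == pytest.approx(sv, rel=1e-9)


class TestSymmetryPlane:
    def test_flat_square_normal_is_z(self, flat_patch):
        np.testing.assert_allclose(
            estimate_symmetry_plane(flat_patch), [0, 0, 1], atol=1e-12
        )

    def test_rotated_square_normal_follows(self, flat_patch):
        rot = flat_patch.copy()
        # rotate 90 degrees about x: (x, y, z) -> (x, -z, y)
        v = rot.vertices.copy()
        rot.vertices = np.column_stack([v[:, 0], -v[:, 2], v[:, 1]])
        np.testing.assert_allclose(
            estimate_symmetry_plane(rot), [0, 1, 0], atol=1e-12
        )

    def test_conch_recovers_coiling_axis(self, small_coil):
        conch = generate_conch(small_coil)
        n = estimate_symmetry_plane(conch)
        angle = np.degrees(np.arccos(min(1.0, abs(float(n @ [0, 0, 1])))))
        assert angle < 5.0

    def test_isotropic_mesh_rejected(self, cube):
        with pytest.raises(ValueError, match="degenerate"):
            estimate_symmetry_plane(cube)
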