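"""Displacement fields: sampling, mesh warping and Jacobian volumetry."""

import numpy as np
import pytest

from longivol import (
    DisplacementField,
    FieldSpec,
    ShapeSpec,
    end_to_end_fixture,
    extract_mesh,
    integrate_jacobian,
    jacobian_map,
    make_field,
    make_segmentation,
    mesh_volume,
    pvc_both_routes,
    sample_displacement,
    warp_mesh,
)
from longivol.fields import FOLLOWUP_TO_BASELINE

from conftest import make_mask


def grid_field(fn, shape=(12, 12, 12), affine=None):
    """Sample an analytic u(x) on a grid into a DisplacementField."""
    affine = np.eye(4) if affine is None else affine
    idx = np.indices(shape, dtype=float).reshape(3, -1).T
    pts = idx @ affine[:3, :3].T + affine[:3, 3]
    u = np.asarray(fn(pts), dtype=float).reshape(shape + (3,))
    return DisplacementField(u, affine)


class TestSampling:
    def test_zero_field(self):
        fld = grid_field(lambda p: np.zeros_like(p))
        pts = np.array([[3.3, 4.4, 5.5], [0.1, 0.2, 0.3]])
        np.testing.assert_array_equal(sample_displacement(fld, pts), 0.0)

    def test_constant_field(self):
        fld = grid_field(lambda p: np.tile([1.0, 2.0, 3.0], (len(p), 1)))
        got = sample_displacement(fld, [[4.7, 5.2, 6.9]])
        np.testing.assert_allclose(got, [[1.0, 2.0, 3.0]], atol=1e-12)

    def test_linear_field_reproduced_exactly(self):
        # trilinear interpolation is exact on fields linear in x
        fld = grid_field(lambda p: 0.1 * p)
        pts = np.array([[2.25, 7.5, 3.125], [5.5, 5.5, 5.5]])
        np.testing.assert_allclose(sample_displacement(fld, pts), 0.1 * pts,
                                   atol=1e-12)

    def test_outside_points_get_zero(self, caplog):
        fld = grid_field(lambda p: np.ones_like(p))
        with caplog.at_level("WARNING", logger="longivol.fields"):
            got = sample_displacement(fld, [[-5.0, 0.0, 0.0], [5.0, 5.0, 5.0]])
        np.testing.assert_array_equal(got[0], 0.0)
        np.testing.assert_allclose(got[1], 1.0)
        assert any("outside" in r.message for r in caplog.records)

    def test_non_finite_point_rejected(self):
        fld = grid_field(lambda p: np.zeros_like(p))
        with pytest.raises(ValueError, match="non-finite"):
            sample_displacement(fld, [[np.nan, 0.0, 0.0]])


class TestWarpMesh:
    def setup_method(self):
        spec = ShapeSpec(semi_axes=(6.0, 5.0, 4.0), center=(12.0, 12.0, 12.0),
                         margin=6.0)
        self.seg = make_segmentation(spec)
        self.mesh = extract_mesh(self.seg)

    def test_zero_field_identity(self):
        fld, _ = make_field(FieldSpec(kind="zero"), self.seg)
        warped = warp_mesh(self.mesh, fld)
        np.testing.assert_array_equal(warped.vertices, self.mesh.vertices)

    def test_translation_preserves_volume(self):
        fld, _ = make_field(FieldSpec(kind="translation",
                                      translation=(3.0, 0.0, 0.0)), self.seg)
        warped = warp_mesh(self.mesh, fld)
        assert mesh_volume(warped) == pytest.approx(mesh_volume(self.mesh),
                                                    rel=1e-9)

    def test_uniform_contraction_gives_minus_five_percent(self):
        centroid = self.mesh.vertices.mean(axis=0)
        fld, _ = make_field(FieldSpec(kind="uniform_scale", scale=(0.983,) * 3,
                                      center=tuple(centroid)), self.seg)
        ratio = mesh_volume(warp_mesh(self.mesh, fld)) / mesh_volume(self.mesh)
        assert ratio == pytest.approx(0.983 ** 3, rel=1e-9)
        assert (ratio - 1) * 100 == pytest.approx(-5.0, abs=0.02)

    def test_wrong_direction_rejected(self):
        fld, _ = make_field(FieldSpec(kind="zero"), self.seg)
        fld.direction = FOLLOWUP_TO_BASELINE
        with pytest.raises(ValueError, match="baseline_to_followup"):
            warp_mesh(self.mesh, fld)

    def test_mesh_escaping_field_rejected(self):
        fld, _ = make_field(FieldSpec(kind="zero"), self.seg)
        runaway = self.mesh.with_vertices(self.mesh.vertices + 100.0)
        with pytest.raises(ValueError, match="escapes"):
            warp_mesh(runaway, fld)


class TestJacobian:
    def test_zero_field_unit_determinant(self):
        fld = grid_field(lambda p: np.zeros_like(p))
        jac = jacobian_map(fld)
        np.testing.assert_allclose(jac.data, 1.0, atol=1e-14)
        assert jac.n_nonpositive == 0

    def test_affine_field_exact_everywhere(self):
        # central AND one-sided second-order differences are exact on linear u
        s = 0.983
        fld = grid_field(lambda p: (s - 1.0) * p)
        jac = jacobian_map(fld)
        np.testing.assert_allclose(jac.data, s ** 3, rtol=1e-12)

    def test_oblique_grid_supported_via_chain_rule(self):
        from scipy.spatial.transform import Rotation
        aff = np.eye(4)
        aff[:3, :3] = Rotation.from_euler("z", 0.4).as_matrix() @ np.diag([1.0, 1.2, 0.8])
        s = 0.95
        fld = grid_field(lambda p: (s - 1.0) * p, affine=aff)
        np.testing.assert_allclose(jacobian_map(fld).data, s ** 3, rtol=1e-10)

    def test_interior_determinant_against_half_spacing_recomputation(self):
        spec = FieldSpec(kind="radial_gaussian_contraction", amplitude=0.05,
                         width=8.0, center=(8.0, 8.0, 8.0))
        coarse = grid_field(spec.displacement, shape=(17, 17, 17))
        jac_c = jacobian_map(coarse).data
        aff_f = np.diag([0.5, 0.5, 0.5, 1.0])
        fine = grid_field(spec.displacement, shape=(33, 33, 33), affine=aff_f)
        jac_f = jacobian_map(fine).data
        # fine grid voxel (2i,2j,2k) coincides with coarse voxel (i,j,k)
        inner = slice(2, -2)
        diff = np.abs(jac_c[inner, inner, inner]
                      - jac_f[::2, ::2, ::2][inner, inner, inner])
        assert diff.max() < 1e-3

    def test_too_small_grid_rejected(self):
        fld = grid_field(lambda p: np.zeros_like(p), shape=(2, 5, 5))
        with pytest.raises(ValueError, match="3 voxels"):
            jacobian_map(fld)


class TestIntegrateJacobian:
    def test_zero_field_counts_voxels(self):
        mask = make_mask([(i, j, k) for i in range(2, 7) for j in range(2, 6)
                          for k in range(2, 7)], shape=(9, 9, 9))
        assert mask.voxel_count == 100
        fld = grid_field(lambda p: np.zeros_like(p), shape=(9, 9, 9))
        assert integrate_jacobian(jacobian_map(fld), mask) == pytest.approx(100.0)

    def test_uniform_scaling_scales_voxel_volume(self):
        mask = make_mask([(4, 4, 4), (4, 5, 4), (5, 5, 5)], shape=(10, 10, 10))
        s = 0.983
        fld = grid_field(lambda p: (s - 1.0) * p, shape=(10, 10, 10))
        got = integrate_jacobian(jacobian_map(fld), mask)
        assert got == pytest.approx(mask.volume() * s ** 3, rel=1e-10)

    def test_grid_mismatch_rejected(self):
        mask = make_mask([(1, 1, 1)], shape=(5, 5, 5))
        fld = grid_field(lambda p: np.zeros_like(p), shape=(6, 6, 6))
        with pytest.raises(ValueError, match="grid mismatch"):
            integrate_jacobian(jacobian_map(fld), mask)


class TestRouteEquivalence:
    def test_smooth_field_routes_agree_within_tenth_point(self):
        shape = ShapeSpec(semi_axes=(11.0, 8.0, 7.0))
        seg, fld, truth = end_to_end_fixture(
            shape, FieldSpec(kind="radial_gaussian_contraction",
                             amplitude=0.04, width=8.0))
        rec = pvc_both_routes(seg, fld)
        assert abs(rec["pvc_difference"]) <= 0.1
        assert rec["pvc_mesh"] == pytest.approx(truth, abs=0.2)
        assert rec["n_nonpositive_jacobians"] == 0

    def test_composing_contractions_increases_atrophy(self):
        shape = ShapeSpec(semi_axes=(10.0, 8.0, 6.0))
        seg = make_segmentation(shape)
        mesh = extract_mesh(seg)
        f1, _ = make_field(FieldSpec(kind="radial_gaussian_contraction",
                                     amplitude=0.03, width=9.0), seg,
                           ground_truth=False)
        f2, _ = make_field(FieldSpec(kind="radial_gaussian_contraction",
                                     amplitude=0.05, width=7.0), seg,
                           ground_truth=False)
        v0 = mesh_volume(mesh)
        v1 = mesh_volume(warp_mesh(mesh, f1), check_closed=False)
        v2 = mesh_volume(warp_mesh(mesh, f2), check_closed=False)
        v12 = mesh_volume(warp_mesh(warp_mesh(mesh, f1), f2), check_closed=False)
        pvc1, pvc2, pvc12 = [(v / v0 - 1) * 100 for v in (v1, v2, v12)]
        assert pvc12 < pvc1 < 0
        assert pvc12 < pvc2 < 0
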