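"""Spherical-harmonic shapes: parsing, geometry, similarity."""

import math

import numpy as np
import pytest

from ninchi import morphology as M
from ninchi.distributions import DistExpr


def mesh_area_oracle(shape, r=1.0, ntheta=2000, nphi=4000):
    """Triangulated-mesh surface area: independent brute-force oracle."""
    th = np.linspace(0.0, math.pi, ntheta)
    ph = np.linspace(0.0, 2 * math.pi, nphi + 1)
    R = shape.radial(th[:, None], ph[None, :])
    s = shape.effective_scale()
    st, ct = np.sin(th)[:, None], np.cos(th)[:, None]
    sp, cp = np.sin(ph)[None, :], np.cos(ph)[None, :]
    X = np.stack([s.a * R * st * cp, s.b * R * st * sp, s.c * R * ct * np.ones_like(sp)], axis=-1) * r
    a = X[:-1, :-1]
    b = X[1:, :-1]
    c = X[:-1, 1:]
    d = X[1:, 1:]
    t1 = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=-1)
    t2 = 0.5 * np.linalg.norm(np.cross(b - d, c - d), axis=-1)
    return float(t1.sum() + t2.sum())


def grid_volume_oracle(shape, r=1.0, ntheta=2000, nphi=4000):
    """Dense midpoint-grid volume: independent brute-force oracle."""
    th = (np.arange(ntheta) + 0.5) * math.pi / ntheta
    ph = (np.arange(nphi) + 0.5) * 2 * math.pi / nphi
    R = shape.radial(th[:, None], ph[None, :])
    s = shape.effective_scale()
    integrand = (R**3) * np.sin(th)[:, None]
    return float(integrand.sum() * (math.pi / ntheta) * (2 * math.pi / nphi) / 3.0
                 * s.a * s.b * s.c * r**3)


class TestParse:
    def test_wire_expression(self):
        shape = M.parse_shape_expr("Y(0,0)*scale(100,1,1)")
        assert isinstance(shape, M.HarmonicShape)
        assert shape.coefficients() == {(0, 0): 1.0}
        assert shape.effective_scale() == M.AffineScale(100, 1, 1)

    def test_rod_expression_with_spaces(self):
        shape = M.parse_shape_expr("Y(0,0)*scale(4, 1, 1)")
        assert shape.effective_scale() == M.AffineScale(4, 1, 1)

    def test_zero_term_pruning_gives_pure_sphere(self):
        assert M.parse_shape_expr("Y(0,0)+Y(2,0)*0") == M.from_category("sphere")

    def test_order_rule_enforced(self):
        with pytest.raises(M.ShapeError, match=r"\|m\| <= l"):
            M.parse_shape_expr("Y(3,5)")

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(M.ShapeError, match="positive"):
            M.parse_shape_expr("Y(0,0)*scale(0,1,1)")

    def test_bbox_expression(self):
        shape = M.parse_shape_expr("bbox(pdf(20,sd=2);pdf(30,sd=3))")
        assert isinstance(shape, M.BoundingBoxShape)
        assert isinstance(shape.x, DistExpr) and shape.z is None

    def test_numeric_factor_scales_coefficient(self):
        shape = M.parse_shape_expr("Y(0,0)*2")
        assert shape.coefficients() == {(0, 0): 2.0}


class TestCategories:
    @pytest.mark.parametrize(
        "name,scale",
        [
            ("sphere", (1, 1, 1)),
            ("msp", (1, 1, 1)),
            ("shell", (1, 1, 1)),
            ("wire", (100, 1, 1)),
            ("rod", (4, 1, 1)),
        ],
    )
    def test_table_mappings(self, name, scale):
        shape = M.from_category(name)
        assert shape.effective_scale() == M.AffineScale(*scale)

    def test_unknown_category_suggests(self):
        with pytest.raises(M.ShapeError, match="did you mean"):
            M.from_category("spher")

    def test_nanohorn_refused(self):
        with pytest.raises(M.ShapeError, match=r"\|m\| <= l"):
            M.from_category("nanohorn")

    def test_cylinder_preset_is_star_shaped(self):
        assert M.from_category("cylinder").is_star_shaped()


class TestGeometryClosedForms:
    SPHERE = M.from_category("sphere")

    def test_sphere_volume(self):
        v = M.volume(self.SPHERE, r=15)
        exact = 4 / 3 * math.pi * 15**3
        assert abs(v - exact) / exact < 1e-3

    def test_sphere_area(self):
        s = M.surface_area(self.SPHERE, r=15)
        exact = 4 * math.pi * 15**2
        assert abs(s - exact) / exact < 1e-3

    def test_sphere_sv_ratio(self):
        assert M.sv_ratio(self.SPHERE, r=15) == pytest.approx(0.2, rel=1e-3)

    def test_affine_volume_scaling_exact(self):
        stretched = M.parse_shape_expr("Y(0,0)*scale(2,1,1)")
        # the affine factor is pulled out analytically, so the ratio is exact
        assert M.volume(stretched) / M.volume(self.SPHERE) == pytest.approx(2.0, rel=1e-14)
        assert M.volume(stretched) == pytest.approx(2 * 4 * math.pi / 3, rel=1e-3)

    def test_prolate_spheroid_area_closed_form(self):
        rod = M.from_category("rod")  # semi-axes (4, 1, 1)
        a, b = 4.0, 1.0
        e = math.sqrt(1 - (b / a) ** 2)
        exact = 2 * math.pi * b * b * (1 + (a / (b * e)) * math.asin(e))
        assert abs(M.surface_area(rod) - exact) / exact < 1e-3

    def test_non_star_shaped_rejected(self):
        bumpy = M.parse_shape_expr("Y(0,0)+Y(2,0)*2")
        with pytest.raises(M.ShapeError, match="star"):
            M.volume(bumpy)


class TestGeometryOracles:
    def test_perturbed_sphere_volume_against_grid(self):
        shape = M.parse_shape_expr("Y(0,0)+Y(2,0)*0.2")
        v = M.volume(shape)
        oracle = grid_volume_oracle(shape)
        assert abs(v - oracle) / oracle < 1e-3

    def test_perturbed_sphere_area_against_mesh(self):
        shape = M.parse_shape_expr("Y(0,0)+Y(2,0)*0.2")
        s = M.surface_area(shape)
        oracle = mesh_area_oracle(shape)
        assert abs(s - oracle) / oracle < 1e-3

    def test_refinement_shrinks_oracle_gap(self):
        rng = np.random.default_rng(5)
        for _ in range(4):
            c = float(rng.uniform(0.1, 0.25))
            l = int(rng.integers(4, 7))
            m = int(rng.integers(-l, l + 1))
            shape = M.HarmonicShape(
                (M.HarmonicTerm(0, 0, 1.0), M.HarmonicTerm(l, m, c))
            )
            oracle = mesh_area_oracle(shape, ntheta=1000, nphi=2000)
            gaps = [
                abs(M.surface_area(shape, ntheta=nt, nphi=2 * nt) - oracle)
                for nt in (4, 8, 16, 64)
            ]
            # quadrature error falls with resolution until it saturates at
            # the mesh oracle's own discretization error
            assert gaps[-1] <= gaps[0]
            assert gaps[-1] / oracle < 1e-3

    def test_isoperimetric_minimum_at_sphere(self):
        # at equal volume the sphere has the smallest surface/volume ratio,
        # and the ratio grows with elongation
        sphere = M.sv_ratio_equal_volume(M.from_category("sphere"))
        rod = M.sv_ratio_equal_volume(M.from_category("rod"))
        wire = M.sv_ratio_equal_volume(M.from_category("wire"))
        cyl = M.sv_ratio_equal_volume(M.from_category("cylinder"))
        assert sphere == pytest.approx((36 * math.pi) ** (1 / 3), rel=1e-3)
        assert sphere < cyl < rod < wire


class TestSimilarity:
    @pytest.mark.parametrize("metric", ["svr", "coeff", "volume_ratio"])
    def test_zero_on_identity_and_symmetric(self, metric):
        s1 = M.from_category("rod")
        s2 = M.from_category("wire")
        assert M.shape_similarity(s1, s1, metric) == 0.0
        assert M.shape_similarity(s1, s2, metric) == pytest.approx(
            M.shape_similarity(s2, s1, metric)
        )

    def test_sphere_vs_wire_svr_positive(self):
        v = M.shape_similarity(M.from_category("sphere"), M.from_category("wire"), "svr")
        assert v > 0

    def test_volume_ratio_closed_form(self):
        s1 = M.from_category("sphere")
        s2 = M.parse_shape_expr("Y(0,0)*scale(2,2,2)")
        assert M.shape_similarity(s1, s2, "volume_ratio") == pytest.approx(
            math.log(8), rel=1e-9
        )

    def test_unknown_metric(self):
        with pytest.raises(M.ShapeError, match="metric"):
            M.shape_similarity(M.from_category("sphere"), M.from_category("rod"), "nope")
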