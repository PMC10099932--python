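"""Distribution expressions, gamma/normal fitting, similarity metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from ninchi import distributions as D


class TestParse:
    def test_between_range(self):
        e = D.parse_dist_expr("rcdf(60)*cdf(100) nm")
        assert [t.kind for t in e.terms] == ["rcdf", "cdf"]
        assert [t.location for t in e.terms] == [60, 100]
        assert e.unit == "nm"

    def test_single_upper_bound(self):
        e = D.parse_dist_expr("cdf(100) nm")
        assert len(e.terms) == 1 and e.terms[0].kind == "cdf"

    @pytest.mark.parametrize(
        "text,canonical",
        [
            ("cdf(20, 0.9) nm", "cdf(20,0.9) nm"),
            ("pdf(27,sd=8) nm", "pdf(27,sd=8) nm"),
            ("pdf(27,σ=8) nm", "pdf(27,sd=8) nm"),
            ("pdf(115,m=95) nm", "pdf(115,m=95) nm"),
            ("pdf(15,ci=(u,0.99)) nm", "pdf(15,ci=(u,0.99)) nm"),
            ("cdf(1, 0.995)", "cdf(1,0.995)"),
        ],
    )
    def test_canonical_forms(self, text, canonical):
        assert D.parse_dist_expr(text).canonical() == canonical

    @pytest.mark.parametrize("bad", ["foo(3)", "pdf()", "pdf(3,zz=1)", "", "cdf(3,1.5)"])
    def test_malformed_raise(self, bad):
        with pytest.raises(D.DistributionError):
            D.parse_dist_expr(bad)

    def test_sum_extension(self):
        e = D.parse_dist_expr("pdf(10,sd=1)+pdf(40,sd=2)")
        assert e.combine == "sum" and len(e.terms) == 2


class TestFitFamily:
    def test_mean_sd_closed_form(self):
        d = D.fit_family({"mean": 27, "sd": 8})
        k, theta = d.params
        assert k == pytest.approx(11.390625, rel=1e-12)
        assert theta == pytest.approx(64 / 27, rel=1e-12)
        assert d.mean() == pytest.approx(27, rel=1e-6)
        assert d.sd() == pytest.approx(8, rel=1e-6)

    def test_mean_mode_closed_form(self):
        d = D.fit_family({"mean": 115, "mode": 95})
        k, theta = d.params
        assert k == pytest.approx(5.75, rel=1e-12)
        assert theta == pytest.approx(20.0, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(D.DistributionError, match="positive"):
            D.fit_family({"mean": 10, "sd": 0})

    def test_mode_above_mean_rejected_for_gamma(self):
        with pytest.raises(D.DistributionError, match="mode"):
            D.fit_family({"mean": 95, "mode": 115})

    def test_central_interval_constraint(self):
        d = D.fit_family({"mean": 15, "ci": ("u", 0.99)})
        assert d.mean() == pytest.approx(15, rel=1e-6)
        assert d.cdf(30) - d.cdf(0) == pytest.approx(0.99, abs=1e-9)

    def test_normal_family(self):
        d = D.fit_family({"mean": 30, "sd": 2}, family="normal")
        assert d.family == "normal" and d.params == (30.0, 2.0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        mean=st.floats(min_value=1.0, max_value=500.0),
        rel_sd=st.floats(min_value=0.02, max_value=0.9),
    )
    def test_parameter_recovery_property(self, mean, rel_sd):
        sd = mean * rel_sd
        d = D.fit_family({"mean": mean, "sd": sd})
        assert d.mean() == pytest.approx(mean, rel=1e-6)
        assert d.sd() == pytest.approx(sd, rel=1e-6)


class TestRealize:
    def test_upper_bound_mass(self):
        d = D.realize(D.parse_dist_expr("cdf(100)"))
        assert d.cdf(100) >= 0.95 - 1e-9

    def test_between_bound_mass(self):
        d = D.realize(D.parse_dist_expr("rcdf(60)*cdf(100)"))
        assert d.cdf(100) - d.cdf(60) >= 0.90 - 1e-6

    def test_pdf_term_moments(self):
        d = D.realize(D.parse_dist_expr("pdf(30,sd=2)"))
        assert d.family == "gamma"
        assert d.mean() == pytest.approx(30, rel=1e-9)
        assert d.sd() == pytest.approx(2, rel=1e-9)

    def test_degenerate_intersection_raises(self):
        with pytest.raises(D.DistributionError, match="degenerate|mass|infeasible"):
            D.realize(D.parse_dist_expr("rcdf(0.7)*cdf(0.3)"))

    def test_density_integrates_to_one(self):
        for text in ("pdf(30,sd=2)", "cdf(100)", "rcdf(60)*cdf(100)"):
            d = D.realize(D.parse_dist_expr(text))
            total, _ = integrate.quad(d.pdf, 0, d.ppf(1 - 1e-13), limit=300)
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_product_density_matches_family_quantiles(self):
        # quadrature oracle: the renormalized product puts its mass where the
        # fitted family was constrained to put it
        expr = D.parse_dist_expr("rcdf(60)*cdf(100)")
        t, dens, _ = D.product_density(expr)
        inside = np.trapezoid(np.where((t >= 60) & (t <= 100), dens, 0.0), t)
        assert inside >= 0.90

    def test_sum_combine_realizes(self):
        d = D.realize(D.parse_dist_expr("pdf(10,sd=1)+pdf(40,sd=2)"))
        assert 10 < d.mean() < 40


class TestSigmoidFactors:
    def test_rcdf_is_pointwise_complement_of_cdf(self):
        term_c = D.parse_dist_expr("cdf(50)").terms[0]
        term_r = D.parse_dist_expr("rcdf(50)").terms[0]
        f_c = D.sigmoid_factor(term_c)
        f_r = D.sigmoid_factor(term_r)
        t = np.linspace(0.0, 200.0, 5001)
        assert np.max(np.abs(f_r(t) - (1.0 - f_c(t)))) < 1e-12
        assert np.max(np.abs(f_c.complement()(t) - f_r(t))) == 0.0


class TestJensenShannon:
    G1 = D.FittedDistribution.gamma(0.44, 23.8)
    G2 = D.FittedDistribution.gamma(0.5, 18.4)

    def test_identity_is_zero(self):
        assert D.jensen_shannon(self.G1, self.G1) == 0.0

    def test_symmetry(self):
        a = D.jensen_shannon(self.G1, self.G2)
        b = D.jensen_shannon(self.G2, self.G1)
        assert abs(a - b) < 1e-10

    def test_bounded_by_one_in_base_two(self):
        d1 = D.FittedDistribution.normal(-100, 0.01)
        d2 = D.FittedDistribution.normal(100, 0.01)
        with pytest.warns(UserWarning, match="non-overlapping"):
            v = D.jensen_shannon(d1, d2)
        assert v == pytest.approx(1.0, abs=1e-6)
        assert 0 <= v <= 1

    def test_monte_carlo_oracle_agreement(self):
        quad = D.jensen_shannon(self.G1, self.G2)
        mc, se = D.jensen_shannon_mc(self.G1, self.G2, n=200_000, seed=11)
        assert abs(quad - mc) < 3 * se

    def test_base_e_rescales(self):
        b2 = D.jensen_shannon(self.G1, self.G2, log_base=2)
        be = D.jensen_shannon(self.G1, self.G2, log_base=math.e)
        assert b2 == pytest.approx(be / math.log(2), rel=1e-6)


class TestKolmogorovSmirnov:
    def test_identity_zero(self):
        d = D.FittedDistribution.gamma(2, 3)
        assert D.ks_distance(d, d) == 0.0

    def test_distant_normals_near_one(self):
        d1 = D.FittedDistribution.normal(0, 1)
        d2 = D.FittedDistribution.normal(1000, 1)
        assert D.ks_distance(d1, d2) == pytest.approx(1.0, abs=1e-9)

    def test_brute_force_grid_oracle(self):
        d1 = D.FittedDistribution.gamma(0.44, 23.8)
        d2 = D.FittedDistribution.gamma(0.5, 18.4)
        t = np.linspace(1e-6, 600, 1_000_001)
        oracle = np.max(np.abs(d1.cdf(t) - d2.cdf(t)))
        assert D.ks_distance(d1, d2) == pytest.approx(oracle, abs=1e-4)
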