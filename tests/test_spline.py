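import numpy as np
import pytest

from paleodown import (
    ConfigurationError,
    GeoGrid,
    GridSpec,
    NumericalError,
    SplineParams,
    aggregate_mean,
    downscale_field,
    fit_local_spline,
    pearson,
    tension_basis,
)
from paleodown.spline import make_downscale_plan


class TestTensionBasis:
    def test_zero_at_origin(self):
        for phi in (0.05, 0.1, 1.0, 10.0):
            assert tension_basis(0.0, phi) == 0.0

    @pytest.mark.parametrize(
        "r,phi,expected",
        [
            # frozen from a 30-digit symbolic evaluation of
            # -(1/(2 pi phi^2)) (ln(phi r/2) + gamma + K0(phi r))
            (1.0, 0.1, -0.136115928966569215470527373033),
            (2.5, 0.1, -0.625174534087269433512037322303),
        ],
    )
    def test_matches_high_precision_closed_form(self, r, phi, expected):
        assert tension_basis(r, phi) == pytest.approx(expected, rel=1e-12)

    def test_continuous_at_origin(self):
        assert abs(tension_basis(1e-8, 0.1)) < 1e-6

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            tension_basis(-0.1, 0.1)

    def test_vectorized_matches_scalar(self):
        r = np.array([0.0, 0.5, 1.0, 3.0])
        vec = tension_basis(r, 0.1)
        assert vec.shape == r.shape
        for i, ri in enumerate(r):
            assert vec[i] == tension_basis(float(ri), 0.1)


class TestFitLocalSpline:
    def test_constant_samples_give_zero_weights(self):
        lat = np.array([0.0, 1.0, 2.0, 0.5])
        lon = np.array([0.0, 1.0, 0.0, 2.0])
        fit = fit_local_spline(lat, lon, np.full(4, 7.25))
        assert np.allclose(fit.lam, 0.0, atol=1e-10)
        assert fit.trend == pytest.approx(7.25)
        assert fit.predict(0.7, 0.9) == pytest.approx(7.25)

    def test_interpolates_three_points(self):
        lat = np.array([0.0, 2.0, 0.0])
        lon = np.array([0.0, 1.0, 3.0])
        vals = np.array([0.0, 1.0, 2.0])
        fit = fit_local_spline(lat, lon, vals)
        pred = fit.predict(lat, lon)
        assert np.allclose(pred, vals, atol=1e-8)

    def test_weights_sum_to_zero(self):
        rng = np.random.default_rng(5)
        lat = rng.uniform(-5, 5, 8)
        lon = rng.uniform(0, 10, 8)
        fit = fit_local_spline(lat, lon, rng.normal(size=8))
        assert abs(fit.lam.sum()) < 1e-8

    def test_five_point_system_matches_symbolic_solve(self):
        """Coefficients agree with an independent 30-digit dense solve."""
        sympy = pytest.importorskip("sympy")
        lat = np.array([0.0, 1.0, -1.0, 2.0, 0.5])
        lon = np.array([0.0, 1.5, 1.0, -0.5, 2.5])
        vals = np.array([1.0, -2.0, 0.5, 3.0, 1.5])
        phi = sympy.Rational(1, 10)
        prec = 30

        def uv(la, lo):
            la, lo = sympy.rad(sympy.Float(la, prec)), sympy.rad(sympy.Float(lo, prec))
            return (sympy.cos(la) * sympy.cos(lo),
                    sympy.cos(la) * sympy.sin(lo), sympy.sin(la))

        def basis(r):
            if r == 0:
                return sympy.Integer(0)
            h = phi * r
            return -(1 / (2 * sympy.pi * phi**2)) * (
                sympy.log(h / 2) + sympy.EulerGamma + sympy.besselk(0, h)
            )

        n = 5
        A = sympy.zeros(n + 1, n + 1)
        for i in range(n):
            ui = uv(lat[i], lon[i])
            for j in range(n):
                if i == j:
                    continue
                uj = uv(lat[j], lon[j])
                dot = sum(a * b for a, b in zip(ui, uj))
                r = sympy.deg(sympy.acos(dot))
                A[i, j] = sympy.N(basis(sympy.N(r, prec)), prec)
            A[i, n] = 1
            A[n, i] = 1
        b = sympy.Matrix(list(vals) + [0])
        sol = A.LUsolve(b)
        fit = fit_local_spline(lat, lon, vals)
        for j in range(n):
            assert fit.lam[j] == pytest.approx(float(sol[j]), rel=1e-8, abs=1e-10)
        assert fit.trend == pytest.approx(float(sol[n]), rel=1e-8)

    def test_duplicate_points_rejected(self):
        lat = np.array([0.0, 0.0, 1.0])
        lon = np.array([0.0, 0.0, 1.0])
        with pytest.raises(NumericalError, match="duplicate"):
            fit_local_spline(lat, lon, np.array([1.0, 2.0, 3.0]))


@pytest.fixture
def coarse_spec():
    return GridSpec(15, 0, 2.5, 2.5, 6, 6)


class TestDownscaleField:
    def test_constant_field_reproduced_everywhere(self, coarse_spec):
        g = GeoGrid(coarse_spec, np.full((6, 6), 4.25))
        fine = downscale_field(g, coarse_spec.refine(5))
        assert np.allclose(fine.values, 4.25, atol=1e-9)

    def test_passes_through_coarse_nodes(self, coarse_spec):
        # odd refinement => every coarse centre is also a fine centre
        rng = np.random.default_rng(0)
        g = GeoGrid(coarse_spec, rng.normal(0, 2, (6, 6)))
        fine = downscale_field(g, coarse_spec.refine(5))
        node_vals = fine.values[2::5, 2::5]
        assert np.max(np.abs(node_vals - g.values)) < 1e-6 * np.ptp(g.values)

    def test_smooth_field_recovered(self):
        spec = GridSpec(30, 0, 2.5, 2.5, 12, 12)

        def f(lat, lon):
            return np.sin(lat * np.pi / 90) + np.cos(lon * np.pi / 180)

        lat, lon = spec.center_mesh()
        g = GeoGrid(spec, f(lat, lon))
        fine_spec = spec.refine(5)
        fine = downscale_field(g, fine_spec)
        flat, flon = fine_spec.center_mesh()
        truth = f(flat, flon)
        # compare away from the domain boundary where extrapolation degrades
        interior = (slice(10, -10), slice(10, -10))
        err = np.abs(fine.values[interior] - truth[interior])
        assert err.max() < 5e-3 * np.ptp(truth)

    def test_aggregation_correlates_with_coarse(self, coarse_spec):
        rng = np.random.default_rng(3)
        lat, lon = coarse_spec.center_mesh()
        g = GeoGrid(coarse_spec, np.sin(lat / 5) + np.cos(lon / 5))
        fine = downscale_field(g, coarse_spec.refine(10))
        agg = aggregate_mean(fine, coarse_spec)
        r = pearson(agg.values.ravel(), g.values.ravel())
        assert r >= 0.99

    def test_deterministic_bit_identical(self, coarse_spec):
        rng = np.random.default_rng(4)
        g = GeoGrid(coarse_spec, rng.normal(size=(6, 6)))
        a = downscale_field(g, coarse_spec.refine(4))
        b = downscale_field(g, coarse_spec.refine(4))
        assert np.array_equal(a.values, b.values)

    def test_too_few_valid_cells(self, coarse_spec):
        mask = np.ones((6, 6), dtype=bool)
        mask[:2, :2] = False  # only 4 valid cells
        g = GeoGrid(coarse_spec, np.zeros((6, 6)), mask)
        with pytest.raises(ConfigurationError, match="n_neighbors"):
            downscale_field(g, coarse_spec.refine(2))

    def test_plan_reuse_bit_identical(self, coarse_spec):
        rng = np.random.default_rng(6)
        fine_spec = coarse_spec.refine(4)
        plan = make_downscale_plan(
            coarse_spec, np.ones((6, 6), bool), fine_spec
        )
        g1 = GeoGrid(coarse_spec, rng.normal(size=(6, 6)))
        direct = downscale_field(g1, fine_spec)
        planned = downscale_field(g1, fine_spec, plan=plan)
        assert np.array_equal(direct.values, planned.values)

    def test_plan_mismatch_rejected(self, coarse_spec):
        fine_spec = coarse_spec.refine(4)
        plan = make_downscale_plan(coarse_spec, np.ones((6, 6), bool), fine_spec)
        mask = np.zeros((6, 6), bool); mask[0, 0] = True
        g = GeoGrid(coarse_spec, np.zeros((6, 6)), mask)
        with pytest.raises(ConfigurationError, match="plan"):
            downscale_field(g, fine_spec, plan=plan)

    def test_nodata_cells_excluded_from_sampling(self, coarse_spec):
        vals = np.full((6, 6), 2.0)
        vals[0, 0] = 1e6  # poisoned cell, masked out
        mask = np.zeros((6, 6), bool); mask[0, 0] = True
        g = GeoGrid(coarse_spec, vals, mask)
        fine = downscale_field(g, coarse_spec.refine(3))
        assert np.allclose(fine.values, 2.0, atol=1e-8)

    def test_spline_params_validation(self):
        with pytest.raises(ConfigurationError):
            SplineParams(tension=0.0)
        with pytest.raises(ConfigurationError):
            SplineParams(n_neighbors=2)
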