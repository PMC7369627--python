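"""Diffusivity models, gradient fitting and Fick's-law fluxes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sedflux import (
    CoreContext,
    DiffusivityModel,
    build_diffusivity,
    db_for_abundance,
    diffusive_flux,
    fit_biodiffusivity,
    fit_gradient,
    molecular_diffusivity,
    o2_fit_window,
    parabolic_window_attenuation,
    sediment_diffusivity,
    sulfide_fit_window,
)
from conftest import ols_oracle


class TestSedimentDiffusivity:
    def test_free_water_limit(self):
        assert sediment_diffusivity(1.0e-4, 0.999999) == pytest.approx(1.0e-4, rel=1e-5)

    @pytest.mark.parametrize(
        "d_mol,phi,expected",
        [(1.0e-4, 0.9, 8.1e-5), (1.0e-4, 0.5, 2.5e-5)],
    )
    def test_porosity_squared_scaling(self, d_mol, phi, expected):
        assert sediment_diffusivity(d_mol, phi) == pytest.approx(expected)

    def test_out_of_range_porosity_rejected(self):
        for phi in (0.0, 1.0, 1.2, -0.1):
            with pytest.raises(ValueError):
                sediment_diffusivity(1e-4, phi)

    def test_ds_never_exceeds_dmol(self):
        for phi in np.linspace(0.05, 0.95, 10):
            assert sediment_diffusivity(1e-4, phi) <= 1e-4

    def test_molecular_diffusivity_magnitudes(self):
        # O2 in water at 25 °C is ~2.3e-5 cm²/s ≈ 2.0e-4 m²/d
        assert molecular_diffusivity("O2", 25.0) == pytest.approx(2.0e-4, rel=0.05)
        # diffusivities shrink in cold water
        assert molecular_diffusivity("O2", 4.0) < molecular_diffusivity("O2", 25.0)
        assert molecular_diffusivity("H2S", 8.0) > 0


class TestBiodiffusivityFit:
    def test_exact_line_recovered(self):
        pts = [(0.0, 1e-5), (500.0, 2e-5), (1000.0, 3e-5), (2000.0, 5e-5)]
        fit = fit_biodiffusivity(pts)
        assert fit.slope == pytest.approx(2e-8, rel=1e-12)
        assert fit.intercept == pytest.approx(1e-5, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_two_points_line_through_both(self):
        fit = fit_biodiffusivity([(100.0, 1e-5), (300.0, 3e-5)])
        db, clipped = db_for_abundance(fit, 100.0)
        assert db == pytest.approx(1e-5)
        assert not clipped

    def test_noisy_points_match_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        x = np.array([128.0, 191.0, 828.0, 2030.0])
        y = 1e-5 + 4e-8 * x + rng.normal(0, 5e-6, 4)
        fit = fit_biodiffusivity(list(zip(x, y)))
        slope, intercept = ols_oracle(x, y)
        assert fit.slope == pytest.approx(slope, rel=1e-12)
        assert fit.intercept == pytest.approx(intercept, rel=1e-12)

    def test_duplicate_abundances_rejected(self):
        with pytest.raises(ValueError):
            fit_biodiffusivity([(100.0, 1e-5), (100.0, 2e-5)])

    def test_negative_prediction_clips_to_zero_with_flag(self):
        fit = fit_biodiffusivity([(0.0, 1e-5), (100.0, 0.5e-5), (200.0, 0.0)])
        db, clipped = db_for_abundance(fit, 1000.0)
        assert db == 0.0
        assert clipped

    def test_zero_abundance_gives_intercept(self):
        fit = fit_biodiffusivity([(100.0, 1e-5), (300.0, 3e-5)])
        db, _ = db_for_abundance(fit, 0.0)
        assert db == pytest.approx(fit.intercept)


class TestGradientFit:
    def test_unit_conversion_um_per_mm_to_mmol_per_m4(self, linear_o2_profile):
        fit = fit_gradient(linear_o2_profile.depths, linear_o2_profile.values, (0.0, 1.5))
        assert fit.slope == pytest.approx(-2.0e5, rel=1e-12)

    def test_constant_profile_slope_zero(self):
        d = np.arange(0, 2.01, 0.25)
        fit = fit_gradient(d, np.full_like(d, 42.0), (0, 2))
        assert fit.slope == 0.0

    def test_noisy_fit_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        d = np.arange(0.0, 2.01, 0.1)
        v = 300 - 150 * d + rng.normal(0, 2.0, d.size)
        fit = fit_gradient(d, v, (0.0, 2.0))
        slope, intercept = ols_oracle(d, v)
        assert fit.slope == pytest.approx(slope * 1e3, rel=1e-12)
        assert fit.intercept == pytest.approx(intercept, rel=1e-12)

    def test_too_few_points_in_window_rejected(self):
        d = np.arange(0.0, 2.01, 0.5)
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_gradient(d, d * 0, (0.0, 0.2))

    def test_window_recorded_as_actual_points_used(self):
        d = np.arange(0.0, 2.01, 0.25)
        fit = fit_gradient(d, 100 - 10 * d, (0.1, 1.4))
        assert fit.window == (0.25, 1.25)
        assert fit.n_points == 5


class TestDiffusiveFlux:
    def _diffusivity(self, phi=0.5, d_mol=2.0e-4, d_b=5.0e-5):
        return DiffusivityModel("O2", d_mol, phi**2 * d_mol, d_b, phi)

    def test_flux_arithmetic_and_sign(self, baltic_context):
        # phi=0.5, Ds+Db = 1e-4 m²/d, slope −1e5 mmol/m⁴ -> J = −5 mmol/m²/d
        ctx = CoreContext("c", "t", 0.5, 8.0, 7.0, 0.0)
        diff = self._diffusivity()
        assert diff.d_s + diff.d_b == pytest.approx(1.0e-4)
        grad = fit_gradient(np.arange(0, 1.01, 0.1), 300 - 100 * np.arange(0, 1.01, 0.1), (0, 1))
        assert grad.slope == pytest.approx(-1.0e5)
        fx = diffusive_flux(ctx, diff, grad)
        assert fx.flux == pytest.approx(-5.0)

    def test_zero_slope_zero_flux(self):
        ctx = CoreContext("c", "t", 0.5, 8.0, 7.0, 0.0)
        d = np.arange(0, 1.01, 0.1)
        grad = fit_gradient(d, np.full_like(d, 100.0), (0, 1))
        assert diffusive_flux(ctx, self._diffusivity(), grad).flux == 0.0

    def test_sign_contract(self):
        """Decreasing profile -> uptake (J < 0); increasing -> efflux (J > 0)."""
        ctx = CoreContext("c", "t", 0.9, 8.0, 7.0, 0.0)
        diff = build_diffusivity("H2S", ctx, d_b=0.0)
        d = np.arange(0, 2.01, 0.25)
        down = fit_gradient(d, 100 - 30 * d, (0, 2))
        up = fit_gradient(d, 10 + 30 * d, (0, 2))
        assert diffusive_flux(ctx, diff, down).flux < 0
        assert diffusive_flux(ctx, diff, up).flux > 0

    def test_flux_increases_with_db_at_fixed_gradient(self):
        ctx = CoreContext("c", "t", 0.9, 8.0, 7.0, 0.0)
        d = np.arange(0, 2.01, 0.25)
        grad = fit_gradient(d, 10 + 30 * d, (0, 2))
        fluxes = [
            diffusive_flux(ctx, build_diffusivity("H2S", ctx, d_b=db), grad).flux
            for db in (0.0, 5e-5, 1e-4)
        ]
        assert fluxes[0] < fluxes[1] < fluxes[2]

    @settings(derandomize=True, max_examples=30)
    @given(offset=st.floats(-50, 500))
    def test_flux_invariant_under_concentration_offset(self, offset):
        ctx = CoreContext("c", "t", 0.88, 8.0, 7.0, 0.0)
        diff = build_diffusivity("H2S", ctx, d_b=3e-5)
        d = np.arange(0, 2.01, 0.25)
        base = 100 + 40 * d
        f1 = diffusive_flux(ctx, diff, fit_gradient(d, base, (0, 2))).flux
        f2 = diffusive_flux(ctx, diff, fit_gradient(d, base + offset, (0, 2))).flux
        assert f2 == pytest.approx(f1, rel=1e-9)

    def test_no_outer_porosity_convention(self):
        ctx = CoreContext("c", "t", 0.5, 8.0, 7.0, 0.0)
        d = np.arange(0, 1.01, 0.1)
        grad = fit_gradient(d, 300 - 100 * d, (0, 1))
        as_printed = diffusive_flux(ctx, self._diffusivity(), grad, "as_printed").flux
        no_outer = diffusive_flux(ctx, self._diffusivity(), grad, "no_outer_porosity").flux
        assert no_outer == pytest.approx(as_printed / 0.5)

    def test_flux_magnitude_identity(self):
        """|J| = phi (Ds+Db) |slope| to machine precision."""
        ctx = CoreContext("c", "t", 0.87, 8.0, 7.0, 0.0)
        diff = build_diffusivity("O2", ctx, d_b=2e-5)
        d = np.arange(0, 1.01, 0.1)
        grad = fit_gradient(d, 280 - 310 * d, (0, 1))
        fx = diffusive_flux(ctx, diff, grad)
        assert abs(fx.flux) == pytest.approx(
            ctx.porosity * (diff.d_s + diff.d_b) * abs(grad.slope), rel=1e-15
        )


class TestWindows:
    def test_o2_window_is_fraction_of_opd(self):
        assert o2_fit_window(2.0) == (0.0, 1.2)

    def test_sulfide_window_below_horizon(self):
        assert sulfide_fit_window(3.8) == (3.8, 4.8)

    def test_attenuation_closed_form(self):
        # OLS slope of the parabola over [0, w] is the interface gradient
        # times 1 − w/(2L); verify against a brute-force discrete fit
        L, C0, w = 1.6, 300.0, 0.9
        d = np.arange(0.0, w + 1e-9, 0.1)
        v = C0 * (1 - d / L) ** 2
        slope, _ = ols_oracle(d, v)
        interface = -2 * C0 / L
        assert slope / interface == pytest.approx(
            parabolic_window_attenuation(w, L), rel=1e-12
        )

    def test_attenuation_bounds(self):
        with pytest.raises(ValueError):
            parabolic_window_attenuation(2.0, 1.6)
        assert parabolic_window_attenuation(1.6, 1.6) == pytest.approx(0.5)
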