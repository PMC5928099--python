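"""Flux-gradient, stoichiometry, yield, upscaling and regression tests."""

import numpy as np
import pytest

from omzflux import budget
from omzflux.budget import (
    Profile,
    Reaction,
    StoichiometryModel,
    YieldModel,
    depth_integrate,
    diffusive_flux,
    dn_regression,
    estimate_flux,
    fit_gradient,
    inventory,
    nitrate_demand,
    percent_attribution,
    percent_contribution,
    volumetric_rate,
    yield_convert,
)


class TestStoichiometry:
    def test_partial_plus_s0_step_equals_full(self):
        m = StoichiometryModel()
        assert m.partial + m.s0_step == m.full

    def test_derived_molar_ratios(self):
        m = StoichiometryModel()
        assert m.no3_per_h2s == pytest.approx(8 / 5)
        assert m.no3_per_s0 == pytest.approx(6 / 5)
        assert m.no3_per_h2s_partial == pytest.approx(2 / 5)

    def test_unbalanced_reaction_rejected(self):
        bad = Reaction({"H2S": 5, "NO3": 7}, {"SO4": 5, "N2": 4, "H2O": 4, "H+": 2})
        with pytest.raises(ValueError, match="balance"):
            StoichiometryModel(full=bad)

    def test_demand_decomposition_full_equals_partial_plus_s0(self):
        """Fully oxidizing H2S = stopping at S0 plus oxidizing the implied S0."""
        h2s_flux = 7.6
        full = nitrate_demand(h2s_flux, mode="full_to_sulfate")
        partial = nitrate_demand(h2s_flux, mode="partial_to_S0")
        implied_s0 = nitrate_demand(0.0, s0_flux=h2s_flux)  # 6/5 per S
        assert full == pytest.approx(partial + implied_s0, rel=1e-12)


class TestFluxGradient:
    def test_linear_profile_slope_exact(self):
        z = np.arange(10.0, 41.0, 5.0)
        prof = Profile("U1", "NO3", z, 30.0 - 0.7 * z)
        assert fit_gradient(prof, 10, 40) == pytest.approx(-0.7, rel=1e-12)

    def test_constant_profile_zero_gradient_zero_flux(self):
        prof = Profile("U1", "NO3", [10.0, 20.0, 30.0], [5.0, 5.0, 5.0])
        g = fit_gradient(prof, 10, 30)
        assert g == pytest.approx(0.0, abs=1e-12)
        assert diffusive_flux(g) == pytest.approx(0.0, abs=1e-9)

    def test_two_point_window_reduces_to_finite_difference(self):
        prof = Profile("U1", "NO3", [12.0, 30.0, 50.0], [25.0, 0.0, 0.0])
        assert fit_gradient(prof, 12, 30) == pytest.approx(-25 / 18, rel=1e-12)

    def test_rejects_window_with_fewer_than_two_points(self):
        prof = Profile("U1", "NO3", [10.0, 20.0, 30.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="2 samples"):
            fit_gradient(prof, 11, 19)

    def test_nitrate_flux_hand_arithmetic(self):
        """25 -> 0 umol/L over 12 -> 30 m at Kz = 1.4e-4 m2/s: +16.8 down."""
        flux = diffusive_flux(-25.0 / 18.0)
        assert flux == pytest.approx(16.8, rel=1e-12)

    def test_sulfide_increasing_with_depth_fluxes_upward(self):
        prof = Profile("U1", "H2S", [30.0, 35.0, 40.0], [0.0, 3.0, 7.0])
        est = estimate_flux(prof, 30, 40)
        assert est.flux_mmol_m2_d < 0  # negative = upward

    def test_flux_linear_in_kz_and_gradient(self):
        assert diffusive_flux(-1.0, 2.8e-4) == pytest.approx(
            2 * diffusive_flux(-1.0, 1.4e-4)
        )
        assert diffusive_flux(-2.0) == pytest.approx(2 * diffusive_flux(-1.0))


class TestNitrateDemand:
    def test_full_oxidation_of_printed_sulfide_flux(self):
        assert nitrate_demand(7.6) == pytest.approx(12.16, rel=1e-12)

    def test_adding_s0_term(self):
        assert nitrate_demand(7.6, s0_flux=6.6) == pytest.approx(
            12.16 + 7.92, rel=1e-12
        )

    def test_zero_fluxes_zero_demand(self):
        assert nitrate_demand(0.0) == 0.0

    def test_sign_stripped(self):
        assert nitrate_demand(-7.6) == nitrate_demand(7.6)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            nitrate_demand(7.6, mode="to_thiosulfate")


class TestAttribution:
    def test_printed_fluxes_give_about_seventy_percent(self):
        pct = percent_attribution(nitrate_demand(7.6), 17.0)
        assert pct == pytest.approx(100 * 12.16 / 17.0, rel=1e-12)
        assert 70.0 <= pct <= 72.0

    def test_zero_demand_zero_percent(self):
        assert percent_attribution(0.0, 17.0) == 0.0

    def test_capped_at_hundred(self):
        assert percent_attribution(30.0, 17.0) == 100.0

    def test_zero_nitrate_flux_rejected(self):
        with pytest.raises(ValueError):
            percent_attribution(12.0, 0.0)

    def test_balanced_synthetic_chemocline_attributes_hundred_percent(self):
        """NO3 supply built to exactly match the full-oxidation demand of
        the upward sulfide flux closes the budget at 100%."""
        h2s = Profile("S", "H2S", [30.0, 35.0, 40.0], [0.0, 2.5, 5.0])
        s_flux = estimate_flux(h2s, 30, 40).flux_mmol_m2_d
        demand = nitrate_demand(s_flux)
        kz_day = budget.DEFAULT_KZ_M2_S * budget.SECONDS_PER_DAY
        grad = -demand / kz_day
        z = np.array([12.0, 21.0, 30.0])
        no3 = Profile("S", "NO3", z, 25.0 + grad * (z - 12.0))
        no3_flux = estimate_flux(no3, 12, 30).flux_mmol_m2_d
        assert percent_attribution(demand, no3_flux) == pytest.approx(100.0)


class TestYields:
    def test_no3_yield_scaling(self):
        y = YieldModel()
        assert y.y_no3_lo == pytest.approx(0.35 * 5 / 8, rel=1e-12)
        assert round(y.y_no3_lo, 2) == 0.22
        assert round(y.y_no3_hi, 2) == 0.36  # 0.58 * 5/8 = 0.3625

    def test_interval_division_oracle(self):
        # yields chosen so y_no3 = 0.22 / 0.37 exactly
        y = YieldModel(0.22 * 8 / 5, 0.37 * 8 / 5)
        lo, hi = yield_convert(100.0, y, "denitrification")
        assert lo == pytest.approx(100 / 0.37, rel=1e-9)
        assert hi == pytest.approx(100 / 0.22, rel=1e-9)

    def test_zero_cfix_degenerate_interval(self):
        assert yield_convert(0.0) == (0.0, 0.0)

    def test_s0_oxidation_uses_per_sulfur_yields(self):
        lo, hi = yield_convert(10.0, YieldModel(), "s0_oxidation")
        assert lo == pytest.approx(10 / 0.58)
        assert hi == pytest.approx(10 / 0.35)

    def test_invalid_yields_rejected(self):
        with pytest.raises(ValueError):
            YieldModel(0.0, 0.5)
        with pytest.raises(ValueError):
            YieldModel(0.6, 0.5)


class TestUpscaling:
    def test_volumetric_rate_examples(self):
        assert round(volumetric_rate(0.17, 1.3e8)) == 22
        assert volumetric_rate(0.19, 1.7e9) == pytest.approx(323.0, rel=1e-9)
        assert volumetric_rate(0.17, 0.0) == 0.0

    def test_constant_rate_rectangle(self):
        prof = Profile("U1", "rate_volumetric", [30.0, 50.0, 65.0],
                       [100.0, 100.0, 100.0], unit="nmol/L/d")
        assert depth_integrate(prof, 30, 65) == pytest.approx(3.5, rel=1e-12)

    def test_zero_width_window(self):
        prof = Profile("U1", "rate_volumetric", [30.0, 65.0], [1.0, 1.0])
        assert depth_integrate(prof, 40, 40) == 0.0

    def test_triangle_profile_matches_closed_form(self):
        prof = Profile("U1", "rate_volumetric", [30.0, 45.0, 60.0],
                       [0.0, 200.0, 0.0])
        # 0.5 * base * height, nmol/L/d*m -> mmol/m2/d
        assert depth_integrate(prof, 30, 60) == pytest.approx(
            0.5 * 30 * 200 * 1e-3, rel=1e-12
        )

    def test_window_interpolation_at_edges(self):
        prof = Profile("U1", "rate_volumetric", [0.0, 100.0], [0.0, 100.0])
        # linear ramp: integral over [25, 75] is mean value 50 x 50 m
        assert depth_integrate(prof, 25, 75) == pytest.approx(2.5, rel=1e-12)

    def test_window_outside_range_rejected(self):
        prof = Profile("U1", "rate_volumetric", [30.0, 65.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="outside"):
            depth_integrate(prof, 20, 65)

    def test_percent_contribution_examples(self):
        assert percent_contribution(13.4, 26.2) == 51
        assert percent_contribution(8.4, 8.0) == 100
        assert percent_contribution(0.32, 4.5) == 7
        with pytest.raises(ValueError):
            percent_contribution(1.0, 0.0)


class TestDnRegression:
    LINE_SLOPE, LINE_INTERCEPT = 1.14, -7.88

    def _rates_on_line(self, log_dens):
        return 10 ** (self.LINE_SLOPE * log_dens + self.LINE_INTERCEPT)

    def test_points_exactly_on_line_recovered(self):
        log_dens = np.linspace(7.0, 10.0, 12)
        res = dn_regression(10**log_dens, self._rates_on_line(log_dens))
        assert res.slope == pytest.approx(self.LINE_SLOPE, rel=1e-9)
        assert res.intercept == pytest.approx(self.LINE_INTERCEPT, rel=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_null_relationship_slope_centred_on_zero(self):
        rng = np.random.default_rng(23)
        slopes = []
        for _ in range(200):
            dens = 10 ** rng.uniform(7, 10, 30)
            rates = 10 ** rng.normal(0.0, 0.3, 30)
            slopes.append(dn_regression(dens, rates).slope)
        assert abs(np.mean(slopes)) < 0.05

    def test_recovery_at_realistic_scatter(self):
        """Scatter tuned to R^2 ~ 0.7: mean slope within 15% of truth."""
        rng = np.random.default_rng(29)
        slopes, r2s = [], []
        for _ in range(100):
            log_dens = rng.uniform(7.08, 9.96, 30)
            noise = rng.normal(0.0, 0.6057, 30)
            rates = 10 ** (np.log10(self._rates_on_line(log_dens)) + noise)
            res = dn_regression(10**log_dens, rates)
            slopes.append(res.slope)
            r2s.append(res.r_squared)
        assert np.mean(r2s) == pytest.approx(0.71, abs=0.1)
        assert np.mean(slopes) == pytest.approx(self.LINE_SLOPE, rel=0.15)

    def test_nonpositive_pairs_excluded_and_counted(self):
        dens = np.array([1e8, 1e9, 1e10, 0.0, 1e7])
        rates = np.array([10.0, 100.0, 1000.0, 5.0, -1.0])
        res = dn_regression(dens, rates)
        assert res.n_used == 3 and res.n_excluded == 2


class TestInventory:
    def test_single_station_hand_arithmetic(self):
        """10 umol/L over a 10 m column and 1e10 m^2: 1e9 moles."""
        prof = Profile("U1", "H2S", [10.0, 20.0], [10.0, 10.0])
        assert inventory({"U1": prof}, {"U1": 1e10}) == pytest.approx(1e9)

    def test_zero_concentration_zero_inventory(self):
        prof = Profile("U1", "H2S", [10.0, 20.0], [0.0, 0.0])
        assert inventory({"U1": prof}, {"U1": 1e10}) == 0.0

    def test_linear_in_area(self):
        prof = Profile("U1", "H2S", [10.0, 20.0, 30.0], [2.0, 5.0, 3.0])
        one = inventory({"U1": prof}, {"U1": 1e9})
        two = inventory({"U1": prof}, {"U1": 2e9})
        assert two == pytest.approx(2 * one)

    def test_missing_area_rejected(self):
        prof = Profile("U1", "H2S", [10.0, 20.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="area"):
            inventory({"U1": prof}, {})
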