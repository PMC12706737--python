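"""Two-film transfer velocities, fluxes, emissions and Monte Carlo."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from harborair import flux as F
from harborair import properties as P


@pytest.fixture(scope="module")
def coeffs():
    return F.COEFFICIENT_PRESETS["calibrated"]


class TestWaterSideVelocity:
    def test_calm_limit_is_stillwater_intercept(self, coeffs):
        assert F.water_side_velocity(268.2, 0.0, 23.0, coeffs) == \
            pytest.approx(coeffs.kw_a0 *
                          (F.schmidt_number_water(268.2, 23.0) /
                           coeffs.sc_ref) ** coeffs.sc_exponent)

    def test_heavier_congener_transfers_slower(self, coeffs):
        light = F.water_side_velocity(226.4, 5.0, 23.0, coeffs)
        heavy = F.water_side_velocity(393.6, 5.0, 23.0, coeffs)
        assert heavy < light

    def test_reference_schmidt_recovers_kref(self, coeffs):
        # invert the Schmidt correlation so Sc_i == Sc_ref exactly
        k = F.water_side_velocity(268.2, 5.0, 23.0, coeffs)
        sc = F.schmidt_number_water(268.2, 23.0)
        k_ref = coeffs.kw_a2 * 25.0 + coeffs.kw_a1 * 5.0 + coeffs.kw_a0
        assert k == pytest.approx(k_ref * (sc / coeffs.sc_ref) ** -0.5)

    def test_monotone_in_wind(self, coeffs):
        u = np.linspace(0.0, 12.0, 40)
        k = F.water_side_velocity(268.2, u, 23.0, coeffs)
        assert (np.diff(k) >= 0).all()

    def test_negative_wind_rejected(self, coeffs):
        with pytest.raises(ValueError):
            F.water_side_velocity(268.2, -1.0, 23.0, coeffs)


class TestAirSideVelocity:
    def test_calm_limit_positive(self, coeffs):
        assert F.air_side_velocity(292.0, 268.2, 0.0, 23.0, coeffs=coeffs) > 0

    def test_identity_diffusivity_ratio(self, coeffs):
        # water vapor's own molar mass/volume gives D_i == D_H2O
        k = F.air_side_velocity(18.02, 12.7, 4.0, 23.0, coeffs=coeffs)
        assert k == pytest.approx((0.2 * 4.0 + 0.3) * 864.0)

    def test_linear_correlation_hand_value(self, coeffs):
        # k_a = (0.2*4 + 0.3) cm/s * 864 * (D_i/D_H2O)^0.61, by hand
        d_i = F.air_diffusivity(292.0, 268.2, 23.0)
        d_w = F.water_vapor_air_diffusivity(23.0)
        expected = 1.1 * 864.0 * (d_i / d_w) ** 0.61
        assert F.air_side_velocity(292.0, 268.2, 4.0, 23.0, coeffs=coeffs) == \
            pytest.approx(expected)

    def test_monotone_in_wind(self, coeffs):
        u = np.linspace(0.0, 12.0, 40)
        k = F.air_side_velocity(292.0, 268.2, u, 23.0, coeffs=coeffs)
        assert (np.diff(k) > 0).all()


class TestOverallMtc:
    def test_hand_series_resistance(self):
        # 1/(1/3 + 1/(500*0.01)) = 1/(1/3 + 1/5) = 1.875
        assert F.overall_mtc(3.0, 500.0, 0.01) == pytest.approx(1.875)

    def test_symmetric_two_resistance(self):
        assert F.overall_mtc(2.0, 200.0, 0.01) == pytest.approx(1.0)

    def test_water_side_limited_asymptote(self):
        assert F.overall_mtc(3.0, 500.0, 1e9) == pytest.approx(3.0, rel=1e-6)

    def test_below_both_conductances(self):
        v = F.overall_mtc(3.0, 500.0, 0.01)
        assert v < 3.0 and v < 5.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            F.overall_mtc(0.0, 500.0, 0.01)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(kw=st.floats(0.01, 100.0), ka=st.floats(0.01, 1000.0),
           hp=st.floats(1e-4, 10.0))
    def test_always_below_min_conductance(self, kw, ka, hp):
        v = F.overall_mtc(kw, ka, hp)
        assert v <= min(kw, ka * hp) * (1 + 1e-12)


class TestFluxAndEmissions:
    def test_gradient_flux_hand_value(self):
        assert F.congener_flux(3.4, 132.0) == pytest.approx(448.8)

    def test_zero_source_and_linearity(self):
        assert F.congener_flux(3.4, 0.0) == 0.0
        assert F.congener_flux(3.4, 264.0) == pytest.approx(2 * F.congener_flux(3.4, 132.0))

    def test_emission_unit_conversion(self):
        # 450 ng/m2/d * 15e6 m2 = 6.75 g/d = 7.8125e-5 g/s
        assert F.emissions_from_flux(450.0, 1.5e7) == pytest.approx(7.8125e-5)
        assert F.emissions_from_flux(0.0, 1.5e7) == 0.0
        assert F.emissions_from_flux(450.0, 3.0e7) == \
            pytest.approx(2 * F.emissions_from_flux(450.0, 1.5e7))

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            F.emissions_from_flux(450.0, 0.0)


class TestSelectWorstCase:
    def test_top_three_by_total(self, water):
        cols = F.peak_columns(water)
        wc = F.select_worst_case(water, 3)
        totals = water[cols].sum(axis=1)
        manual = water.loc[totals.nlargest(3).index, cols].mean(axis=0)
        pd.testing.assert_series_equal(wc, manual)

    def test_identical_samples_degenerate(self, water):
        cols = F.peak_columns(water)
        clones = pd.concat([water.iloc[[0]]] * 5, ignore_index=True)
        wc = F.select_worst_case(clones, 3)
        np.testing.assert_allclose(wc.to_numpy(), water.iloc[0][cols].to_numpy(float))

    def test_k_equals_n_is_plain_mean(self, water):
        cols = F.peak_columns(water)
        wc = F.select_worst_case(water, len(water))
        np.testing.assert_allclose(wc.to_numpy(), water[cols].mean(axis=0).to_numpy())

    def test_too_few_samples_rejected(self, water):
        with pytest.raises(ValueError):
            F.select_worst_case(water.iloc[:2], 3)


class TestComputeFluxes:
    def test_additive_over_peaks(self, worst_case_132, met, table):
        res = F.compute_fluxes(worst_case_132, met, table)
        assert res["flux"].sum() == pytest.approx(
            (res["v_aw"] * worst_case_132).sum())

    def test_oracle_single_hour_single_peak(self, table, calm_met):
        """Brute-force recomputation of one hour/peak without the module path."""
        rec = P.record_for(table, "PCB44+47+65")
        conc = pd.Series({"PCB44+47+65": 132.0})
        res = F.compute_fluxes(conc, calm_met, table)
        c = F.COEFFICIENT_PRESETS["calibrated"]
        # independent evaluation from first principles
        sc = F.schmidt_number_water(rec.molar_volume, 23.0)
        kw = (c.kw_a2 * 16.0 + c.kw_a1 * 4.0) * (sc / 660.0) ** -0.5
        d_ratio = (F.air_diffusivity(rec.mw, rec.molar_volume, 23.0)
                   / F.water_vapor_air_diffusivity(23.0))
        ka = (0.2 * 4.0 + 0.3) * 864.0 * d_ratio ** 0.61
        h = rec.h298 * np.exp((rec.du_aw / 8.314) * (1 / 298.15 - 1 / 296.15))
        hp = h / (8.314 * 296.15)
        v = 1.0 / (1.0 / kw + 1.0 / (ka * hp))
        assert res["flux"].iloc[0] == pytest.approx(v * 132.0, rel=1e-10)

    def test_monotone_in_wind_speed(self, worst_case_132, met, table):
        breezy = met.copy()
        breezy["u10"] = met["u10"] * 1.5
        assert F.compute_fluxes(worst_case_132, breezy, table)["flux"].sum() > \
            F.compute_fluxes(worst_case_132, met, table)["flux"].sum()

    def test_monotone_in_water_temperature(self, worst_case_132, met, table):
        warm = met.copy()
        warm["t_water"] = met["t_water"] + 5.0
        assert F.compute_fluxes(worst_case_132, warm, table)["flux"].sum() > \
            F.compute_fluxes(worst_case_132, met, table)["flux"].sum()

    def test_gross_volatilization_nonnegative(self, worst_case_132, met, table):
        res = F.compute_fluxes(worst_case_132, met, table)
        assert (res["flux"] >= 0).all()
        assert (res["v_aw"] >= 0).all()


class TestMonteCarlo:
    def test_degenerate_distributions_collapse_to_deterministic(
            self, worst_case_132, met, table):
        det = F.compute_fluxes(worst_case_132, met, table)
        mc = F.monte_carlo_flux(worst_case_132, met.iloc[:1], table,
                                n_iter=100, seed=4, conc_sd_log=0.0,
                                henry_sd_log=0.0)
        det1 = F.compute_fluxes(worst_case_132, met.iloc[:1], table)
        assert mc["total_sd"] == pytest.approx(0.0, abs=1e-9)
        assert mc["total_mean"] == pytest.approx(det1["flux"].sum(), rel=1e-12)

    def test_seeded_reproducibility(self, worst_case_132, met, table):
        a = F.monte_carlo_flux(worst_case_132, met, table, n_iter=200, seed=9)
        b = F.monte_carlo_flux(worst_case_132, met, table, n_iter=200, seed=9)
        assert a["total_mean"] == b["total_mean"]
        pd.testing.assert_frame_equal(a["per_peak"], b["per_peak"])

    def test_small_n_iter_rejected(self, worst_case_132, met, table):
        with pytest.raises(ValueError):
            F.monte_carlo_flux(worst_case_132, met, table, n_iter=50, seed=1)

    def test_seed_required(self, worst_case_132, met, table):
        with pytest.raises(ValueError):
            F.monte_carlo_flux(worst_case_132, met, table, n_iter=200, seed=None)
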