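"""Emission model: activity-factor identities, acclimation windows, simulation."""
import numpy as np
import pandas as pd
import pytest

import sedgeflux as sf
from sedgeflux.megan import leaf_flux


def raw_met(t_air, ppfd, step_min=60):
    n = len(t_air)
    ts = pd.date_range("2022-08-01", periods=n, freq=f"{step_min}min")
    return pd.DataFrame({"timestamp": ts, "t_air": t_air, "ppfd": ppfd})


class TestRollingAcclimation:
    def test_constant_series_means_are_constant(self):
        met = sf.rolling_acclimation(raw_met([300.0] * 48, [500.0] * 48))
        assert (met["t24"] == 300.0).all() and (met["t240"] == 300.0).all()
        assert (met["p24"] == 500.0).all()

    def test_first_record_expanding_window(self):
        met = sf.rolling_acclimation(raw_met([290.0, 310.0], [0.0, 800.0]))
        assert met["t24"].iloc[0] == 290.0  # window of one
        assert met["t24"].iloc[1] == 300.0

    def test_daytime_conditional_ppfd_mean(self):
        # square-wave 12 h day / 12 h night: daytime-conditional mean stays 1000
        ppfd = ([1000.0] * 12 + [0.0] * 12) * 2
        met = sf.rolling_acclimation(raw_met([300.0] * 48, ppfd))
        assert met["p24"].iloc[-1] == pytest.approx(1000.0)
        assert met["p240"].iloc[-1] == pytest.approx(1000.0)

    def test_irregular_timestamps_rejected(self):
        met = raw_met([300.0] * 3, [0.0] * 3)
        met.loc[2, "timestamp"] += pd.Timedelta(minutes=7)
        with pytest.raises(sf.ValidationError, match="uniform"):
            sf.rolling_acclimation(met)


class TestGammaTMegan:
    def test_at_optimum_equals_eopt(self):
        coef = sf.MeganCoefficients()
        # t240 = 297 -> Topt = 313 K; x = 0 collapses the quotient to 1
        assert sf.gamma_t_megan(313.0, 297.0, 297.0, coef) == pytest.approx(
            coef.eopt_base, rel=1e-12)

    def test_standard_condition_normalization(self):
        # 303 K leaf with 297 K acclimation is the model's standard point
        assert sf.gamma_t_megan(303.0, 297.0, 297.0) == pytest.approx(1.0, abs=0.001)

    def test_value_at_30C_frozen(self):
        # hand evaluation of the closed form at 303.15 K (see docs)
        assert sf.gamma_t_megan(303.15, 297.0, 297.0) == pytest.approx(1.0172, abs=5e-4)

    def test_rising_limb_monotonic(self):
        assert sf.gamma_t_megan(308.15, 297.0, 297.0) > sf.gamma_t_megan(
            298.15, 297.0, 297.0)

    def test_warm_acclimation_raises_peak_and_optimum(self):
        coef = sf.MeganCoefficients()
        warm = sf.gamma_t_megan(313.0, 302.0, 302.0, coef)
        std = sf.gamma_t_megan(313.0, 297.0, 297.0, coef)
        assert warm > std

    def test_extreme_temperatures_do_not_overflow(self):
        vals = sf.gamma_t_megan(np.array([200.0, 400.0]), 297.0, 297.0)
        assert np.isfinite(vals).all() and (vals >= 0).all()


class TestGammaP:
    def test_dark_means_zero(self):
        # light off -> emission off (no storage pool)
        assert sf.gamma_p(0.0, 200.0, 200.0) == 0.0

    def test_standard_value_at_1000(self):
        # frozen from direct evaluation: alpha=0.001351, C_P=1.124
        assert sf.gamma_p(1000.0, 200.0, 200.0) == pytest.approx(0.904, abs=0.002)

    def test_saturates_toward_cp(self):
        coef = sf.MeganCoefficients()
        alpha = coef.alpha_base - coef.alpha_slope * np.log(200.0)
        c_p = coef.cp_base * 200.0 ** 0.6
        assert sf.gamma_p(1e7, 200.0, 200.0, coef) == pytest.approx(c_p, rel=1e-3)
        assert sf.gamma_p(1000.0, 200.0, 200.0, coef) < c_p

    def test_no_daylight_history_returns_zero(self):
        assert sf.gamma_p(500.0, 0.0, 0.0) == 0.0


class TestLeafFluxAndSimulation:
    def test_dark_flux_zero_for_both_response_kinds(self, sedge):
        step = {"t_air": 303.15, "ppfd": 0.0, "t24": 297.0, "t240": 297.0,
                "p24": 200.0, "p240": 200.0}
        megan_sp = sf.SpeciesParams("m", 2.0, 1.5, "megan_default")
        assert leaf_flux(sedge, step) == 0.0
        assert leaf_flux(megan_sp, step) == 0.0

    def test_flux_linear_in_emission_factor_and_lai(self, met_with_heatwave, sedge):
        double_ef = sf.SpeciesParams("s2", 4.0, 1.5, "exponential", q10=7.2)
        f1 = sf.simulate_flux_series(sedge, met_with_heatwave).flux
        f2 = sf.simulate_flux_series(double_ef, met_with_heatwave).flux
        np.testing.assert_allclose(f2, 2 * f1, rtol=1e-12)

    def test_exponential_reference_identity(self):
        # at 30 degC the temperature factor is 1, so flux = EF * LAI * gamma_P
        sp = sf.SpeciesParams("s", 2.0, 1.5, "exponential", q10=7.2)
        step = {"t_air": 303.15, "ppfd": 1000.0, "t24": 297.0, "t240": 297.0,
                "p24": 200.0, "p240": 200.0}
        gp = sf.gamma_p(1000.0, 200.0, 200.0)
        assert leaf_flux(sp, step) == pytest.approx(2.0 * 1.5 * gp, rel=1e-12)

    def test_simulation_requires_acclimation(self, sedge):
        met = raw_met([300.0] * 4, [500.0] * 4)
        with pytest.raises(sf.ValidationError, match="rolling_acclimation"):
            sf.simulate_flux_series(sedge, met)

    def test_simulation_deterministic_and_aligned(self, met_with_heatwave, sedge):
        a = sf.simulate_flux_series(sedge, met_with_heatwave)
        b = sf.simulate_flux_series(sedge, met_with_heatwave)
        assert a.data.equals(b.data)
        assert len(a.data) == len(met_with_heatwave)
        assert (a.flux >= 0).all()

    def test_all_dark_series_gives_zero_flux(self, sedge):
        met = sf.rolling_acclimation(raw_met([300.0] * 24, [0.0] * 24))
        assert (sf.simulate_flux_series(sedge, met).flux == 0).all()

    def test_constant_daytime_conditions_give_stable_flux(self, sedge):
        # after spin-up under constant light/temperature the emission holds steady
        n = 24 * 12
        met = sf.rolling_acclimation(raw_met([303.15] * n, [1000.0] * n))
        flux = sf.simulate_flux_series(sedge, met).flux
        tail = flux.iloc[-8:]
        assert tail.max() - tail.min() <= 1e-9 * tail.max()

    def test_daytime_flux_increases_with_temperature(self):
        sp = sf.SpeciesParams("s", 2.0, 1.5, "exponential", q10=7.2)
        base = {"ppfd": 1000.0, "t24": 297.0, "t240": 297.0, "p24": 200.0, "p240": 200.0}
        fluxes = [leaf_flux(sp, {**base, "t_air": t}) for t in (295.0, 300.0, 305.0, 310.0)]
        assert all(b > a for a, b in zip(fluxes, fluxes[1:]))
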