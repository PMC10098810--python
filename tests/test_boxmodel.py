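"""Mixed-layer box model: gas exchange, NCP, stepping, conservation."""

import numpy as np
import pytest

from dielco2.boxmodel import (
    BoxState,
    ForcingSeries,
    NCPParams,
    airsea_flux,
    gas_transfer_velocity,
    ncp_tendencies,
    run,
    schmidt_number,
    step,
)
from dielco2.carbsys import (
    SeawaterState,
    compute_constants,
    equilibrate_to_atmosphere,
    solve_system,
)
from dielco2.synthgen import DIURNAL_SHAPE


def _day_par():
    """Daylight in slots 3-6 (09:00-21:00), peaking at midday."""
    return np.array([0, 0, 0, 0.5, 1.0, 0.8, 0.2, 0.0])


class TestGasTransfer:
    def test_zero_wind_gives_zero(self):
        assert gas_transfer_velocity(0.0, 20.0) == 0.0

    def test_quadratic_law(self):
        assert gas_transfer_velocity(8.0, 15.0) == pytest.approx(
            4.0 * gas_transfer_velocity(4.0, 15.0))

    def test_published_coefficients_at_7p5ms_20C(self):
        """Direct evaluation of the quadratic-wind relation at u10=7.5, 20 °C."""
        sc = 2116.8 - 136.25 * 20 + 4.7353 * 20**2 - 0.092307 * 20**3 \
            + 0.0007555 * 20**4
        expect = 0.251 * 7.5**2 * (sc / 660.0) ** -0.5  # cm/h
        k = gas_transfer_velocity(7.5, 20.0)
        assert k == pytest.approx(expect * 0.01 / 3600.0, rel=1e-12)
        assert k == pytest.approx(3.92e-5, rel=0.01)  # m/s, hand evaluation

    def test_schmidt_polynomial_validity(self):
        assert schmidt_number(20.0) == pytest.approx(668.0, abs=1.0)
        with pytest.raises(ValueError):
            schmidt_number(45.0)


class TestAirSeaFlux:
    def test_no_gradient_no_flux(self):
        assert airsea_flux(1e-5, 0.03, 1025.0, 400.0, 400.0) == 0.0

    def test_sign_follows_gradient(self):
        into = airsea_flux(1e-5, 0.03, 1025.0, 450.0, 400.0)
        outof = airsea_flux(1e-5, 0.03, 1025.0, 350.0, 400.0)
        assert into > 0 > outof

    def test_linear_in_k_and_ice_scaling(self):
        f1 = airsea_flux(1e-5, 0.03, 1025.0, 450.0, 400.0)
        assert airsea_flux(2e-5, 0.03, 1025.0, 450.0, 400.0) == 2 * f1
        assert airsea_flux(1e-5, 0.03, 1025.0, 450.0, 400.0, ice=0.75) == \
            pytest.approx(0.25 * f1)


class TestNCP:
    def test_no_light_no_respiration_is_inert(self):
        ddic, dalk = ncp_tendencies(np.zeros(8), NCPParams(0.0, 0.0))
        assert np.all(ddic == 0) and np.all(dalk == 0)

    def test_daily_integral_equals_net(self):
        par = np.tile(_day_par(), 3)
        for net in (0.0, 0.7):
            ddic, _ = ncp_tendencies(par, NCPParams(gross_daily=2.0,
                                                    net_daily=net))
            daily = ddic.reshape(3, 8).sum(1)
            np.testing.assert_allclose(daily, -net, atol=1e-12)

    def test_midday_drawdown_positive(self):
        ddic, _ = ncp_tendencies(_day_par(), NCPParams(gross_daily=2.0))
        assert ddic[4] < 0  # peak light draws DIC down
        assert ddic[0] > 0  # night respiration returns it

    def test_calcification_removes_alk_twice_dic(self):
        p = NCPParams(gross_daily=2.0, net_daily=0.0, calc_frac=0.1)
        ddic, dalk = ncp_tendencies(_day_par(), p)
        ddic0, _ = ncp_tendencies(_day_par(), NCPParams(2.0, 0.0))
        extra = ddic - ddic0  # the calcification part of the DIC tendency
        np.testing.assert_allclose(dalk, 2.0 * extra, atol=1e-15)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            NCPParams(gross_daily=-1.0)
        with pytest.raises(ValueError):
            NCPParams(gross_daily=1.0, net_daily=2.0)


def _quiet_forcing(n_days=1, xco2=284.0, sst=18.0, u10=0.0):
    n = 8 * n_days
    return ForcingSeries(xco2=np.full(n, xco2), sst=np.full(n, sst),
                         u10=np.full(n, u10), par=np.zeros(n))


def _box(dic=2000.0, t=18.0):
    return BoxState(SeawaterState(t, 35.0, dic, 2300.0), depth=30.0)


class TestStepAndRun:
    def test_zero_wind_zero_ncp_preserves_dic(self):
        out = run(_box(), _quiet_forcing(2))
        np.testing.assert_allclose(out.dic, np.full_like(out.dic, 2000.0),
                                   rtol=0, atol=1e-12)

    def test_one_day_has_eight_rows(self):
        out = run(_box(), _quiet_forcing(1))
        assert out.pco2.shape[-1] == 8

    def test_replay_is_bit_identical(self):
        f = ForcingSeries(xco2=284.0, sst=18 + 0.3 * DIURNAL_SHAPE,
                          u10=np.full(8, 7.0), par=_day_par())
        ncp = NCPParams(gross_daily=1.5)
        a = run(_box(), f, ncp)
        b = run(_box(), f, ncp)
        assert np.array_equal(a.pco2, b.pco2)
        assert np.array_equal(a.dic, b.dic)

    def test_thermally_forced_day_peaks_with_sst(self):
        sst = 18.0 + 0.5 * DIURNAL_SHAPE
        f = ForcingSeries(xco2=284.0, sst=sst, u10=np.full(8, 7.0),
                          par=np.zeros(8))
        out = run(_box(), f)
        assert np.argmax(out.pco2[0]) == np.argmax(sst)

    def test_empty_forcing_rejected(self):
        with pytest.raises(ValueError):
            ForcingSeries(xco2=284.0, sst=np.empty((1, 0)), u10=0.0, par=0.0)

    def test_carbon_budget_closes(self):
        rng = np.random.default_rng(11)
        f = ForcingSeries(
            xco2=400.0,
            sst=18 + rng.normal(0, 0.3, 80),
            u10=rng.lognormal(2.0, 0.3, 80),
            par=np.tile(_day_par(), 10),
        )
        out = run(_box(), f, NCPParams(gross_daily=2.0, net_daily=0.5))
        assert np.max(np.abs(out.carbon_closure)) < 1e-9 * 2000.0

    def test_relaxation_toward_atmosphere(self):
        """Constant forcing: pCO2 relaxes to the atmospheric value with the
        linearized e-folding time depth / (k K0 dpCO2/dDIC)."""
        eq = equilibrate_to_atmosphere(SeawaterState(18.0, 35.0, 2000.0,
                                                     2300.0), 400.0)
        box = BoxState(eq.replace(dic=eq.dic - 20.0), depth=30.0)
        days = 120
        f = _quiet_forcing(days, xco2=400.0, u10=10.0)
        out = run(box, f)
        gap = 400.0 - out.pco2[0]
        assert gap[0] > 0 and gap[-1] < gap[0]  # monotone approach

        # analytic linearization
        cons = compute_constants(eq)
        k = gas_transfer_velocity(10.0, 18.0)
        up = solve_system(eq.replace(dic=eq.dic + 1.0))
        dpdc = (float(up.pco2) - 400.0) / 1e-6  # µatm per mol kg-1
        tau = 30.0 / (k * float(cons.k0) * dpdc * 1e-6)  # seconds
        # fitted e-folding from the simulated decay
        t = np.arange(days * 8) * 3 * 3600.0
        fit = -1.0 / np.polyfit(t, np.log(gap), 1)[0]
        assert fit == pytest.approx(tau, rel=0.10)

    def test_step_sets_temperature_and_conserves(self):
        box = _box()
        new, res, flux = step(box, 400.0, 19.0, 5.0)
        assert float(new.state.temperature) == 19.0
        rho = new.density
        ddic = float(new.state.dic - box.state.dic)
        assert ddic == pytest.approx(
            float(flux) * 3 * 3600 / (30.0 * float(rho)) * 1e6, rel=1e-12)
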