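"""Equilibrium solver: constants anchors, speciation closure, monotonicity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dielco2.carbsys import (
    CarbsysError,
    ConvergenceError,
    SeawaterState,
    compute_constants,
    equilibrate_to_atmosphere,
    seawater_density,
    solve_system,
)

import reference_chemistry as ref


class TestConstants:
    def test_published_check_values_at_25C_S35(self):
        """pK values printed by the source formulations at T=25 °C, S=35."""
        c = compute_constants(SeawaterState(25.0, 35.0, 2000.0, 2300.0))
        assert -np.log10(c.k1) == pytest.approx(5.8472, abs=5e-4)
        assert -np.log10(c.k2) == pytest.approx(8.9660, abs=5e-4)
        assert c.k0 == pytest.approx(2.839e-2, rel=2e-3)
        assert -np.log10(c.kb) == pytest.approx(8.5975, abs=2e-3)
        assert -np.log10(c.ksp_calc) == pytest.approx(6.3693, abs=2e-3)
        assert -np.log10(c.ksp_arag) == pytest.approx(6.1883, abs=2e-3)

    def test_reference_agreement_across_ts_plane(self):
        """pK agreement with the independently coded reference constants."""
        for t in (-1.0, 5.0, 18.0, 30.0):
            for s in (31.0, 35.0, 38.0):
                c = compute_constants(SeawaterState(t, s, 2000.0, 2300.0))
                k = ref.constants(t, s)
                for mine, theirs in [(c.k1, k["K1"]), (c.k2, k["K2"]),
                                     (c.kw, k["KW"]), (c.kb, k["KB"]),
                                     (c.ksi, k["KSi"]), (c.ks, k["KS"])]:
                    assert -np.log10(mine) == pytest.approx(
                        -np.log10(theirs), abs=1e-4)

    def test_solubility_decreases_with_temperature(self):
        cold = compute_constants(SeawaterState(0.0, 35.0, 2000.0, 2300.0))
        warm = compute_constants(SeawaterState(30.0, 35.0, 2000.0, 2300.0))
        assert cold.k0 > warm.k0

    def test_fresh_water_has_zero_salinity_totals(self):
        c = compute_constants(SeawaterState(15.0, 0.0, 2000.0, 2300.0))
        for tot in (c.total_borate, c.total_sulfate, c.total_fluoride,
                    c.total_calcium):
            assert tot == 0.0

    def test_k1_exceeds_k2(self, state_sample):
        c = compute_constants(state_sample)
        assert np.all(c.k1 > c.k2)

    @pytest.mark.parametrize("field,value", [
        ("temperature", 45.0), ("temperature", -5.0), ("salinity", 50.0),
    ])
    def test_out_of_range_names_offending_field(self, field, value):
        with pytest.raises(CarbsysError, match=field):
            SeawaterState(**{**dict(temperature=18.0, salinity=35.0,
                                    dic=2000.0, alkalinity=2300.0),
                             field: value})


class TestSolveSystem:
    def test_example_state_matches_reference(self, example_state):
        mine = solve_system(example_state)
        theirs = ref.solve(18.0, 35.0, 2050.0, 2300.0, 0.5, 5.0)
        assert float(mine.pco2) == pytest.approx(theirs["pco2"], abs=1.0)
        assert float(mine.ph) == pytest.approx(theirs["ph"], abs=0.002)
        assert float(mine.omega_arag) == pytest.approx(
            theirs["omega_arag"], abs=0.01)

    def test_speciation_closes_to_dic(self, state_sample):
        r = solve_system(state_sample)
        total = r.co2aq + r.hco3 + r.co3
        np.testing.assert_allclose(total, state_sample.dic, rtol=1e-6)

    def test_alkalinity_round_trip(self, state_sample):
        """Re-evaluating TA at the returned [H+] reproduces the input A_T."""
        r = solve_system(state_sample)
        for i in range(0, 1000, 37):
            k = ref.constants(float(state_sample.temperature[i]),
                              float(state_sample.salinity[i]))
            ta = ref.total_alkalinity(
                float(r.hplus[i]) * 1e-9,
                float(state_sample.dic[i]) * 1e-6,
                float(state_sample.phosphate[i]) * 1e-6,
                float(state_sample.silicate[i]) * 1e-6, k)
            assert ta * 1e6 == pytest.approx(
                float(state_sample.alkalinity[i]), rel=1e-5)

    def test_ph_is_log_of_hplus(self, example_state):
        r = solve_system(example_state)
        assert float(r.ph) == pytest.approx(
            -np.log10(float(r.hplus) * 1e-9), abs=1e-12)

    def test_aragonite_less_saturated_than_calcite(self, state_sample):
        r = solve_system(state_sample)
        assert np.all(r.omega_arag < r.omega_calc)

    def test_no_root_raises_with_diagnostics(self):
        # alkalinity beyond what any [H+] in the bracket can balance
        state = SeawaterState(18.0, 35.0, 2000.0, 1.0e5)
        with pytest.raises(ConvergenceError, match="bracket"):
            solve_system(state)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        t=st.floats(0.0, 32.0), s=st.floats(30.0, 38.0),
        alk=st.floats(2200.0, 2400.0), frac=st.floats(0.88, 0.97),
    )
    def test_monotonicity_in_drivers(self, t, s, alk, frac):
        """pCO2 and [H+] increase with C_T and T, decrease with A_T."""
        base = SeawaterState(t, s, alk * frac, alk)
        r0 = solve_system(base)
        up_dic = solve_system(base.replace(dic=base.dic + 5.0))
        up_alk = solve_system(base.replace(alkalinity=base.alkalinity + 5.0))
        up_t = solve_system(base.replace(temperature=base.temperature + 0.5))
        assert up_dic.pco2 > r0.pco2 and up_dic.hplus > r0.hplus
        assert up_alk.pco2 < r0.pco2 and up_alk.hplus < r0.hplus
        assert up_t.pco2 > r0.pco2


class TestOracleEquivalence:
    def test_thousand_state_sample(self, state_sample):
        """Vectorized solver vs brute-force reference on 1000 states."""
        mine = solve_system(state_sample)
        pco2 = np.empty(1000)
        ph = np.empty(1000)
        om = np.empty(1000)
        for i in range(1000):
            out = ref.solve(float(state_sample.temperature[i]),
                            float(state_sample.salinity[i]),
                            float(state_sample.dic[i]),
                            float(state_sample.alkalinity[i]),
                            float(state_sample.phosphate[i]),
                            float(state_sample.silicate[i]))
            pco2[i], ph[i], om[i] = out["pco2"], out["ph"], out["omega_arag"]
        assert np.max(np.abs(mine.pco2 - pco2)) <= 1.0
        assert np.max(np.abs(mine.ph - ph)) <= 0.002
        assert np.max(np.abs(mine.omega_arag - om)) <= 0.01


class TestEquilibration:
    def test_post_condition_at_284ppm(self):
        template = SeawaterState(18.0, 34.7, 2000.0, 2300.0)
        eq = equilibrate_to_atmosphere(template, 284.0)
        r = solve_system(eq)
        assert float(r.pco2) == pytest.approx(284.0, abs=0.01)
        assert float(r.ph) == pytest.approx(8.17, abs=0.05)

    def test_buffer_factor_bounds_dic_uptake(self):
        """Doubling CO2 adds less DIC than the linear no-buffering estimate.

        The Revelle factor R = (dpCO2/pCO2)/(dC_T/C_T) is ~10 for surface
        seawater, so DIC at 568 ppm minus DIC at 284 ppm must be positive
        yet below dic(284) * (568/284 - 1) / R.
        """
        template = SeawaterState(18.0, 35.0, 2000.0, 2300.0)
        lo = equilibrate_to_atmosphere(template, 284.0)
        hi = equilibrate_to_atmosphere(template, 568.0)
        # Revelle factor by finite difference of the reference solver
        c0 = float(lo.dic)
        p1 = ref.solve(18.0, 35.0, c0 * 1.001, 2300.0)["pco2"]
        revelle = (p1 / 284.0 - 1.0) / 0.001
        assert 8.0 < revelle < 14.0
        gained = float(hi.dic) - c0
        assert 0.0 < gained < c0 * (568.0 / 284.0 - 1.0) / revelle

    def test_thermal_sensitivity_in_takahashi_range(self, state_sample):
        """(dpCO2/dT)/pCO2 within 3.5-5.0 %/°C for pCO2 in [200, 1200]."""
        r0 = solve_system(state_sample)
        keep = (r0.pco2 > 200) & (r0.pco2 < 1200)
        up = solve_system(state_sample.replace(
            temperature=state_sample.temperature + 0.05))
        dn = solve_system(state_sample.replace(
            temperature=state_sample.temperature - 0.05))
        frac = ((up.pco2 - dn.pco2) / 0.1 / r0.pco2)[keep]
        assert frac.min() > 0.035 and frac.max() < 0.050

    def test_sensitivity_triples_with_carbon_uptake(self):
        """dpCO2/dT after equilibration to 1090 ppm is >= 3x that at 284."""
        template = SeawaterState(18.0, 35.0, 2000.0, 2300.0)
        slopes = {}
        for x in (284.0, 1090.0):
            eq = equilibrate_to_atmosphere(template, x)
            up = solve_system(eq.replace(temperature=18.05))
            dn = solve_system(eq.replace(temperature=17.95))
            slopes[x] = float(up.pco2 - dn.pco2) / 0.1
        assert slopes[1090.0] >= 3.0 * slopes[284.0]

    def test_out_of_range_target_raises(self):
        template = SeawaterState(18.0, 35.0, 2000.0, 2300.0)
        with pytest.raises(CarbsysError):
            equilibrate_to_atmosphere(template, 50.0)


def test_density_plausible_range():
    rho = seawater_density(np.array([-1.0, 18.0, 30.0]), 35.0)
    assert np.all((rho > 1018) & (rho < 1029))
    # colder water is denser
    assert rho[0] > rho[1] > rho[2]
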