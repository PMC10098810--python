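"""Independent brute-force reference for the carbonate-system solver.

A deliberately simple scalar implementation used only as a cross-check in
tests: the equilibrium constants are typed here a second time, directly
from the primary formulations (Lueker et al. 2000; Dickson 1990a, 1990b;
Millero 1995; Perez & Fraga 1987; Weiss 1974; Mucci 1983), and the
total-alkalinity balance is solved by bracketed root finding
(scipy.optimize.brentq over pH) rather than the package's vectorized
Newton iteration.  Agreement therefore checks the production code's
constants, alkalinity expression and root-finding independently of its
implementation strategy.

This is a synthetic stand-in for an external reference package; it shares
the published formulas (checked against their printed values at T=25 °C,
S=35) but none of the production code.
"""

from __future__ import annotations

import math

from scipy.optimize import brentq


def constants(t_c: float, s: float) -> dict:
    """Equilibrium constants at surface pressure, total pH scale."""
    t = t_c + 273.15
    lt = math.log(t)
    sq = math.sqrt(s)
    ion = 19.924 * s / (1000.0 - 1.005 * s)

    out = {}
    out["TB"] = 0.000232 / 10.811 * s / 1.80655
    out["TS"] = 0.14 / 96.062 * s / 1.80655
    out["TF"] = 0.000067 / 18.998 * s / 1.80655
    out["Ca"] = 0.02128 / 40.087 * s / 1.80655

    out["KS"] = math.exp(
        -4276.1 / t + 141.328 - 23.093 * lt
        + (-13856.0 / t + 324.57 - 47.986 * lt) * math.sqrt(ion)
        + (35474.0 / t - 771.54 + 114.723 * lt) * ion
        - 2698.0 / t * ion ** 1.5 + 1776.0 / t * ion ** 2
        + math.log(1.0 - 0.001005 * s)
    )
    ftot = 1.0 + out["TS"] / out["KS"]
    out["KF"] = math.exp(874.0 / t - 9.68 + 0.111 * sq) / ftot  # free scale
    swst = ftot / (ftot + out["TF"] / out["KF"])

    out["K0"] = math.exp(
        -60.2409 + 93.4517 * 100.0 / t + 23.3585 * math.log(t / 100.0)
        + s * (0.023517 - 0.023656 * t / 100.0 + 0.0047036 * (t / 100.0) ** 2)
    )
    out["K1"] = 10.0 ** -(3633.86 / t - 61.2172 + 9.67770 * lt
                          - 0.011555 * s + 0.0001152 * s * s)
    out["K2"] = 10.0 ** -(471.78 / t + 25.9290 - 3.16967 * lt
                          - 0.01781 * s + 0.0001122 * s * s)
    out["KB"] = math.exp(
        (-8966.90 - 2890.53 * sq - 77.942 * s + 1.728 * s ** 1.5
         - 0.0996 * s * s) / t
        + 148.0248 + 137.1942 * sq + 1.62142 * s
        - (24.4344 + 25.085 * sq + 0.2474 * s) * lt
        + 0.053105 * sq * t
    )
    out["KW"] = math.exp(
        148.9802 - 13847.26 / t - 23.6521 * lt
        + (118.67 / t - 5.977 + 1.0495 * lt) * sq - 0.01615 * s
    ) * swst
    out["KP1"] = math.exp(
        -4576.752 / t + 115.525 - 18.453 * lt
        + (-106.736 / t + 0.69171) * sq + (-0.65643 / t - 0.01844) * s
    ) * swst
    out["KP2"] = math.exp(
        -8814.715 / t + 172.0883 - 27.927 * lt
        + (-160.340 / t + 1.3566) * sq + (0.37335 / t - 0.05778) * s
    ) * swst
    out["KP3"] = math.exp(
        -3070.75 / t - 18.141
        + (17.27039 / t + 2.81197) * sq + (-44.99486 / t - 0.09984) * s
    ) * swst
    out["KSi"] = math.exp(
        -8904.2 / t + 117.385 - 19.334 * lt
        + (-458.79 / t + 3.5913) * math.sqrt(ion)
        + (188.74 / t - 1.5998) * ion
        + (-12.1652 / t + 0.07871) * ion ** 2
        + math.log(1.0 - 0.001005 * s)
    ) * swst
    out["KspC"] = 10.0 ** (
        -171.9065 - 0.077993 * t + 2839.319 / t + 71.595 * math.log10(t)
        + (-0.77712 + 0.0028426 * t + 178.34 / t) * sq
        - 0.07711 * s + 0.0041249 * s ** 1.5
    )
    out["KspA"] = 10.0 ** (
        -171.945 - 0.077993 * t + 2903.293 / t + 71.595 * math.log10(t)
        + (-0.068393 + 0.0017276 * t + 88.135 / t) * sq
        - 0.10018 * s + 0.0059415 * s ** 1.5
    )
    return out


def total_alkalinity(h: float, dic: float, tp: float, tsi: float,
                     k: dict) -> float:
    """TA (mol kg-1) from total-scale [H+] and DIC (mol kg-1)."""
    den = h * h + k["K1"] * h + k["K1"] * k["K2"]
    hco3 = dic * k["K1"] * h / den
    co3 = dic * k["K1"] * k["K2"] / den
    boh4 = k["TB"] * k["KB"] / (k["KB"] + h)
    oh = k["KW"] / h
    hfree = h / (1.0 + k["TS"] / k["KS"])
    hso4 = k["TS"] * hfree / (k["KS"] + hfree)
    hf = k["TF"] * hfree / (k["KF"] + hfree)
    h3 = h ** 3
    dp = h3 + k["KP1"] * h * h + k["KP1"] * k["KP2"] * h \
        + k["KP1"] * k["KP2"] * k["KP3"]
    p_alk = tp * (k["KP1"] * k["KP2"] * h
                  + 2.0 * k["KP1"] * k["KP2"] * k["KP3"] - h3) / dp
    sioh3 = tsi * k["KSi"] / (k["KSi"] + h)
    return hco3 + 2.0 * co3 + boh4 + oh + p_alk + sioh3 - hfree - hso4 - hf


def solve(t_c: float, s: float, dic_umol: float, alk_umol: float,
          po4_umol: float = 0.0, si_umol: float = 0.0) -> dict:
    """Scalar CO2-system solution via brentq over pH in [2, 12]."""
    k = constants(t_c, s)
    dic, alk = dic_umol * 1e-6, alk_umol * 1e-6
    tp, tsi = po4_umol * 1e-6, si_umol * 1e-6

    def f(ph):
        return total_alkalinity(10.0 ** -ph, dic, tp, tsi, k) - alk

    ph = brentq(f, 2.0, 12.0, xtol=1e-12)
    h = 10.0 ** -ph
    den = h * h + k["K1"] * h + k["K1"] * k["K2"]
    co2 = dic * h * h / den
    co3 = dic * k["K1"] * k["K2"] / den
    return {
        "ph": ph,
        "hplus": h * 1e9,
        "pco2": co2 / k["K0"] * 1e6,
        "co2aq": co2 * 1e6,
        "hco3": dic * k["K1"] * h / den * 1e6,
        "co3": co3 * 1e6,
        "omega_arag": k["Ca"] * co3 / k["KspA"],
        "omega_calc": k["Ca"] * co3 / k["KspC"],
    }
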