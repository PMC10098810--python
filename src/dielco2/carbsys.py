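"""Equilibrium seawater CO2-system solver.

Given temperature, salinity, dissolved inorganic carbon (DIC, ``C_T``) and
total alkalinity (``A_T``) — plus the minor phosphate and silicate bases —
this module solves the total-alkalinity balance for the hydrogen-ion
concentration on the total pH scale and derives pCO2, pH, carbonate
speciation and the calcite/aragonite saturation states.

Conventions follow the OMIP carbonate-chemistry protocol as implemented by
the mocsy/CO2SYS family: K1/K2 of Lueker et al. (2000, total scale), KB of
Dickson (1990), KW and phosphate/silicate constants of Millero (1995,
seawater scale, converted to total), KS of Dickson (1990, free scale), KF
of Perez & Fraga (1987), CO2 solubility of Weiss (1974), and solubility
products of Mucci (1983).  Everything is evaluated at surface pressure
(0 dbar) and concentrations are gravimetric (µmol kg⁻¹) end to end.

All functions are vectorized: scalar or broadcastable ndarray inputs are
accepted and results have the broadcast shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

__all__ = [
    "SeawaterState",
    "EquilibriumConstants",
    "CO2SystemResult",
    "CarbsysError",
    "ConvergenceError",
    "compute_constants",
    "solve_system",
    "equilibrate_to_atmosphere",
    "seawater_density",
]

# Valid surface-ocean ranges enforced on solver inputs.
TEMP_RANGE = (-2.0, 40.0)
SAL_RANGE = (0.0, 45.0)

# pH-solver bracket on [H+] (mol kg-1) and tolerances.
H_MIN, H_MAX = 1e-12, 1e-2
H_RTOL = 1e-8
MAX_ITER = 100


class CarbsysError(ValueError):
    """Invalid input to the CO2-system solver."""


class ConvergenceError(RuntimeError):
    """The alkalinity-balance root search failed to converge."""


def _asarray(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass
class SeawaterState:
    """One (or a vector of) surface seawater state(s).

    Parameters
    ----------
    temperature : °C, in [-2, 40]
    salinity : practical salinity, in [0, 45]
    dic : dissolved inorganic carbon C_T, µmol kg⁻¹, > 0
    alkalinity : total alkalinity A_T, µmol kg⁻¹, > 0
    phosphate, silicate : total dissolved inorganic P and Si, µmol kg⁻¹, ≥ 0
    """

    temperature: np.ndarray
    salinity: np.ndarray
    dic: np.ndarray
    alkalinity: np.ndarray
    phosphate: np.ndarray = field(default_factory=lambda: np.asarray(0.0))
    silicate: np.ndarray = field(default_factory=lambda: np.asarray(0.0))

    def __post_init__(self):
        for f in fields(self):
            setattr(self, f.name, _asarray(getattr(self, f.name)))
        self.validate()

    def validate(self) -> None:
        checks = [
            ("temperature", self.temperature, TEMP_RANGE),
            ("salinity", self.salinity, SAL_RANGE),
        ]
        for name, val, (lo, hi) in checks:
            if np.any(val < lo) or np.any(val > hi):
                raise CarbsysError(
                    f"{name} outside valid range [{lo}, {hi}]: "
                    f"min={np.min(val):.3f}, max={np.max(val):.3f}"
                )
        for name, val in [("dic", self.dic), ("alkalinity", self.alkalinity)]:
            if np.any(~(val > 0)):
                raise CarbsysError(f"{name} must be > 0")
        for name, val in [("phosphate", self.phosphate), ("silicate", self.silicate)]:
            if np.any(val < 0):
                raise CarbsysError(f"{name} must be >= 0")

    def replace(self, **kw) -> "SeawaterState":
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d.update(kw)
        return SeawaterState(**d)


@dataclass
class EquilibriumConstants:
    """Thermodynamic constants on the total pH scale at surface pressure.

    All dissociation constants are in mol kg⁻¹ (K0 in mol kg⁻¹ atm⁻¹,
    solubility products in mol² kg⁻²); totals in mol kg⁻¹.
    """

    k0: np.ndarray
    k1: np.ndarray
    k2: np.ndarray
    kb: np.ndarray
    kw: np.ndarray
    kp1: np.ndarray
    kp2: np.ndarray
    kp3: np.ndarray
    ksi: np.ndarray
    ks: np.ndarray  # bisulfate, free scale
    kf: np.ndarray  # hydrogen fluoride, free scale
    ksp_arag: np.ndarray
    ksp_calc: np.ndarray
    total_borate: np.ndarray
    total_sulfate: np.ndarray
    total_fluoride: np.ndarray
    total_calcium: np.ndarray


def compute_constants(state: SeawaterState) -> EquilibriumConstants:
    """Evaluate the full constants set at the state's T, S (total scale)."""
    t, s = state.temperature, state.salinity
    if np.any(t < TEMP_RANGE[0]) or np.any(t > TEMP_RANGE[1]):
        raise CarbsysError("temperature outside constant-fit validity [-2, 40] °C")
    if np.any(s < SAL_RANGE[0]) or np.any(s > SAL_RANGE[1]):
        raise CarbsysError("salinity outside constant-fit validity [0, 45]")

    tk = t + 273.15
    lnt = np.log(tk)
    sqs = np.sqrt(s)

    # salinity-proportional totals, mol kg-1
    tb = 0.000232 / 10.811 * s / 1.80655  # Uppström (1974)
    tso4 = 0.14 / 96.062 * s / 1.80655  # Morris & Riley (1966)
    tf = 0.000067 / 18.998 * s / 1.80655  # Riley (1965)
    tca = 0.02128 / 40.087 * s / 1.80655  # Riley & Tongudai (1967)

    ist = 19.924 * s / (1000.0 - 1.005 * s)  # ionic strength

    # bisulfate, Dickson (1990a), free scale
    lnks = (
        -4276.1 / tk + 141.328 - 23.093 * lnt
        + (-13856.0 / tk + 324.57 - 47.986 * lnt) * np.sqrt(ist)
        + (35474.0 / tk - 771.54 + 114.723 * lnt) * ist
        - 2698.0 / tk * ist**1.5
        + 1776.0 / tk * ist**2
        + np.log(1.0 - 0.001005 * s)
    )
    ks = np.exp(lnks)

    # hydrogen fluoride, Perez & Fraga (1987), total scale -> free scale
    kf_total = np.exp(874.0 / tk - 9.68 + 0.111 * sqs)
    free_to_tot = 1.0 + tso4 / ks
    kf = kf_total / free_to_tot

    # seawater scale -> total scale conversion factor
    sws_to_tot = free_to_tot / (free_to_tot + tf / kf)

    # CO2 solubility, Weiss (1974), mol kg-1 atm-1
    k0 = np.exp(
        -60.2409 + 93.4517 * (100.0 / tk) + 23.3585 * np.log(tk / 100.0)
        + s * (0.023517 - 0.023656 * (tk / 100.0) + 0.0047036 * (tk / 100.0) ** 2)
    )

    # carbonic acid, Lueker et al. (2000), total scale
    pk1 = 3633.86 / tk - 61.2172 + 9.67770 * lnt - 0.011555 * s + 0.0001152 * s**2
    pk2 = 471.78 / tk + 25.9290 - 3.16967 * lnt - 0.01781 * s + 0.0001122 * s**2
    k1 = 10.0 ** (-pk1)
    k2 = 10.0 ** (-pk2)

    # boric acid, Dickson (1990b), total scale
    lnkb = (
        (-8966.90 - 2890.53 * sqs - 77.942 * s + 1.728 * s**1.5 - 0.0996 * s**2) / tk
        + 148.0248 + 137.1942 * sqs + 1.62142 * s
        - (24.4344 + 25.085 * sqs + 0.2474 * s) * lnt
        + 0.053105 * sqs * tk
    )
    kb = np.exp(lnkb)

    # water, Millero (1995), seawater scale -> total
    lnkw = (
        148.9802 - 13847.26 / tk - 23.6521 * lnt
        + (118.67 / tk - 5.977 + 1.0495 * lnt) * sqs
        - 0.01615 * s
    )
    kw = np.exp(lnkw) * sws_to_tot

    # phosphoric acid, Millero (1995), seawater scale -> total
    lnkp1 = (
        -4576.752 / tk + 115.525 - 18.453 * lnt
        + (-106.736 / tk + 0.69171) * sqs
        + (-0.65643 / tk - 0.01844) * s
    )
    lnkp2 = (
        -8814.715 / tk + 172.0883 - 27.927 * lnt
        + (-160.340 / tk + 1.3566) * sqs
        + (0.37335 / tk - 0.05778) * s
    )
    lnkp3 = (
        -3070.75 / tk - 18.141
        + (17.27039 / tk + 2.81197) * sqs
        + (-44.99486 / tk - 0.09984) * s
    )
    kp1 = np.exp(lnkp1) * sws_to_tot
    kp2 = np.exp(lnkp2) * sws_to_tot
    kp3 = np.exp(lnkp3) * sws_to_tot

    # silicic acid, Millero (1995), seawater scale -> total
    lnksi = (
        -8904.2 / tk + 117.385 - 19.334 * lnt
        + (-458.79 / tk + 3.5913) * np.sqrt(ist)
        + (188.74 / tk - 1.5998) * ist
        + (-12.1652 / tk + 0.07871) * ist**2
        + np.log(1.0 - 0.001005 * s)
    )
    ksi = np.exp(lnksi) * sws_to_tot

    # CaCO3 solubility products, Mucci (1983)
    log10_kspc = (
        -171.9065 - 0.077993 * tk + 2839.319 / tk + 71.595 * np.log10(tk)
        + (-0.77712 + 0.0028426 * tk + 178.34 / tk) * sqs
        - 0.07711 * s + 0.0041249 * s**1.5
    )
    log10_kspa = (
        -171.945 - 0.077993 * tk + 2903.293 / tk + 71.595 * np.log10(tk)
        + (-0.068393 + 0.0017276 * tk + 88.135 / tk) * sqs
        - 0.10018 * s + 0.0059415 * s**1.5
    )

    return EquilibriumConstants(
        k0=k0, k1=k1, k2=k2, kb=kb, kw=kw,
        kp1=kp1, kp2=kp2, kp3=kp3, ksi=ksi, ks=ks, kf=kf,
        ksp_arag=10.0**log10_kspa, ksp_calc=10.0**log10_kspc,
        total_borate=tb, total_sulfate=tso4, total_fluoride=tf,
        total_calcium=tca,
    )


@dataclass
class CO2SystemResult:
    """Derived carbonate-system variables (total pH scale)."""

    pco2: np.ndarray  # µatm
    fco2: np.ndarray  # µatm
    hplus: np.ndarray  # nmol kg-1, total scale
    ph: np.ndarray  # total-scale pH
    omega_arag: np.ndarray
    omega_calc: np.ndarray
    co2aq: np.ndarray  # µmol kg-1 ([CO2*] = CO2(aq) + H2CO3)
    hco3: np.ndarray  # µmol kg-1
    co3: np.ndarray  # µmol kg-1


def _alkalinity_parts(h, dic, tp, tsi, c: EquilibriumConstants):
    """Total alkalinity (mol kg-1) and its dH derivative at total-scale [H+]."""
    k1, k2 = c.k1, c.k2
    den = h * (h + k1) + k1 * k2
    # carbonate alkalinity and derivative
    ac = dic * k1 * (h + 2.0 * k2) / den
    dac = dic * k1 * (den - (h + 2.0 * k2) * (2.0 * h + k1)) / den**2

    ab = c.total_borate * c.kb / (c.kb + h)
    dab = -c.total_borate * c.kb / (c.kb + h) ** 2

    aoh = c.kw / h
    daoh = -c.kw / h**2

    free_to_tot = 1.0 + c.total_sulfate / c.ks
    hfree = h / free_to_tot
    dhfree = 1.0 / free_to_tot

    hso4 = c.total_sulfate * hfree / (c.ks + hfree)
    dhso4 = c.total_sulfate * c.ks / (c.ks + hfree) ** 2 * dhfree

    hf = c.total_fluoride * hfree / (c.kf + hfree)
    dhf = c.total_fluoride * c.kf / (c.kf + hfree) ** 2 * dhfree

    # phosphate: contributes HPO4 + 2 PO4 - H3PO4 relative to the H2PO4 level
    kp1, kp2, kp3 = c.kp1, c.kp2, c.kp3
    d3 = h**3 + kp1 * h**2 + kp1 * kp2 * h + kp1 * kp2 * kp3
    num = kp1 * kp2 * h + 2.0 * kp1 * kp2 * kp3 - h**3
    ap = tp * num / d3
    dnum = kp1 * kp2 - 3.0 * h**2
    dd3 = 3.0 * h**2 + 2.0 * kp1 * h + kp1 * kp2
    dap = tp * (dnum * d3 - num * dd3) / d3**2

    asi = tsi * c.ksi / (c.ksi + h)
    dasi = -tsi * c.ksi / (c.ksi + h) ** 2

    alk = ac + ab + aoh + ap + asi - hfree - hso4 - hf
    dalk = dac + dab + daoh + dap + dasi - dhfree - dhso4 - dhf
    return alk, dalk


def _solve_h(dic, alk, tp, tsi, c: EquilibriumConstants, h_init=None):
    """Vectorized safeguarded Newton for total-scale [H+] (mol kg-1).

    Newton steps in ln[H+] with per-element bisection fallback on the
    bracket [1e-12, 1e-2]; raises ConvergenceError if the bracket does not
    contain a root or the iteration stalls.
    """
    shape = np.broadcast_shapes(
        np.shape(dic), np.shape(alk), np.shape(tp), np.shape(tsi),
        np.shape(c.k1),
    )
    dic, alk, tp, tsi = (np.broadcast_to(_asarray(v), shape).copy()
                         for v in (dic, alk, tp, tsi))

    f_lo, _ = _alkalinity_parts(np.full(shape, H_MIN), dic, tp, tsi, c)
    f_hi, _ = _alkalinity_parts(np.full(shape, H_MAX), dic, tp, tsi, c)
    # alkalinity decreases monotonically with H: root requires f(lo) >= alk >= f(hi)
    bad = (f_lo - alk < 0) | (f_hi - alk > 0)
    if np.any(bad):
        i = np.argwhere(bad)[0]
        raise ConvergenceError(
            "no [H+] root in bracket [1e-12, 1e-2] mol kg-1 at index "
            f"{tuple(i)}: alk={alk[tuple(i)]:.6e} outside attainable "
            f"[{f_hi[tuple(i)]:.6e}, {f_lo[tuple(i)]:.6e}] mol kg-1"
        )

    if h_init is None:
        h = np.full(shape, 10.0**-8.0)
    else:
        h = np.clip(np.broadcast_to(_asarray(h_init), shape).copy(), H_MIN, H_MAX)
    lo = np.full(shape, H_MIN)
    hi = np.full(shape, H_MAX)

    converged = np.zeros(shape, dtype=bool)
    for _ in range(MAX_ITER):
        f, df = _alkalinity_parts(h, dic, tp, tsi, c)
        resid = f - alk
        # maintain the bracket (alkalinity is decreasing in H)
        lo = np.where(resid > 0, np.maximum(lo, h), lo)
        hi = np.where(resid < 0, np.minimum(hi, h), hi)

        step = -resid / (df * h)  # Newton step in ln H
        step = np.clip(step, -1.0, 1.0)
        h_new = h * np.exp(step)
        # fall back to bisection when Newton leaves the bracket
        outside = (h_new <= lo) | (h_new >= hi)
        h_new = np.where(outside, np.sqrt(lo * hi), h_new)

        newly = np.abs(h_new - h) <= H_RTOL * h
        h = np.where(converged, h, h_new)
        converged |= newly
        if np.all(converged):
            break
    else:
        n_bad = int(np.sum(~converged))
        raise ConvergenceError(
            f"pH solver did not converge for {n_bad} element(s) after "
            f"{MAX_ITER} iterations (rtol={H_RTOL})"
        )
    return h


def solve_system(state: SeawaterState, h_init=None,
                 constants: EquilibriumConstants | None = None) -> CO2SystemResult:
    """Solve the CO2 system for a state (vectorized).

    ``h_init`` (mol kg-1) warm-starts the Newton iteration, e.g. with the
    previous time step's root.  ``constants`` may be supplied to reuse a
    precomputed set (they must match the state's T and S).
    """
    c = constants if constants is not None else compute_constants(state)
    dic = state.dic * 1e-6
    alk = state.alkalinity * 1e-6
    tp = state.phosphate * 1e-6
    tsi = state.silicate * 1e-6

    h = _solve_h(dic, alk, tp, tsi, c, h_init=h_init)

    den = h * (h + c.k1) + c.k1 * c.k2
    co2aq = dic * h**2 / den
    hco3 = dic * c.k1 * h / den
    co3 = dic * c.k1 * c.k2 / den

    pco2 = co2aq / c.k0 * 1e6  # µatm
    fco2 = pco2 * fugacity_factor(state.temperature)
    omega_c = c.total_calcium * co3 / c.ksp_calc
    omega_a = c.total_calcium * co3 / c.ksp_arag

    return CO2SystemResult(
        pco2=pco2, fco2=fco2,
        hplus=h * 1e9, ph=-np.log10(h),
        omega_arag=omega_a, omega_calc=omega_c,
        co2aq=co2aq * 1e6, hco3=hco3 * 1e6, co3=co3 * 1e6,
    )


def fugacity_factor(temperature):
    """fCO2/pCO2 ratio from the CO2 virial equation of state (Weiss 1974).

    Reported results default to pCO2; apply this factor only when fugacity
    is explicitly wanted.
    """
    tk = _asarray(temperature) + 273.15
    rt = 82.05736 * tk  # cm3 atm mol-1
    b = -1636.75 + 12.0408 * tk - 3.27957e-2 * tk**2 + 3.16528e-5 * tk**3
    delta = 57.7 - 0.118 * tk
    return np.exp((b + 2.0 * delta) / rt)


def equilibrate_to_atmosphere(template: SeawaterState, xco2,
                              tol: float = 0.01, max_iter: int = 60) -> SeawaterState:
    """Adjust DIC so the solved pCO2 equals the atmospheric mixing ratio.

    ``xco2`` is in ppm (treated as the target seawater pCO2 in µatm, i.e.
    zero air-sea disequilibrium at 1 atm total pressure).  All other state
    fields are kept.  Newton iteration on DIC with a finite-difference
    slope; converges to |pCO2 - xco2| < ``tol`` µatm.
    """
    xco2 = _asarray(xco2)
    if np.any(xco2 < 100.0) or np.any(xco2 > 2500.0):
        raise CarbsysError("xco2 outside supported range [100, 2500] ppm")

    c = compute_constants(template)
    shape = np.broadcast_shapes(np.shape(template.dic), np.shape(xco2),
                                np.shape(c.k1))
    dic = np.broadcast_to(template.dic, shape).astype(float).copy()
    state = template.replace(dic=dic)

    h = None
    for _ in range(max_iter):
        res = solve_system(state, h_init=h, constants=c)
        h = res.hplus * 1e-9
        err = res.pco2 - xco2
        if np.all(np.abs(err) < tol):
            return state
        ddic = 1.0  # µmol kg-1 probe for the local slope
        res2 = solve_system(state.replace(dic=state.dic + ddic), h_init=h,
                            constants=c)
        slope = (res2.pco2 - res.pco2) / ddic
        new_dic = state.dic - err / slope
        if np.any(~(new_dic > 0)):
            raise ConvergenceError(
                "equilibration drove DIC non-positive; target pCO2 unreachable"
            )
        state = state.replace(dic=new_dic)
    raise ConvergenceError(
        f"equilibrate_to_atmosphere did not reach |dpCO2| < {tol} µatm "
        f"in {max_iter} iterations"
    )


def seawater_density(temperature, salinity):
    """Surface seawater density (kg m-3), Millero & Poisson (1981) at 0 dbar."""
    t = _asarray(temperature)
    s = _asarray(salinity)
    rho_w = (
        999.842594 + 6.793952e-2 * t - 9.095290e-3 * t**2
        + 1.001685e-4 * t**3 - 1.120083e-6 * t**4 + 6.536332e-9 * t**5
    )
    a = (
        0.824493 - 4.0899e-3 * t + 7.6438e-5 * t**2
        - 8.2467e-7 * t**3 + 5.3875e-9 * t**4
    )
    b = -5.72466e-3 + 1.0227e-4 * t - 1.6546e-6 * t**2
    return rho_w + a * s + b * s**1.5 + 4.8314e-4 * s**2
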