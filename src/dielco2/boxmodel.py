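"""0-D mixed-layer carbon simulator at 3-h cadence.

A well-mixed surface box of fixed depth carries DIC and alkalinity.  At
each 3-h step, temperature is prescribed from the forcing (there is no heat
budget: the diurnal SST cycle is an input, which isolates the carbonate
chemistry response), DIC is updated by air-sea CO2 exchange — gas transfer
velocity quadratic in the 10-m wind speed with Schmidt-number correction —
and by a light-driven net-community-production (NCP) term that draws DIC
down in daylight and respires it back at a constant rate.  Salinity and
(absent calcification) alkalinity are constant within a day.

Carbon is conserved exactly: over any run the change in the column carbon
inventory equals the time-integrated air-sea flux plus the biological
source/sink.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .amplitudes import SLOTS_PER_DAY
from .carbsys import (
    EquilibriumConstants,
    SeawaterState,
    compute_constants,
    seawater_density,
    solve_system,
)

__all__ = [
    "BoxState",
    "ForcingSeries",
    "NCPParams",
    "SimOutput",
    "schmidt_number",
    "gas_transfer_velocity",
    "airsea_flux",
    "ncp_tendencies",
    "step",
    "run",
]

DT_SECONDS = 3.0 * 3600.0

#: Wanninkhof (2014) quadratic coefficient, cm h-1 (m s-1)-2, converted to SI
K_QUADRATIC = 0.251 * 0.01 / 3600.0


@dataclass
class BoxState:
    """A mixed-layer box: seawater state plus depth and density."""

    state: SeawaterState
    depth: float = 30.0  # m
    density: np.ndarray = None  # kg m-3, derived from T, S if omitted

    def __post_init__(self):
        if np.any(~(np.asarray(self.depth, float) > 0)):
            raise ValueError("mixed-layer depth must be > 0")
        if self.density is None:
            self.density = seawater_density(
                self.state.temperature, self.state.salinity
            )
        self.density = np.asarray(self.density, float)
        if np.any(self.density < 1015) or np.any(self.density > 1030):
            raise ValueError("density outside plausible surface range")


@dataclass
class ForcingSeries:
    """3-h forcing for one or many boxes; time is the trailing axis.

    Fields broadcast against each other; ``xco2`` is the atmospheric CO2
    mixing ratio (ppm), ``sst`` the prescribed sea surface temperature
    (°C), ``u10`` the 10-m wind speed (m s-1), ``par`` a [0, 1]
    photosynthetically-active-radiation proxy (zero at night) and ``ice``
    an optional sea-ice fraction scaling the gas exchange.
    """

    xco2: np.ndarray
    sst: np.ndarray
    u10: np.ndarray
    par: np.ndarray
    ice: np.ndarray = None

    def __post_init__(self):
        self.sst = np.atleast_2d(np.asarray(self.sst, float))
        n = self.sst.shape[-1]
        if n == 0:
            raise ValueError("forcing series is empty")
        if n % SLOTS_PER_DAY:
            raise ValueError("forcing length must be a whole number of days")
        self.xco2 = np.broadcast_to(np.asarray(self.xco2, float), self.sst.shape)
        self.u10 = np.broadcast_to(np.asarray(self.u10, float), self.sst.shape)
        self.par = np.broadcast_to(np.asarray(self.par, float), self.sst.shape)
        if self.ice is None:
            self.ice = np.zeros_like(self.sst)
        self.ice = np.broadcast_to(np.asarray(self.ice, float), self.sst.shape)
        if np.any(self.u10 < 0):
            raise ValueError("wind speed must be >= 0")
        if np.any((self.par < 0) | (self.par > 1)):
            raise ValueError("par proxy must lie in [0, 1]")

    @property
    def n_slots(self) -> int:
        return self.sst.shape[-1]


@dataclass
class NCPParams:
    """Net-community-production parameterization.

    ``gross_daily`` is the daylight DIC drawdown (µmol kg-1 day-1)
    distributed over slots in proportion to PAR; a constant community
    respiration returns ``gross_daily - net_daily`` per day, so the daily
    DIC integral equals ``-net_daily`` by construction.  ``calc_frac``
    routes a fraction of production into CaCO3, removing alkalinity and
    DIC at 2:1.
    """

    gross_daily: np.ndarray = 0.0
    net_daily: np.ndarray = 0.0
    calc_frac: float = 0.0

    def __post_init__(self):
        self.gross_daily = np.asarray(self.gross_daily, float)
        self.net_daily = np.asarray(self.net_daily, float)
        if np.any(self.gross_daily < 0) or self.calc_frac < 0:
            raise ValueError("NCP parameters must be >= 0")
        if np.any(self.gross_daily - self.net_daily < 0):
            raise ValueError("gross production must not be below net NCP")


def schmidt_number(temperature) -> np.ndarray:
    """Schmidt number of CO2 in seawater (Wanninkhof 2014 polynomial)."""
    t = np.asarray(temperature, float)
    if np.any(t < -2.0) or np.any(t > 40.0):
        raise ValueError("temperature outside Schmidt polynomial validity")
    return (2116.8 - 136.25 * t + 4.7353 * t**2
            - 0.092307 * t**3 + 0.0007555 * t**4)


def gas_transfer_velocity(u10, temperature) -> np.ndarray:
    """Piston velocity k (m s-1): 0.251 u10² (Sc/660)^-1/2, u10 in m s-1."""
    u = np.asarray(u10, float)
    if np.any(u < 0):
        raise ValueError("wind speed must be >= 0")
    sc = schmidt_number(temperature)
    return K_QUADRATIC * u**2 * np.sqrt(660.0 / sc)


def airsea_flux(k, k0, density, pco2_atm, pco2_ocean, ice=0.0) -> np.ndarray:
    """Air-sea CO2 flux, mol C m-2 s-1, positive into the ocean.

    F = k K0 ρ (pCO2_atm - pCO2_ocean), scaled by the open-water fraction
    (1 - ice).  K0 in mol kg-1 atm-1 and ρ in kg m-3 put the solubility on
    a volumetric basis; pCO2 in µatm.
    """
    dp = (np.asarray(pco2_atm, float) - np.asarray(pco2_ocean, float)) * 1e-6
    return k * k0 * density * dp * (1.0 - np.asarray(ice, float))


def ncp_tendencies(par: np.ndarray, ncp: NCPParams):
    """Per-slot DIC and alkalinity tendencies (µmol kg-1 per 3 h).

    ``par`` has shape (..., n_slots) with n_slots a whole number of days.
    Production in a slot is gross_daily · par / (daily PAR sum); respiration
    is uniform over the day.
    """
    shape = par.shape
    days = shape[-1] // SLOTS_PER_DAY
    p = par.reshape(shape[:-1] + (days, SLOTS_PER_DAY))
    psum = p.sum(-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(psum > 0, p / psum, 0.0)
    gross = np.asarray(ncp.gross_daily, float)[..., None, None]
    net = np.asarray(ncp.net_daily, float)[..., None, None]
    production = gross * frac
    respiration = (gross - net) / SLOTS_PER_DAY
    calcif = ncp.calc_frac * production
    ddic = (-production + respiration - calcif).reshape(shape)
    dalk = (-2.0 * calcif).reshape(shape)
    return ddic, dalk


def step(box: BoxState, xco2, sst, u10, par_ddic=0.0, par_dalk=0.0,
         ice=0.0, dt: float = DT_SECONDS, h_init=None):
    """Advance one 3-h step; returns (new BoxState, CO2SystemResult, flux).

    The returned diagnostics are valid at the *start* of the step (after
    setting T to the forcing SST); the new state carries the updated DIC
    and alkalinity.
    """
    state = box.state.replace(temperature=np.asarray(sst, float))
    cons = compute_constants(state)
    res = solve_system(state, h_init=h_init, constants=cons)

    rho = seawater_density(state.temperature, state.salinity)
    k = gas_transfer_velocity(u10, state.temperature)
    flux = airsea_flux(k, cons.k0, rho, xco2, res.pco2, ice=ice)

    # mol m-2 s-1 -> µmol kg-1 per step
    ddic_flux = flux * dt / (box.depth * rho) * 1e6
    new_state = state.replace(
        dic=state.dic + ddic_flux + par_ddic,
        alkalinity=state.alkalinity + par_dalk,
    )
    return BoxState(new_state, depth=box.depth, density=rho), res, flux


@dataclass
class SimOutput:
    """3-h output series of a run; arrays are (..., n_slots)."""

    sst: np.ndarray
    dic: np.ndarray
    alkalinity: np.ndarray
    pco2: np.ndarray
    hplus: np.ndarray
    ph: np.ndarray
    omega_arag: np.ndarray
    flux: np.ndarray  # mol C m-2 s-1, positive into the ocean
    carbon_closure: np.ndarray = field(default=None)


def run(initial: BoxState, forcing: ForcingSeries,
        ncp: NCPParams | None = None, dt: float = DT_SECONDS) -> SimOutput:
    """Integrate the box over the forcing series (vectorized over boxes).

    Deterministic given its inputs; emits every 3-h slot.  Any solver
    failure aborts with the offending slot index.
    """
    if forcing.n_slots == 0:
        raise ValueError("forcing series is empty")
    ncp = ncp or NCPParams()
    ddic_bio, dalk_bio = ncp_tendencies(forcing.par, ncp)

    n = forcing.n_slots
    shape = np.broadcast_shapes(forcing.sst.shape[:-1],
                                np.shape(initial.state.dic))
    out = {k: np.empty(shape + (n,)) for k in
           ("sst", "dic", "alkalinity", "pco2", "hplus", "ph",
            "omega_arag", "flux")}

    box = BoxState(
        initial.state.replace(
            dic=np.broadcast_to(initial.state.dic, shape).copy(),
            alkalinity=np.broadcast_to(initial.state.alkalinity, shape).copy(),
        ),
        depth=initial.depth,
    )
    h = None
    bio_int = np.zeros(shape)
    flux_int = np.zeros(shape)
    dic0 = box.state.dic.copy()
    for i in range(n):
        try:
            new_box, res, flux = step(
                box, forcing.xco2[..., i], forcing.sst[..., i],
                forcing.u10[..., i],
                par_ddic=ddic_bio[..., i], par_dalk=dalk_bio[..., i],
                ice=forcing.ice[..., i], dt=dt, h_init=h,
            )
        except Exception as e:
            raise RuntimeError(f"box-model step failed at slot {i}: {e}") from e
        h = res.hplus * 1e-9
        out["sst"][..., i] = forcing.sst[..., i]
        out["dic"][..., i] = box.state.dic  # start-of-step value, as solved
        out["alkalinity"][..., i] = box.state.alkalinity
        out["pco2"][..., i] = res.pco2
        out["hplus"][..., i] = res.hplus
        out["ph"][..., i] = res.ph
        out["omega_arag"][..., i] = res.omega_arag
        out["flux"][..., i] = flux
        flux_int += flux * dt / (box.depth * new_box.density) * 1e6
        bio_int += ddic_bio[..., i]
        box = new_box

    closure = (box.state.dic - dic0) - (flux_int + bio_int)
    return SimOutput(carbon_closure=closure, **out)
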