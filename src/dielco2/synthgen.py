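"""Synthetic surface-ocean generator.

Replaces a gridded ocean model with a latitude-resolved ensemble of
mixed-layer cells carrying everything the diurnal CO2-system analysis
needs: mean-state meridional gradients (temperature, salinity, alkalinity,
nutrients), seasonal SST cycles, stochastic diurnal SST cycles peaking at
15:00 local solar time with heavy-tailed day-to-day amplitude variability,
log-normal AR(1) winds, a solar-geometry PAR proxy, and scenario
backgrounds in which DIC is equilibrated to the prescribed atmospheric CO2
trajectory.

Day-to-day diurnal SST amplitudes are drawn as ``mean_amplitude x g`` with
``g`` log-normal (mean one) and AR(1)-correlated through a Gaussian
copula.  The log-normal family reproduces the large extreme-to-mean
amplitude ratios of global-model diurnal statistics (99th and 99.9th
percentile amplitudes roughly 5 and 9 times the mean); its sigma and the
meridional amplitude profile are the shipped default calibration and are
identical across scenarios, so scenario responses are emergent.

All randomness derives from one integer seed; each (scenario, year) pair
gets an independent substream, so results do not depend on how years are
chunked into batches.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import lfilter

from .boxmodel import ForcingSeries, NCPParams
from .carbsys import SeawaterState, equilibrate_to_atmosphere
from .amplitudes import DAYS_PER_YEAR, SLOTS_PER_DAY

__all__ = [
    "GeneratorConfig",
    "Grid",
    "CellSpec",
    "SCENARIOS",
    "load_default_config",
    "build_grid",
    "xco2_trajectory",
    "generate_forcing",
    "background_state",
    "ncp_params",
    "DIURNAL_SHAPE",
]

#: zero-mean, unit peak-to-peak diurnal shape at slots 00:00 ... 21:00
#: local solar time; maximum at 15:00, minimum at 06:00.
DIURNAL_SHAPE = np.array(
    [-0.26, -0.36, -0.42, -0.10, 0.35, 0.58, 0.28, -0.07]
)

#: scenario -> (first year, last year, [(year, xCO2 ppm) anchors])
SCENARIOS = {
    "picontrol": (1850, 2100, [(1850, 284.0), (2100, 284.0)]),
    "historical": (1850, 2014, [(1850, 284.0), (2014, 398.0)]),
    "ssp126": (2015, 2100, [(2015, 398.0), (2063.5, 474.0), (2100, 446.0)]),
    "ssp585": (2015, 2100, [(2015, 398.0), (2100, 1135.0)]),
}
_SCENARIO_ID = {name: i for i, name in enumerate(SCENARIOS)}


class GeneratorConfig(dict):
    """Nested dict of generator parameters (TOML section -> key -> value)."""

    def section(self, name: str) -> dict:
        return self[name]


def load_default_config() -> GeneratorConfig:
    """The shipped default calibration."""
    text = (resources.files("dielco2") / "data" / "default_calibration.toml")
    with text.open("rb") as fh:
        return GeneratorConfig(tomllib.load(fh))


def load_config(path) -> GeneratorConfig:
    with open(path, "rb") as fh:
        return GeneratorConfig(tomllib.load(fh))


@dataclass
class CellSpec:
    """Parameters of one synthetic cell."""

    latitude: float
    weight: float
    t_mean: float
    t_seasonal_half: float
    salinity: float
    alkalinity: float
    phosphate: float
    silicate: float
    sst_diurnal_mean: float  # mean daily peak-to-peak amplitude, degC
    lognormal_sigma: float
    ar1_daily: float
    ncp_gross: float  # µmol kg-1 day-1
    ncp_net: float
    mixed_layer_depth: float
    wind_median: float


@dataclass
class Grid:
    """Array-of-cells container; indexable to a :class:`CellSpec`."""

    latitude: np.ndarray
    weight: np.ndarray
    t_mean: np.ndarray
    t_seasonal_half: np.ndarray
    salinity: np.ndarray
    alkalinity: np.ndarray
    phosphate: np.ndarray
    silicate: np.ndarray
    sst_diurnal_mean: np.ndarray
    lognormal_sigma: float
    ar1_daily: float
    ncp_gross: np.ndarray
    ncp_net: np.ndarray
    mixed_layer_depth: float
    wind_median: np.ndarray

    def __len__(self) -> int:
        return self.latitude.size

    def __getitem__(self, i: int) -> CellSpec:
        return CellSpec(
            latitude=float(self.latitude[i]),
            weight=float(self.weight[i]),
            t_mean=float(self.t_mean[i]),
            t_seasonal_half=float(self.t_seasonal_half[i]),
            salinity=float(self.salinity[i]),
            alkalinity=float(self.alkalinity[i]),
            phosphate=float(self.phosphate[i]),
            silicate=float(self.silicate[i]),
            sst_diurnal_mean=float(self.sst_diurnal_mean[i]),
            lognormal_sigma=self.lognormal_sigma,
            ar1_daily=self.ar1_daily,
            ncp_gross=float(self.ncp_gross[i]),
            ncp_net=float(self.ncp_net[i]),
            mixed_layer_depth=self.mixed_layer_depth,
            wind_median=float(self.wind_median[i]),
        )


def build_grid(n_cells: int, seed: int,
               config: GeneratorConfig | None = None) -> Grid:
    """Deterministic latitude-resolved cell ensemble.

    Latitudes are mid-points uniformly spaced between the configured
    bounds; cell area weights are proportional to cos(latitude) and
    normalized to sum to one.  A seeded multiplicative jitter perturbs the
    diurnal-amplitude and NCP profiles so cells at the same latitude band
    are not identical.
    """
    if n_cells < 10:
        raise ValueError("need at least 10 cells for meaningful statistics")
    cfg = config or load_default_config()
    g, ms, sd, ncp, wind = (cfg["grid"], cfg["mean_state"],
                            cfg["sst_diurnal"], cfg["ncp"], cfg["wind"])

    edges = np.linspace(g["lat_min"], g["lat_max"], n_cells + 1)
    lat = 0.5 * (edges[:-1] + edges[1:])
    rad = np.deg2rad(lat)
    w = np.cos(rad)
    w = w / w.sum()

    cos2 = np.cos(rad) ** 2
    sin2 = np.sin(rad) ** 2
    t_mean = ms["t_polar"] + (ms["t_equator"] - ms["t_polar"]) * cos2
    seas = (ms["seas_half_base"]
            + ms["seas_half_midlat"] * np.sin(2 * rad) ** 2
            + ms["seas_half_polar"] * sin2)
    sal = (ms["s_background"] + ms["s_gyre_bump"]
           * np.exp(-((np.abs(lat) - ms["s_gyre_lat"]) / ms["s_gyre_width"]) ** 2))
    alk = ms["alk_at_s35"] + ms["alk_per_s"] * (sal - 35.0)
    po4 = ms["po4_equator"] + (ms["po4_polar"] - ms["po4_equator"]) * sin2**2
    si = ms["si_equator"] + (ms["si_polar"] - ms["si_equator"]) * sin2**2

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC311]))
    jit = g["cell_jitter_sigma"]
    amp_jit = np.exp(rng.normal(0.0, jit, n_cells) - jit**2 / 2)
    ncp_jit = np.exp(rng.normal(0.0, jit, n_cells) - jit**2 / 2)
    wind_jit = np.exp(rng.normal(0.0, 0.05, n_cells))

    amp = (sd["amp_polar"] + (sd["amp_equator"] - sd["amp_polar"]) * cos2) * amp_jit
    gross = (ncp["gross_polar"]
             + (ncp["gross_equator"] - ncp["gross_polar"]) * cos2) * ncp_jit

    return Grid(
        latitude=lat, weight=w, t_mean=t_mean, t_seasonal_half=seas,
        salinity=sal, alkalinity=alk, phosphate=po4, silicate=si,
        sst_diurnal_mean=amp,
        lognormal_sigma=sd["lognormal_sigma"], ar1_daily=sd["ar1_daily"],
        ncp_gross=gross, ncp_net=np.full(n_cells, float(ncp["net_daily"])),
        mixed_layer_depth=float(cfg["mixed_layer"]["depth"]),
        wind_median=wind["median"] * wind_jit,
    )


def xco2_trajectory(scenario: str, year) -> np.ndarray:
    """Atmospheric CO2 mixing ratio (ppm) from the scenario anchor points.

    Monotone-cubic (PCHIP) interpolation through the anchors; exact at the
    anchors.  Years outside the scenario span raise.
    """
    if scenario not in SCENARIOS:
        raise KeyError(f"unknown scenario {scenario!r}; "
                       f"choose from {sorted(SCENARIOS)}")
    y0, y1, anchors = SCENARIOS[scenario]
    year = np.asarray(year, dtype=float)
    if np.any(year < y0) or np.any(year > y1):
        raise ValueError(f"year outside {scenario} span [{y0}, {y1}]")
    xs, ys = zip(*anchors)
    if len(xs) == 2:
        out = np.interp(year, xs, ys)
    else:
        out = PchipInterpolator(xs, ys)(year)
    return out if out.shape else float(out)


def _solar_par(lat_deg: np.ndarray, doy: np.ndarray, slot: np.ndarray):
    """Cosine-of-zenith PAR proxy in [0, 1]; zero at night.

    ``lat_deg``, ``doy`` (0-based day of a 365-day year) and ``slot``
    (0..7) broadcast together; slot centres are at local solar hours
    1.5, 4.5, ..., 22.5 shifted so slot k spans [3k, 3k+3).
    """
    lat = np.deg2rad(lat_deg)
    dec = np.deg2rad(-23.44) * np.cos(2 * np.pi * (doy + 10.5) / DAYS_PER_YEAR)
    hour = slot * 3.0 + 1.5
    ha = np.deg2rad(15.0 * (hour - 12.0))
    cosz = np.sin(lat) * np.sin(dec) + np.cos(lat) * np.cos(dec) * np.cos(ha)
    return np.clip(cosz, 0.0, 1.0)


def _year_rng(seed: int, scenario: str, year: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _SCENARIO_ID[scenario], int(year)])
    )


def generate_forcing(grid: Grid, scenario: str, years, seed: int,
                     config: GeneratorConfig | None = None) -> ForcingSeries:
    """3-h forcing for every (year, cell) box; shape (n_years*n_cells, slots).

    Box ordering is year-major: box ``y * n_cells + c`` is cell ``c`` in
    ``years[y]``.  Bit-reproducible for a given (grid, scenario, years,
    seed, config); each year draws from an independent substream.
    """
    cfg = config or load_default_config()
    sd, wind = cfg["sst_diurnal"], cfg["wind"]
    years = [int(y) for y in np.atleast_1d(years)]
    nc = len(grid)
    nslots = DAYS_PER_YEAR * SLOTS_PER_DAY

    doy = np.arange(DAYS_PER_YEAR)
    slot = np.arange(SLOTS_PER_DAY)
    # seasonal SST peaks in late summer of each hemisphere
    peak = np.where(grid.latitude >= 0, 227.0, 45.0)
    seasonal = (grid.t_mean[:, None] + grid.t_seasonal_half[:, None]
                * np.cos(2 * np.pi * (doy[None, :] - peak[:, None])
                         / DAYS_PER_YEAR))
    par_cell = _solar_par(grid.latitude[:, None, None],
                          doy[None, :, None], slot[None, None, :])
    par_cell = par_cell.reshape(nc, nslots)

    sigma, rho_d = grid.lognormal_sigma, grid.ar1_daily
    rho_w, sig_w = wind["ar1_slot"], wind["sigma"]

    sst_all, u10_all, par_all, xco2_all = [], [], [], []
    for year in years:
        rng = _year_rng(seed, scenario, year)
        # day-to-day amplitude factors: AR(1) Gaussian -> lognormal, mean 1
        eps = rng.standard_normal((nc, DAYS_PER_YEAR))
        z = lfilter([np.sqrt(1 - rho_d**2)], [1.0, -rho_d], eps, axis=1)
        z[:, 0] = eps[:, 0]  # stationary start
        g_fac = np.exp(sigma * z - sigma**2 / 2)
        amp = grid.sst_diurnal_mean[:, None] * g_fac  # (nc, days)

        sst = (seasonal[:, :, None]
               + amp[:, :, None] * DIURNAL_SHAPE[None, None, :])
        sst = np.maximum(sst.reshape(nc, nslots), sd["sst_floor"])

        epsw = rng.standard_normal((nc, nslots))
        zw = lfilter([np.sqrt(1 - rho_w**2)], [1.0, -rho_w], epsw, axis=1)
        zw[:, 0] = epsw[:, 0]
        u10 = grid.wind_median[:, None] * np.exp(sig_w * zw)

        xco2 = np.full((nc, nslots), float(xco2_trajectory(scenario, year)))

        sst_all.append(sst)
        u10_all.append(u10)
        par_all.append(par_cell)
        xco2_all.append(xco2)

    return ForcingSeries(
        xco2=np.concatenate(xco2_all),
        sst=np.concatenate(sst_all),
        u10=np.concatenate(u10_all),
        par=np.concatenate(par_all),
    )


def background_state(grid: Grid, scenario: str, year,
                     config: GeneratorConfig | None = None) -> SeawaterState:
    """Scenario background: DIC equilibrated to the atmospheric trajectory.

    The template uses each cell's annual-mean temperature; a configurable
    fixed air-sea disequilibrium offset (default 0 µatm) is added to the
    atmospheric value before equilibration.
    """
    cfg = config or load_default_config()
    diseq = float(cfg["chemistry"]["disequilibrium"])
    xco2 = np.asarray(xco2_trajectory(scenario, year), dtype=float)
    template = SeawaterState(
        temperature=grid.t_mean,
        salinity=grid.salinity,
        dic=0.85 * grid.alkalinity,
        alkalinity=grid.alkalinity,
        phosphate=grid.phosphate,
        silicate=grid.silicate,
    )
    return equilibrate_to_atmosphere(template, xco2 + diseq)


def ncp_params(grid: Grid, config: GeneratorConfig | None = None) -> NCPParams:
    """Box-model NCP parameters for every cell of the grid."""
    cfg = config or load_default_config()
    return NCPParams(
        gross_daily=grid.ncp_gross,
        net_daily=grid.ncp_net,
        calc_frac=float(cfg["ncp"]["calc_frac"]),
    )
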