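"""End-to-end scenario experiment.

Reproduces the analysis chain at desk scale: a preindustrial baseline run
characterizes natural diurnal variability; historical and SSP windows are
then run with the diurnal forcing statistics frozen at the preindustrial
calibration while only the background DIC (equilibrated to the scenario
atmospheric CO2 trajectory) changes.  From the 3-h CO2-system output the
pipeline computes peak-to-peak diurnal and seasonal amplitudes, fixed-
baseline extreme thresholds and probability ratios, the thermal/nonthermal
Taylor decomposition of the mean diurnal pCO2 cycle, and area-weighted
monthly probability densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import extremes as ext
from .amplitudes import (
    DAYS_PER_YEAR,
    SLOTS_PER_DAY,
    MONTH_LENGTHS,
    diurnal_amplitude,
    global_mean,
    month_of_day,
    percent_change,
    seasonal_amplitude,
)
from .boxmodel import BoxState, NCPParams, run
from .carbsys import SeawaterState
from .drivers import MeanDiurnalCycle, Decomposition, decompose, diurnal_anomaly_maxima
from .synthgen import (
    GeneratorConfig,
    Grid,
    background_state,
    build_grid,
    generate_forcing,
    load_default_config,
    ncp_params,
)

__all__ = ["ExperimentConfig", "WindowResult", "ExperimentResult",
           "run_experiment", "run_window", "summary_report"]

#: variables tracked through the amplitude/extreme statistics
VARIABLES = ("pco2", "hplus", "ph", "omega_arag", "sst")

#: (scenario, first year, last year) of the standard analysis windows
DEFAULT_WINDOWS = {
    "pi_baseline": ("picontrol", 1850, 1899),
    "hist_late": ("historical", 1995, 2014),
    "ssp126_end": ("ssp126", 2081, 2100),
    "ssp585_end": ("ssp585", 2081, 2100),
}

#: years of the preindustrial window standing in for 1850-1869 conditions
EARLY_WINDOW_YEARS = 20


@dataclass
class ExperimentConfig:
    """Desk-scale experiment design.

    The preindustrial baseline is ``pi_years`` long; scenario windows are
    taken from :data:`DEFAULT_WINDOWS` (each 20 years).  ``year_block``
    bounds how many simulated years are held in memory at once and has no
    effect on results.
    """

    n_cells: int = 200
    seed: int = 12345
    pi_years: int = 50
    windows: dict = field(default_factory=lambda: dict(DEFAULT_WINDOWS))
    year_block: int = 10
    generator: GeneratorConfig | None = None
    decompose_windows: tuple = ("hist_late", "ssp585_end")

    def __post_init__(self):
        if self.generator is None:
            self.generator = load_default_config()
        y0 = self.windows["pi_baseline"][1]
        self.windows["pi_baseline"] = ("picontrol", y0, y0 + self.pi_years - 1)


@dataclass
class WindowResult:
    """Reductions of one simulated window."""

    name: str
    scenario: str
    years: tuple
    daily_amp: dict  # var -> (n_cells, n_days) float32
    seasonal_amp: dict  # var -> (n_cells, n_years)
    mean_cycle: MeanDiurnalCycle | None  # mean diurnal input fields per cell
    mean_pco2_cycle: np.ndarray | None  # (n_cells, 8) mean 3-h pCO2
    monthly: dict  # var -> (n_cells*n_years, 12) monthly means
    mean_field: dict  # var -> (n_cells,) window-mean value
    carbon_closure: float  # worst |closure| µmol kg-1 across boxes

    def mean_diurnal_amplitude(self, var: str) -> np.ndarray:
        return self.daily_amp[var].mean(axis=1)


def _reduce_block(outarr: np.ndarray, nc: int, ny: int):
    """(B, slots) -> per-day (B, days, 8) view."""
    return outarr.reshape(ny * nc, DAYS_PER_YEAR, SLOTS_PER_DAY)


def run_window(grid: Grid, name: str, scenario: str, y0: int, y1: int,
               seed: int, gen_cfg: GeneratorConfig,
               year_block: int = 10, want_cycle: bool = False) -> WindowResult:
    """Simulate one window and reduce it to amplitude/cycle statistics.

    Years are chunked into blocks of at most ``year_block``; chunking does
    not affect results because every (scenario, year) has its own random
    substream and background.
    """
    nc = len(grid)
    years = list(range(y0, y1 + 1))
    ncp_cell = ncp_params(grid, gen_cfg)

    daily = {v: [] for v in VARIABLES}
    monthly = {v: [] for v in VARIABLES}
    slot_sums = {v: np.zeros((nc, SLOTS_PER_DAY))
                 for v in ("sst", "sal", "dic", "alk", "pco2")}
    mean_sums = {v: np.zeros(nc) for v in VARIABLES}
    n_days_total = 0
    worst_closure = 0.0
    month_idx = month_of_day(np.arange(DAYS_PER_YEAR))

    for i in range(0, len(years), year_block):
        block = years[i:i + year_block]
        ny = len(block)
        forcing = generate_forcing(grid, scenario, block, seed, gen_cfg)
        bg = background_state(grid, scenario,
                              np.asarray(block, float)[:, None], gen_cfg)
        dic0 = np.asarray(bg.dic).reshape(ny * nc)

        tile = lambda a: np.tile(np.asarray(a, float), ny)
        init = BoxState(
            SeawaterState(
                temperature=forcing.sst[:, 0],
                salinity=tile(grid.salinity),
                dic=dic0,
                alkalinity=tile(grid.alkalinity),
                phosphate=tile(grid.phosphate),
                silicate=tile(grid.silicate),
            ),
            depth=grid.mixed_layer_depth,
        )
        ncp = NCPParams(gross_daily=tile(ncp_cell.gross_daily),
                        net_daily=tile(ncp_cell.net_daily),
                        calc_frac=ncp_cell.calc_frac)
        out = run(init, forcing, ncp)
        worst_closure = max(worst_closure,
                            float(np.max(np.abs(out.carbon_closure))))

        fields = {"pco2": out.pco2, "hplus": out.hplus, "ph": out.ph,
                  "omega_arag": out.omega_arag, "sst": out.sst}
        for v, arr in fields.items():
            byday = _reduce_block(arr, nc, ny)
            amp = diurnal_amplitude(byday, axis=-1)  # (B, days)
            daily[v].append(
                amp.reshape(ny, nc, DAYS_PER_YEAR)
                .transpose(1, 0, 2).reshape(nc, -1).astype(np.float32)
            )
            daymean = byday.mean(-1)  # (B, days)
            msum = np.zeros((ny * nc, 12))
            for m in range(12):
                msum[:, m] = daymean[:, month_idx == m].mean(-1)
            monthly[v].append(msum)
            mean_sums[v] += byday.mean((-1, -2)).reshape(ny, nc).sum(0)

        cyc_fields = {"sst": out.sst, "dic": out.dic, "alk": out.alkalinity,
                      "pco2": out.pco2}
        for v, arr in cyc_fields.items():
            slots = _reduce_block(arr, nc, ny).sum(1)  # (B, 8)
            slot_sums[v] += slots.reshape(ny, nc, SLOTS_PER_DAY).sum(0)
        slot_sums["sal"] += grid.salinity[:, None] * (ny * DAYS_PER_YEAR)
        n_days_total += ny * DAYS_PER_YEAR

    daily = {v: np.concatenate(a, axis=1) for v, a in daily.items()}
    monthly = {v: np.concatenate(a, axis=0) for v, a in monthly.items()}
    seasonal = {v: seasonal_amplitude(m, axis=-1)
                .reshape(-1, nc).T for v, m in monthly.items()}
    mean_field = {v: s / len(years) for v, s in mean_sums.items()}

    cycle = pco2_cycle = None
    if want_cycle:
        per_slot = {v: s / n_days_total for v, s in slot_sums.items()}
        cycle = MeanDiurnalCycle(
            temperature=per_slot["sst"],
            salinity=per_slot["sal"],
            dic=per_slot["dic"],
            alkalinity=per_slot["alk"],
            phosphate=np.repeat(grid.phosphate[:, None], SLOTS_PER_DAY, 1),
            silicate=np.repeat(grid.silicate[:, None], SLOTS_PER_DAY, 1),
        )
        pco2_cycle = per_slot["pco2"]

    return WindowResult(
        name=name, scenario=scenario, years=(y0, y1),
        daily_amp=daily, seasonal_amp=seasonal,
        mean_cycle=cycle, mean_pco2_cycle=pco2_cycle,
        monthly=monthly, mean_field=mean_field,
        carbon_closure=worst_closure,
    )


@dataclass
class ExperimentResult:
    """Everything the summary tables are built from."""

    config: ExperimentConfig
    grid: Grid
    windows: dict  # name -> WindowResult
    thresholds: dict  # (var, percentile) -> (n_cells,)
    pr: dict  # (window, var, percentile) -> per-cell Pr
    decompositions: dict  # window -> Decomposition

    def early_window_amp(self, var: str) -> np.ndarray:
        """Per-cell mean diurnal amplitude of the 1850-1869 analogue.

        The first 20 years of the preindustrial baseline stand in for the
        1850-1869 early-historical window (atmospheric CO2 is within a few
        ppm of the preindustrial 284 ppm there).
        """
        nd = EARLY_WINDOW_YEARS * DAYS_PER_YEAR
        return self.windows["pi_baseline"].daily_amp[var][:, :nd].mean(1)

    def global_amp(self, window: str, var: str) -> float:
        w = self.grid.weight
        if window == "early":
            return float(global_mean(self.early_window_amp(var), w))
        return float(global_mean(
            self.windows[window].mean_diurnal_amplitude(var), w))


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the full chain; deterministic for a given config."""
    grid = build_grid(config.n_cells, config.seed, config.generator)
    windows = {}
    for name, (scenario, y0, y1) in config.windows.items():
        windows[name] = run_window(
            grid, name, scenario, y0, y1, config.seed, config.generator,
            year_block=config.year_block,
            want_cycle=name in config.decompose_windows,
        )

    base = windows["pi_baseline"]
    thresholds, pr = {}, {}
    for var in VARIABLES:
        for p, pc in ((99.0, 0.01), (99.9, 0.001)):
            thr = ext.percentile_threshold(base.daily_amp[var], p, axis=1)
            thresholds[(var, p)] = thr
            for name, res in windows.items():
                if name == "pi_baseline":
                    continue
                pi = ext.exceedance_probability(res.daily_amp[var], thr, axis=1)
                pr[(name, var, p)] = ext.probability_ratio(pi, pc)

    decompositions = {}
    for name in config.decompose_windows:
        if name in windows and windows[name].mean_cycle is not None:
            decompositions[name] = decompose(windows[name].mean_cycle)

    return ExperimentResult(config=config, grid=grid, windows=windows,
                            thresholds=thresholds, pr=pr,
                            decompositions=decompositions)


def _density_summary(res: ExperimentResult, var: str) -> pd.DataFrame:
    """Area-weighted mean ± SD of binned monthly output per window."""
    rows = []
    for name, wr in res.windows.items():
        m = wr.monthly[var]  # (n_boxes, 12)
        w = np.repeat(np.tile(res.grid.weight, m.shape[0] // len(res.grid)),
                      12)
        vals = m.reshape(-1)
        mean = np.average(vals, weights=w)
        sd = np.sqrt(np.average((vals - mean) ** 2, weights=w))
        rows.append({"window": name, "variable": var,
                     "mean": mean, "sd": sd})
    return pd.DataFrame(rows)


def summary_report(res: ExperimentResult):
    """Headline tables: amplitudes, % changes, Pr, decomposition, densities.

    Returns a dict of DataFrames plus a plain-text summary; raises if a
    required stage is missing from the bundle.
    """
    missing = [k for k in ("pi_baseline",) if k not in res.windows]
    if missing:
        raise ValueError(f"incomplete bundle; missing stages: {missing}")

    w = res.grid.weight
    amp_rows = []
    for var in VARIABLES:
        base = res.global_amp("early", var)
        for name in res.windows:
            val = res.global_amp(name, var)
            amp_rows.append({
                "variable": var, "window": name,
                "diurnal_amplitude": val,
                "change_vs_early": val - base,
                "pct_change_vs_early": percent_change(base, val),
                "seasonal_amplitude": float(global_mean(
                    res.windows[name].seasonal_amp[var].mean(1), w)),
            })
    amp_table = pd.DataFrame(amp_rows)

    pr_rows = []
    for (name, var, p), prs in res.pr.items():
        gm = ext.global_mean_pr(prs, w)
        baseline_days = int(round(100 if p == 99.0 else 1000))
        pr_rows.append({
            "window": name, "variable": var, "percentile": p,
            "global_mean_pr": gm,
            "return_period_days": int(ext.return_period(gm, baseline_days)),
            "baseline_threshold_mean": float(global_mean(
                res.thresholds[(var, p)], w)),
        })
    pr_table = pd.DataFrame(pr_rows)

    dec_rows = []
    for name, dec in res.decompositions.items():
        mx, th, nt = diurnal_anomaly_maxima(dec)
        dec_rows.append({
            "window": name,
            "median_residual_pct": 100 * float(np.nanmedian(
                dec.residual_fraction)),
            "mean_anomaly_max": float(global_mean(mx, w)),
            "mean_thermal_at_max": float(global_mean(th, w)),
            "mean_nonthermal_at_max": float(global_mean(nt, w)),
        })
    dec_table = pd.DataFrame(dec_rows)

    dens_table = pd.concat([_density_summary(res, v) for v in VARIABLES],
                           ignore_index=True)

    lines = ["Diurnal CO2-system variability: experiment summary",
             f"cells={res.config.n_cells} seed={res.config.seed} "
             f"pi_years={res.config.pi_years}", ""]
    for var in VARIABLES:
        sub = amp_table[amp_table.variable == var]
        lines.append(f"[{var}] global mean diurnal amplitude")
        for _, r in sub.iterrows():
            lines.append(
                f"  {r.window:<12} {r.diurnal_amplitude:10.4g}  "
                f"change {r.change_vs_early:+.4g} "
                f"({r.pct_change_vs_early:+.1f}%)"
            )
    lines.append("")
    for _, r in pr_table.iterrows():
        lines.append(
            f"Pr[{r.variable} q{r.percentile}] {r.window:<12} "
            f"= {r.global_mean_pr:6.2f}  (1 in {r.return_period_days} days)"
        )
    lines.append("")
    for _, r in dec_table.iterrows():
        lines.append(
            f"decomposition {r.window}: median residual "
            f"{r.median_residual_pct:.3f}% of peak-to-peak; anomaly max "
            f"{r.mean_anomaly_max:+.3f} = thermal {r.mean_thermal_at_max:+.3f} "
            f"+ nonthermal {r.mean_nonthermal_at_max:+.3f} µatm"
        )

    return {
        "amplitudes": amp_table,
        "probability_ratios": pr_table,
        "decomposition": dec_table,
        "densities": dens_table,
        "text": "\n".join(lines),
    }
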