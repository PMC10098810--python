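"""Tabular and netCDF I/O for states, forcing and 3-h output series.

CSV tables are tidy (one row per cell/time sample) with CF-style variable
names (``temperature``, ``salinity``, ``dic``, ``talk``, ``po4``,
``sio3``).  netCDF files are written through xarray's scipy backend
(netCDF3 classic), which keeps the package free of compiled netCDF
dependencies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from .boxmodel import ForcingSeries, SimOutput
from .carbsys import CO2SystemResult, SeawaterState, solve_system

__all__ = [
    "states_from_frame",
    "frame_from_states",
    "solve_table",
    "read_states_csv",
    "write_results_csv",
    "forcing_to_dataset",
    "forcing_from_dataset",
    "simoutput_to_dataset",
]

STATE_COLUMNS = {
    "temperature": "temperature",
    "salinity": "salinity",
    "dic": "dic",
    "talk": "alkalinity",
    "po4": "phosphate",
    "sio3": "silicate",
}
RESULT_COLUMNS = ("pco2", "hplus", "ph", "omega_arag", "omega_calc",
                  "co2aq", "hco3", "co3")


def states_from_frame(df: pd.DataFrame) -> SeawaterState:
    """Columnar table -> vector state; optional nutrient columns default 0."""
    kw = {}
    for col, fld in STATE_COLUMNS.items():
        if col in df.columns:
            kw[fld] = df[col].to_numpy(float)
        elif fld in ("phosphate", "silicate"):
            kw[fld] = np.zeros(len(df))
        else:
            raise KeyError(f"missing required column {col!r}")
    return SeawaterState(**kw)


def frame_from_states(state: SeawaterState,
                      result: CO2SystemResult | None = None) -> pd.DataFrame:
    df = pd.DataFrame({col: np.atleast_1d(getattr(state, fld))
                       for col, fld in STATE_COLUMNS.items()})
    if result is not None:
        for name in RESULT_COLUMNS:
            df[name] = np.atleast_1d(getattr(result, name))
    return df


def solve_table(df: pd.DataFrame) -> pd.DataFrame:
    """Offline CO2-system computation on a columnar table of states."""
    state = states_from_frame(df)
    return frame_from_states(state, solve_system(state))


def read_states_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_results_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def forcing_to_dataset(forcing: ForcingSeries) -> xr.Dataset:
    dims = ("cell", "time")
    return xr.Dataset(
        {name: (dims, getattr(forcing, name))
         for name in ("xco2", "sst", "u10", "par", "ice")},
        attrs={"cadence_hours": 3},
    )


def forcing_from_dataset(ds: xr.Dataset) -> ForcingSeries:
    return ForcingSeries(
        xco2=ds["xco2"].values, sst=ds["sst"].values,
        u10=ds["u10"].values, par=ds["par"].values,
        ice=ds["ice"].values if "ice" in ds else None,
    )


def simoutput_to_dataset(out: SimOutput) -> xr.Dataset:
    dims = ("cell", "time")
    data = {name: (dims, np.atleast_2d(getattr(out, name)))
            for name in ("sst", "dic", "alkalinity", "pco2", "hplus",
                         "ph", "omega_arag", "flux")}
    return xr.Dataset(data, attrs={"cadence_hours": 3})


def write_netcdf(ds: xr.Dataset, path) -> None:
    """Write netCDF3 via the scipy backend (no libnetcdf dependency)."""
    ds.to_netcdf(path, engine="scipy")


def read_netcdf(path) -> xr.Dataset:
    return xr.open_dataset(path, engine="scipy")
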