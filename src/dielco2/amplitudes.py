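"""Peak-to-peak amplitude metrics and area-weighted aggregation.

The diurnal amplitude of a variable is the difference between its maximum
and minimum 3-hourly values within one 24-h local solar day (8 slots); the
seasonal amplitude is the difference between the maximum and minimum
monthly means within one year.  Global statistics are area-weighted means
over cells, with weights proportional to the cosine of latitude.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "diurnal_amplitude",
    "seasonal_amplitude",
    "global_mean",
    "percent_change",
    "SLOTS_PER_DAY",
    "MONTH_LENGTHS",
]

SLOTS_PER_DAY = 8  # 3-h cadence
#: 365-day no-leap calendar
MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
DAYS_PER_YEAR = int(MONTH_LENGTHS.sum())


def diurnal_amplitude(day_values, axis: int = -1) -> np.ndarray:
    """max - min over the 8 3-h slots of each day.

    ``day_values`` must have exactly 8 finite values along ``axis``; missing
    slots are an error rather than being imputed.
    """
    v = np.asarray(day_values, dtype=float)
    if v.shape[axis] != SLOTS_PER_DAY:
        raise ValueError(
            f"expected {SLOTS_PER_DAY} 3-h slots per day, got {v.shape[axis]}"
        )
    if not np.all(np.isfinite(v)):
        raise ValueError("missing/non-finite 3-h slot in daily series")
    return v.max(axis=axis) - v.min(axis=axis)


def seasonal_amplitude(monthly_means, axis: int = -1) -> np.ndarray:
    """max - min over the 12 monthly means of each year."""
    v = np.asarray(monthly_means, dtype=float)
    if v.shape[axis] != 12:
        raise ValueError(f"expected 12 monthly means per year, got {v.shape[axis]}")
    if not np.all(np.isfinite(v)):
        raise ValueError("missing/non-finite monthly mean")
    return v.max(axis=axis) - v.min(axis=axis)


def global_mean(values, weights, axis: int = -1) -> np.ndarray:
    """Area-weighted mean: sum(w_i v_i) / sum(w_i)."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("empty input to global_mean")
    if w.ndim and v.shape[axis] != w.shape[0]:
        raise ValueError("values and weights length mismatch")
    if np.any(~(w > 0)):
        raise ValueError("weights must be > 0")
    return np.sum(v * w, axis=axis) / np.sum(w)


def percent_change(baseline, value) -> np.ndarray:
    """100 * (value - baseline) / baseline."""
    b = np.asarray(baseline, dtype=float)
    if np.any(b == 0):
        raise ValueError("percent_change undefined for zero baseline")
    return 100.0 * (np.asarray(value, dtype=float) - b) / b


def month_of_day(day_of_year) -> np.ndarray:
    """0-based month index for 0-based day-of-year (365-day calendar)."""
    edges = np.concatenate([[0], np.cumsum(MONTH_LENGTHS)])
    return np.searchsorted(edges, np.asarray(day_of_year) + 1, side="left") - 1
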