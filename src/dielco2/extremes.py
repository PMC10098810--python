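"""Fixed-baseline extreme-event statistics for diurnal amplitudes.

Extremes are defined locally against a fixed baseline period: per cell, the
99th and 99.9th percentiles of daily diurnal amplitudes over the baseline
give thresholds, and later periods are characterized by the probability
ratio Pr = Pi/Pc — the exceedance probability in the evaluation period
divided by that in the baseline (0.01 and 0.001 by construction).  A Pr of
10 means a formerly 1-in-100-day amplitude occurs 10 times as often.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "percentile_threshold",
    "exceedance_probability",
    "probability_ratio",
    "return_period",
    "global_mean_pr",
]


def percentile_threshold(amplitudes, p, axis: int = -1) -> np.ndarray:
    """Order-statistic percentile with linear interpolation.

    Warns when fewer than 1000 baseline days are supplied for p >= 99.9,
    where the empirical quantile is poorly constrained.
    """
    a = np.asarray(amplitudes, dtype=float)
    if a.size == 0:
        raise ValueError("empty amplitude sample")
    n = a.shape[axis]
    if p >= 99.9 and n < 1000:
        warnings.warn(
            f"only {n} baseline days for the {p}th percentile; "
            "threshold is poorly sampled",
            stacklevel=2,
        )
    return np.percentile(a, p, axis=axis, method="linear")


def exceedance_probability(amplitudes, threshold, axis: int = -1) -> np.ndarray:
    """Fraction of days strictly exceeding the threshold."""
    a = np.asarray(amplitudes, dtype=float)
    thr = np.asarray(threshold, dtype=float)
    if np.any(~np.isfinite(thr)):
        raise ValueError("threshold must be finite")
    if a.ndim > 1 and thr.ndim:
        thr = np.expand_dims(thr, axis)
    return np.mean(a > thr, axis=axis)


def probability_ratio(pi, pc) -> np.ndarray:
    """Pr = Pi/Pc; baseline probability zero yields inf with a warning."""
    pi = np.asarray(pi, dtype=float)
    pc = np.asarray(pc, dtype=float)
    if np.any(pc == 0):
        warnings.warn(
            "zero baseline exceedance probability: Pr flagged as inf",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        pr = np.where(pc > 0, pi / pc, np.where(pi > 0, np.inf, np.nan))
    return pr


def return_period(pr, baseline_days) -> np.ndarray:
    """Convert Pr into a return period in whole days.

    A baseline 1-in-``baseline_days`` event with probability ratio ``pr``
    recurs roughly every baseline_days/pr days.
    """
    pr = np.asarray(pr, dtype=float)
    if np.any(~(pr > 0)):
        raise ValueError("return period undefined for Pr <= 0")
    return np.round(np.asarray(baseline_days, dtype=float) / pr).astype(int)


def global_mean_pr(pr, weights) -> float:
    """Area-weighted mean of per-cell Pr, excluding non-finite cells.

    Cells with infinite or undefined Pr (zero baseline probability) are
    excluded from the aggregation; the number excluded is reported via a
    warning so it is never silent.
    """
    pr = np.asarray(pr, dtype=float)
    w = np.asarray(weights, dtype=float)
    ok = np.isfinite(pr)
    n_bad = int(np.sum(~ok))
    if n_bad:
        warnings.warn(
            f"excluding {n_bad} cell(s) with non-finite Pr from global mean",
            stacklevel=2,
        )
    if not np.any(ok):
        raise ValueError("no cells with finite Pr")
    return float(np.sum(pr[ok] * w[ok]) / np.sum(w[ok]))
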