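"""Growth phenotypes from optical-density series and dry-cell-weight data.

The maximum specific growth rate is the steepest log-linear stretch of an
OD time course: a window of fixed time span slides over the series one
sample at a time, a least-squares line is fitted to ln(OD) vs. time in
each window, and the largest slope wins. Natural log is used throughout,
so the slope is the specific growth rate mu in 1/h directly.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_T_EPS = 1e-9


@dataclass
class GrowthRateResult:
    """Maximum specific growth rate and the sliding-window scan behind it."""

    mu_max: float  # 1/h
    window_start: float  # h, start time of the winning window
    windows: pd.DataFrame  # columns t_start, t_end, n_points, slope


def max_growth_rate(time_h, od, window_h: float = 5.0) -> GrowthRateResult:
    """Maximum slope of ln(OD) over sliding windows of ``window_h`` hours.

    Windows are defined by time span, not point count (missing samples are
    tolerated): window i covers samples with t in [t_i, t_i + window_h]
    and windows advance one sample at a time. Requires strictly
    increasing times, strictly positive OD, and a series spanning at
    least one full window.
    """
    t = np.asarray(time_h, dtype=float)
    y = np.asarray(od, dtype=float)
    if t.ndim != 1 or t.shape != y.shape or len(t) < 2:
        raise ValueError("time and OD must be 1-D arrays of equal length >= 2")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")
    if np.any(y <= 0):
        raise ValueError("OD values must be > 0 (log undefined)")
    if window_h <= 0:
        raise ValueError("window_h must be > 0")
    if t[-1] - t[0] + _T_EPS < window_h:
        raise ValueError(f"series spans {t[-1] - t[0]:.3f} h < window of {window_h} h")

    ln_od = np.log(y)
    rows = []
    for i in range(len(t)):
        if t[i] + window_h > t[-1] + _T_EPS:
            break
        j = int(np.searchsorted(t, t[i] + window_h + _T_EPS, side="right"))
        tt, yy = t[i:j], ln_od[i:j]
        if len(tt) < 2:
            continue
        slope = np.polyfit(tt, yy, 1)[0]
        rows.append((t[i], tt[-1], len(tt), slope))
    windows = pd.DataFrame(rows, columns=["t_start", "t_end", "n_points", "slope"])
    best = windows["slope"].idxmax()
    return GrowthRateResult(
        mu_max=float(windows.loc[best, "slope"]),
        window_start=float(windows.loc[best, "t_start"]),
        windows=windows,
    )


def biomass_yield(dcw_mg: float, substrate_g_per_l: float, volume_l: float) -> float:
    """Biomass yield in gDCW per g substrate.

    yield = DCW (mg) / (substrate (g/L) * volume (L) * 1000).
    """
    if dcw_mg <= 0 or substrate_g_per_l <= 0 or volume_l <= 0:
        raise ValueError("dry cell weight, substrate concentration and volume must all be > 0")
    return dcw_mg / (substrate_g_per_l * volume_l * 1000.0)
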