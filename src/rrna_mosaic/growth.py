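"""Doubling-time estimation from OD600 growth curves.

The doubling time is ln 2 divided by the exponential growth rate, obtained by
least squares on (time, ln OD) within a fitting window. The automatic window
is the contiguous subsequence of >= 4 points with positive slope that
maximizes R-squared (ties: the longer, then the earlier window), so a clean
exponential is fitted over its full extent while lag and stationary phases
are excluded on real curves.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GrowthSeries:
    """An OD600 time series for one strain/condition."""

    times: tuple[float, ...]  # hours, strictly increasing
    od: tuple[float, ...]  # OD600 > 0
    label: str = ""

    def __post_init__(self):
        if len(self.times) != len(self.od) or len(self.times) < 3:
            raise ValueError("need >= 3 paired (time, OD) points")
        t = np.asarray(self.times)
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not all(v > 0 for v in self.od):
            raise ValueError("OD values must be positive")


@dataclass(frozen=True)
class DoublingTimeFit:
    """Doubling time in hours plus the diagnostics of the log-linear fit."""

    doubling_time_h: float  # nan if no growth
    slope: float  # per hour, on ln OD
    r_squared: float
    window: tuple[int, int]  # index range [i, j) of the fitted points
    no_growth: bool = False


def _fit(t: np.ndarray, ln_od: np.ndarray) -> tuple[float, float]:
    res = stats.linregress(t, ln_od)
    r2 = 0.0 if np.isnan(res.rvalue) else res.rvalue**2
    return res.slope, r2


def doubling_time(
    series: GrowthSeries, window: str | tuple[int, int] = "auto"
) -> DoublingTimeFit:
    """Fit ln OD ~ time and return ln2/slope.

    window
        ``auto``: best contiguous window of >= 4 points (see module
        docstring); or an explicit ``(i, j)`` half-open index range with >= 3
        points. A non-positive slope (no growth within the window, cf. curves
        where no growth was observed) yields ``no_growth=True`` and a NaN
        doubling time.
    """
    t = np.asarray(series.times, dtype=float)
    ln_od = np.log(np.asarray(series.od, dtype=float))
    n = len(t)

    if window == "auto":
        best = None
        min_len = min(4, n)
        for i in range(n):
            for j in range(i + min_len, n + 1):
                slope, r2 = _fit(t[i:j], ln_od[i:j])
                if slope <= 0:
                    continue
                key = (round(r2, 12), j - i, -i)
                if best is None or key > best[0]:
                    best = (key, slope, r2, (i, j))
        if best is None:
            return DoublingTimeFit(float("nan"), 0.0, 0.0, (0, n), no_growth=True)
        _, slope, r2, win = best
    else:
        i, j = window
        if j - i < 3:
            raise ValueError("explicit window needs >= 3 points")
        slope, r2 = _fit(t[i:j], ln_od[i:j])
        win = (i, j)
        if slope <= 0:
            return DoublingTimeFit(float("nan"), slope, r2, win, no_growth=True)
    return DoublingTimeFit(np.log(2.0) / slope, slope, r2, win)


def read_growth_tsv(path: str | os.PathLike) -> list[GrowthSeries]:
    """Read TSV columns time_h, od600[, label] into one series per label."""
    df = pd.read_csv(path, sep="\t")
    for col in ("time_h", "od600"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if "label" not in df.columns:
        df["label"] = ""
    out = []
    for label, grp in df.groupby("label", sort=False):
        grp = grp.sort_values("time_h")
        out.append(
            GrowthSeries(
                times=tuple(grp["time_h"]), od=tuple(grp["od600"]), label=str(label)
            )
        )
    return out
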