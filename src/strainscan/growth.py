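"""Growth-rate estimation from optical-density time series.

The specific growth rate is the slope of ln(OD) against time over the curve's
log-linear (exponential) portion; doubling time is ln(2) divided by that
slope.  The linear portion is found by scanning contiguous windows for the
longest stretch that is well fit by a line with positive slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError, FitError


@dataclass(frozen=True)
class GrowthCurve:
    """An OD time series for one strain in one condition."""

    time: np.ndarray  # hours, strictly increasing
    od: np.ndarray  # optical density, > 0
    strain_id: str = ""
    condition: str = ""

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        od = np.asarray(self.od, dtype=float)
        if t.ndim != 1 or t.shape != od.shape:
            raise DataError("time and od must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise DataError("time must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "od", od)


@dataclass(frozen=True)
class GrowthFit:
    """Result of a log-linear growth fit."""

    growth_rate: float  # 1/h, natural-log slope
    doubling_time: float  # h, ln(2)/growth_rate
    window: tuple[int, int]  # inclusive [start_index, end_index]
    r_squared: float
    low_confidence: bool = False
    strain_id: str = ""
    condition: str = ""


def _window_stats(y: np.ndarray, t: np.ndarray, w_min: int):
    """Slope and R^2 for every contiguous window, via prefix sums.

    Yields ``(length, slopes, r2, starts)`` for each window length from the
    full series down to ``w_min``.  Zero-variance windows get R^2 = 0.
    """
    n = y.size
    c = np.concatenate
    St = c([[0.0], np.cumsum(t)])
    Sy = c([[0.0], np.cumsum(y)])
    Stt = c([[0.0], np.cumsum(t * t)])
    Sty = c([[0.0], np.cumsum(t * y)])
    Syy = c([[0.0], np.cumsum(y * y)])
    for length in range(n, w_min - 1, -1):
        i = np.arange(0, n - length + 1)
        j = i + length
        st = St[j] - St[i]
        sy = Sy[j] - Sy[i]
        stt = Stt[j] - Stt[i]
        sty = Sty[j] - Sty[i]
        syy = Syy[j] - Syy[i]
        sxx = stt - st * st / length
        sxy = sty - st * sy / length
        syy_c = syy - sy * sy / length
        slopes = sxy / sxx
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(syy_c > 0, (sxy * sxy) / (sxx * syy_c), 0.0)
        yield length, slopes, r2, i


def detect_linear_window(
    log_od: np.ndarray,
    time: np.ndarray,
    w_min: int = 5,
    r2_min: float = 0.999,
) -> tuple[int, int, bool]:
    """Locate the log-linear portion of a growth curve.

    Among contiguous windows of at least ``w_min`` points with least-squares
    R^2 >= ``r2_min`` and positive slope, returns the longest (ties broken by
    higher R^2, then earlier start) as an inclusive ``(start, end)`` index
    pair.  If no window qualifies, returns the ``w_min``-point window with the
    highest R^2 and a ``low_confidence`` flag.
    """
    y = np.asarray(log_od, dtype=float)
    t = np.asarray(time, dtype=float)
    if y.size < w_min:
        raise DataError(f"series has {y.size} points; need at least w_min={w_min}")
    fallback = None
    for length, slopes, r2, starts in _window_stats(y, t, w_min):
        ok = (slopes > 0) & (r2 >= r2_min)
        if ok.any():
            k = np.argmax(np.where(ok, r2, -np.inf))
            return int(starts[k]), int(starts[k] + length - 1), False
        if length == w_min:
            k = int(np.argmax(r2))
            fallback = (int(starts[k]), int(starts[k] + length - 1), True)
    assert fallback is not None
    return fallback


def fit_growth_rate(
    curve: GrowthCurve, w_min: int = 5, r2_min: float = 0.999, blank: float = 0.0
) -> GrowthFit:
    """Estimate the exponential growth rate of one curve.

    Fits ln(OD) vs time by least squares over the detected log-linear window.
    ``blank`` is an optional constant subtracted from OD before the log
    transform (no blank subtraction by default).
    """
    od = curve.od - blank
    if np.any(od <= 0):
        raise DataError("OD values must be > 0 (after blank subtraction)")
    y = np.log(od)
    start, end, low_conf = detect_linear_window(y, curve.time, w_min, r2_min)
    seg = slice(start, end + 1)
    res = stats.linregress(curve.time[seg], y[seg])
    if res.slope <= 0:
        raise FitError(
            f"non-positive fitted slope ({res.slope:.4g}) for strain "
            f"{curve.strain_id or '?'}; curve has no exponential growth phase"
        )
    return GrowthFit(
        growth_rate=float(res.slope),
        doubling_time=float(np.log(2) / res.slope),
        window=(start, end),
        r_squared=float(res.rvalue**2),
        low_confidence=low_conf,
        strain_id=curve.strain_id,
        condition=curve.condition,
    )


def fit_growth_table(
    curves: pd.DataFrame, w_min: int = 5, r2_min: float = 0.999, blank: float = 0.0
) -> pd.DataFrame:
    """Fit every (strain, condition) series of a long-form curve table.

    Expects columns ``strain_id, condition, time_h, od``; returns one row per
    series with the fit, its window and a low-confidence flag.
    """
    required = {"strain_id", "condition", "time_h", "od"}
    if not required.issubset(curves.columns):
        raise DataError(f"curve table needs columns {sorted(required)}")
    rows = []
    for (strain, condition), chunk in curves.groupby(
        ["strain_id", "condition"], sort=True
    ):
        chunk = chunk.sort_values("time_h")
        fit = fit_growth_rate(
            GrowthCurve(
                time=chunk["time_h"].to_numpy(),
                od=chunk["od"].to_numpy(),
                strain_id=str(strain),
                condition=str(condition),
            ),
            w_min=w_min,
            r2_min=r2_min,
            blank=blank,
        )
        rows.append(
            {
                "strain_id": strain,
                "condition": condition,
                "growth_rate": fit.growth_rate,
                "doubling_time": fit.doubling_time,
                "r_squared": fit.r_squared,
                "window_start": fit.window[0],
                "window_end": fit.window[1],
                "low_confidence": fit.low_confidence,
            }
        )
    return pd.DataFrame(rows)


def cohort_dispersion(rates) -> float:
    """Inter-strain dispersion of growth rates: sample std (n-1) over mean."""
    r = np.asarray(rates, dtype=float)
    if r.size < 2:
        raise DataError("dispersion needs at least 2 strains")
    mean = r.mean()
    if mean == 0:
        raise DataError("zero mean growth rate; dispersion undefined")
    return float(r.std(ddof=1) / mean)
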