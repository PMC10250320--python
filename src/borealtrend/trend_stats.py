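"""Robust per-series trend estimation.

Annual tree-cover (or climate) series are summarised by Theil-Sen slopes with
Yue-Pilon pre-whitening, accompanied by the Mann-Kendall trend test.  The
pre-whitening step removes lag-1 autocorrelation from the detrended residuals
before the final slope/test, which de-biases the trend test under serial
correlation while leaving a genuine linear trend untouched.

All estimators accept plain arrays; :func:`trend_table` is the vectorised
entry point for a long-format plot x year table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnnualSeries",
    "TrendEstimate",
    "sen_slope",
    "mann_kendall",
    "lag1_autocorrelation",
    "yue_pilon_prewhiten",
    "estimate_trend",
    "relative_change",
    "trend_table",
]

#: |r1| below which pre-whitening is skipped (avoids needless length loss).
R1_THRESHOLD = 0.05
#: mean cover (percent) below which relative change is flagged undefined.
RELATIVE_CHANGE_GUARD = 1.0
#: minimum number of present years (out of the nominal 20) for a trend.
MIN_YEARS = 15


@dataclass(frozen=True)
class AnnualSeries:
    """One plot's (or pixel's) annual values on a calendar-year axis.

    Missing entries are explicit NaNs in ``values``; ``years`` must be unique
    and strictly increasing.  Values are tree cover in percent for the cover
    product, but any real-valued annual quantity (deg C, mm) is accepted.
    """

    years: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        years = np.asarray(self.years, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if years.ndim != 1 or years.shape != values.shape:
            raise ValueError("years and values must be 1-D and equally long")
        if years.size and np.any(np.diff(years) <= 0):
            raise ValueError("years must be unique and strictly increasing")
        if np.any(np.isinf(values)):
            raise ValueError("values must be finite where present")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)

    def dropna(self) -> "AnnualSeries":
        keep = np.isfinite(self.values)
        return AnnualSeries(self.years[keep], self.values[keep])

    @property
    def n_present(self) -> int:
        return int(np.isfinite(self.values).sum())


@dataclass
class TrendEstimate:
    """Sen slope plus Mann-Kendall statistics for one annual series."""

    slope_abs: float  # percent per year
    slope_rel: float  # per year; NaN when flagged undefined
    mean_value: float  # percent
    mk_S: int
    mk_Z: float
    p_value: float
    lag1: float
    n_used: int
    valid: bool = True
    rel_defined: bool = True
    notes: str = ""

    @classmethod
    def missing(cls, note: str = "too few years") -> "TrendEstimate":
        return cls(np.nan, np.nan, np.nan, 0, np.nan, np.nan, np.nan, 0,
                   valid=False, rel_defined=False, notes=note)


def _as_series(series, values=None) -> AnnualSeries:
    if isinstance(series, AnnualSeries):
        return series
    if values is None:
        values = np.asarray(series, dtype=float)
        return AnnualSeries(np.arange(values.size, dtype=float), values)
    return AnnualSeries(np.asarray(series, dtype=float), np.asarray(values, dtype=float))


def sen_slope(series, values=None) -> float:
    """Theil-Sen slope: median of all pairwise slopes (v_j - v_i)/(t_j - t_i).

    Accepts an :class:`AnnualSeries`, a bare value array (years 0..n-1), or
    ``(years, values)``.  Requires at least two points with distinct years.
    """
    s = _as_series(series, values).dropna()
    t, v = s.years, s.values
    if t.size < 2:
        raise ValueError("sen_slope needs at least 2 non-missing points")
    i, j = np.triu_indices(t.size, k=1)
    return float(np.median((v[j] - v[i]) / (t[j] - t[i])))


def mann_kendall(series, values=None) -> tuple[int, float, float]:
    """Mann-Kendall S, tie-corrected Z (with continuity correction) and p.

    S sums the signs of all pairwise differences in time order; its variance
    uses the standard tie correction and Z applies the +/-1 continuity
    correction before a two-sided normal p-value.  An all-tied series gives
    S = 0, Z = 0, p = 1.
    """
    s = _as_series(series, values).dropna()
    v = s.values
    n = v.size
    if n < 3:
        raise ValueError("mann_kendall needs at least 3 non-missing points")
    i, j = np.triu_indices(n, k=1)
    S = int(np.sign(v[j] - v[i]).sum())
    # tie-corrected variance of S
    _, counts = np.unique(v, return_counts=True)
    ties = counts[counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if var_s <= 0 or S == 0:
        return S, 0.0, 1.0
    z = (S - np.sign(S)) / np.sqrt(var_s)
    p = 2.0 * stats.norm.sf(abs(z))
    return S, float(z), float(min(p, 1.0))


def lag1_autocorrelation(residuals) -> float:
    """Lag-1 serial correlation r1 = sum (y_t - m)(y_{t+1} - m) / sum (y_t - m)^2.

    A zero-variance input returns 0 by convention.
    """
    y = np.asarray(residuals, dtype=float)
    y = y[np.isfinite(y)]
    if y.size < 3:
        raise ValueError("lag1_autocorrelation needs at least 3 points")
    d = y - y.mean()
    denom = np.sum(d * d)
    if denom == 0:
        return 0.0
    return float(np.sum(d[:-1] * d[1:]) / denom)


def yue_pilon_prewhiten(series, values=None, r1_threshold: float = R1_THRESHOLD) -> AnnualSeries:
    """Trend-free pre-whitening of an equally spaced annual series.

    Steps: (1) Sen slope b; (2) detrend; (3) lag-1 autocorrelation r1 of the
    residuals; (4) whiten y''_t = y'_t - r1 * y'_{t-1} (length n-1);
    (5) add the trend b*t back.  When |r1| <= ``r1_threshold`` the series is
    returned unchanged (no length loss).
    """
    s = _as_series(series, values).dropna()
    t, v = s.years, s.values
    if t.size < 4:
        raise ValueError("yue_pilon_prewhiten needs at least 4 points")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0]):
        raise ValueError("yue_pilon_prewhiten requires equally spaced years; resample upstream")
    b = sen_slope(s)
    resid = v - b * t
    r1 = lag1_autocorrelation(resid)
    if abs(r1) <= r1_threshold:
        return s
    whitened = resid[1:] - r1 * resid[:-1]
    return AnnualSeries(t[1:], whitened + b * t[1:])


def relative_change(slope_abs: float, mean_value: float,
                    guard: float = RELATIVE_CHANGE_GUARD) -> tuple[float, bool]:
    """Slope divided by the period-mean value; flagged undefined below ``guard``.

    Returns ``(value, defined)``; the ratio is numerically unstable for mean
    cover near zero, hence the 1 percent guard.
    """
    if mean_value < 0:
        raise ValueError("mean_value must be nonnegative")
    if mean_value < guard:
        return np.nan, False
    return float(slope_abs / mean_value), True


def estimate_trend(series, values=None, min_years: int = MIN_YEARS,
                   prewhiten: bool = True,
                   r1_threshold: float = R1_THRESHOLD) -> TrendEstimate:
    """Full trend estimate: pre-whiten, then Sen slope and Mann-Kendall.

    The mean value (and hence the relative slope) always refers to the raw
    series over the whole window.  Series with fewer than ``min_years``
    non-missing years are flagged missing rather than raising.  Gappy but
    otherwise valid series are re-indexed to consecutive steps for the
    pre-whitening pass only; slopes always use the true year axis.
    """
    s = _as_series(series, values).dropna()
    if s.n_present < max(min_years, 4):
        return TrendEstimate.missing()
    mean_value = float(s.values.mean())
    dt = np.diff(s.years)
    equal = np.allclose(dt, dt[0])
    work = s if equal else AnnualSeries(np.arange(s.years.size, dtype=float) * dt.min() + s.years[0], s.values)
    b0 = sen_slope(work)
    resid = work.values - b0 * work.years
    r1 = lag1_autocorrelation(resid)
    pw = yue_pilon_prewhiten(work, r1_threshold=r1_threshold) if prewhiten else work
    slope = sen_slope(pw)
    S, Z, p = mann_kendall(pw)
    rel, defined = relative_change(slope, mean_value) if mean_value >= 0 else (np.nan, False)
    return TrendEstimate(
        slope_abs=float(slope), slope_rel=rel, mean_value=mean_value,
        mk_S=S, mk_Z=Z, p_value=p, lag1=float(r1), n_used=pw.years.size,
        valid=True, rel_defined=defined,
    )


# ---------------------------------------------------------------------------
# vectorised entry points


def sen_slope_matrix(values: np.ndarray, years: np.ndarray | None = None) -> np.ndarray:
    """Row-wise Sen slope for a (series x year) matrix with no missing data."""
    v = np.asarray(values, dtype=float)
    t = np.arange(v.shape[1], dtype=float) if years is None else np.asarray(years, dtype=float)
    i, j = np.triu_indices(t.size, k=1)
    slopes = (v[:, j] - v[:, i]) / (t[j] - t[i])
    return np.median(slopes, axis=1)


def trend_table(df: pd.DataFrame, value_col: str = "value", **kwargs) -> pd.DataFrame:
    """Per-plot trend estimates from a long table (plot_id, year, value)."""
    rows = []
    for plot_id, g in df.groupby("plot_id", sort=True):
        g = g.sort_values("year")
        est = estimate_trend(g["year"].to_numpy(float), g[value_col].to_numpy(float), **kwargs)
        rows.append({"plot_id": plot_id, "slope_abs": est.slope_abs,
                     "slope_rel": est.slope_rel, "mean_value": est.mean_value,
                     "mk_S": est.mk_S, "mk_Z": est.mk_Z, "p_value": est.p_value,
                     "lag1": est.lag1, "n_used": est.n_used, "valid": est.valid})
    return pd.DataFrame(rows)
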