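"""Descriptive profile summaries of plot-level trends.

Binned running means along standardised boundary distance (SBD), stratified
means +/- SD by disturbance / vegetation / zone, missing-aware block
aggregation of trend rasters for coarse maps, and a range-shrinkage metric
comparing the latitudinal (SBD) span of treed area between two epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

BIN_WIDTH = 0.025
SBD_LO, SBD_HI = -1.5, 1.5

#: default SBD intervals for the verbal zones used in the zonal summaries
DEFAULT_ZONES = {
    "southern_boundary": (-1.1, -0.9),
    "interior": (-0.5, 0.5),
    "northern_interior": (0.5, 0.9),
}


@dataclass
class BinnedProfile:
    """Per-bin mean/sd/count of a plot value along SBD.

    Bins are half-open [lo, hi) of width ``bin_width`` partitioning
    [-1.5, 1.5]; the rightmost bin is closed so the endpoint is kept.
    """

    bin_centers: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    counts: np.ndarray
    bin_width: float = BIN_WIDTH

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_center": self.bin_centers, "mean": self.means,
                             "sd": self.sds, "count": self.counts})


def binned_running_mean(plots: pd.DataFrame, value: str = "slope_abs",
                        bin_width: float = BIN_WIDTH,
                        lo: float = SBD_LO, hi: float = SBD_HI) -> BinnedProfile:
    """Running mean of ``value`` along SBD with fixed-width bins.

    Rows with missing SBD or value are dropped; empty bins carry count 0 and
    NaN moments.
    """
    sbd = plots["sbd"].to_numpy(float)
    val = plots[value].to_numpy(float)
    ok = np.isfinite(sbd) & np.isfinite(val)
    sbd, val = sbd[ok], val[ok]
    nbins = int(round((hi - lo) / bin_width))
    edges = lo + np.arange(nbins + 1) * bin_width
    idx = np.clip(np.floor((sbd - lo) / bin_width).astype(int), 0, nbins - 1)
    inside = (sbd >= lo) & (sbd <= hi)
    idx, val = idx[inside], val[inside]
    counts = np.bincount(idx, minlength=nbins)
    sums = np.bincount(idx, weights=val, minlength=nbins)
    sq = np.bincount(idx, weights=val * val, minlength=nbins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / counts, np.nan)
        var = np.where(counts > 1, (sq - counts * means ** 2) / (counts - 1), np.nan)
    sds = np.sqrt(np.maximum(var, 0.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return BinnedProfile(centers, means, sds, counts, bin_width)


def assign_zone(sbd, zones: dict | None = None) -> np.ndarray:
    """Map SBD values to named zones (half-open (lo, hi] intervals); else 'other'."""
    zones = zones or DEFAULT_ZONES
    sbd = np.asarray(sbd, float)
    out = np.full(sbd.shape, "other", dtype=object)
    for name, (lo, hi) in zones.items():
        out[(sbd > lo) & (sbd <= hi)] = name
    return out


def stratified_stats(plots: pd.DataFrame, by, value: str = "slope_abs",
                     zones: dict | None = None) -> pd.DataFrame:
    """Mean +/- sample SD (n-1) and n of ``value`` per stratum.

    ``by`` is a list of grouping columns; the pseudo-column ``"zone"`` is
    derived from SBD using the zone map.  Strata with no finite value are
    reported with n = 0 and missing moments.
    """
    df = plots.copy()
    if "zone" in by and "zone" not in df.columns:
        df["zone"] = assign_zone(df["sbd"].to_numpy(float), zones)
    rows = []
    for key, g in df.groupby(list(by), sort=True, dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        vals = g[value].to_numpy(float)
        vals = vals[np.isfinite(vals)]
        rec = dict(zip(by, key))
        rec.update({
            "n": int(vals.size),
            "mean": float(vals.mean()) if vals.size else np.nan,
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
        })
        rows.append(rec)
    return pd.DataFrame(rows)


def coarse_trend_map(raster: xr.DataArray, factor: int) -> xr.DataArray:
    """Missing-aware block-mean aggregation by an integer ``factor``.

    Blocks that are entirely missing stay missing; partial blocks average the
    available cells.  Edge rows/columns that do not fill a block are trimmed.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return raster.copy()
    return raster.coarsen(lat=factor, lon=factor, boundary="trim").mean()


@dataclass
class RangeShrinkage:
    """Change in the SBD span of treed area between two epochs.

    ``span`` is the distance between the configured lower/upper quantiles of
    the treed (cover >= threshold) SBD distribution; ``shrinkage`` is
    span(first epoch) - span(second epoch), positive when the treed belt
    contracted.
    """

    threshold: float
    quantiles: tuple
    south_edge: tuple  # (epoch1, epoch2) lower-quantile SBD
    north_edge: tuple
    span: tuple
    shrinkage: float
    treed_fraction: pd.DataFrame  # per-bin treed fraction per epoch
    flagged: bool = False
    note: str = ""


def range_shrinkage_metric(plots: pd.DataFrame, cover_epochs: tuple[str, str],
                           cover_threshold: float = 10.0,
                           quantiles: tuple[float, float] = (0.05, 0.95),
                           bin_width: float = BIN_WIDTH) -> RangeShrinkage:
    """Shrinkage of the treed SBD belt between two epochs.

    ``cover_epochs`` names two plot-table columns holding epoch-mean cover
    (e.g. mean cover 2000-2004 and 2015-2019).  Per epoch the metric records
    the treed-area fraction per SBD bin and the (q_lo, q_hi) SBD quantiles of
    treed plots; shrinkage is the reduction of the inter-quantile span.
    """
    q_lo, q_hi = quantiles
    edges_n = int(round((SBD_HI - SBD_LO) / bin_width))
    centers = SBD_LO + (np.arange(edges_n) + 0.5) * bin_width
    south, north, spans = [], [], []
    frames = []
    for col in cover_epochs:
        cov = plots[col].to_numpy(float)
        sbd = plots["sbd"].to_numpy(float)
        ok = np.isfinite(cov) & np.isfinite(sbd)
        cov, sbd = cov[ok], sbd[ok]
        treed = cov >= cover_threshold
        if not treed.any():
            return RangeShrinkage(cover_threshold, quantiles, (np.nan, np.nan),
                                  (np.nan, np.nan), (np.nan, np.nan), np.nan,
                                  pd.DataFrame(), flagged=True,
                                  note=f"no treed plots in epoch {col}")
        lo_q = float(np.quantile(sbd[treed], q_lo))
        hi_q = float(np.quantile(sbd[treed], q_hi))
        south.append(lo_q)
        north.append(hi_q)
        spans.append(hi_q - lo_q)
        idx = np.clip(np.floor((sbd - SBD_LO) / bin_width).astype(int), 0, edges_n - 1)
        tot = np.bincount(idx, minlength=edges_n)
        tr = np.bincount(idx[treed], minlength=edges_n)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(tot > 0, tr / tot, np.nan)
        frames.append(pd.DataFrame({"bin_center": centers, "epoch": col,
                                    "treed_fraction": frac, "n": tot}))
    return RangeShrinkage(
        threshold=cover_threshold, quantiles=quantiles,
        south_edge=tuple(south), north_edge=tuple(north), span=tuple(spans),
        shrinkage=float(spans[0] - spans[1]),
        treed_fraction=pd.concat(frames, ignore_index=True),
    )
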