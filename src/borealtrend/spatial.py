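"""Spatial autocorrelation of trend fields.

Empirical semivariograms on great-circle distances, weighted least-squares
fits of the standard bounded variogram models, and likelihood-based selection
of a residual correlation structure.  The fitted practical range (distance at
which the model reaches 95 % of its sill) is what the sampling design uses as
the minimum transect spacing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy.optimize import curve_fit, minimize
from sklearn.metrics.pairwise import haversine_distances

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088

MODELS = ("exponential", "gaussian", "spherical", "nugget")


def great_circle_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Pairwise haversine distance matrix in km between two point sets."""
    a = np.deg2rad(np.column_stack([np.atleast_1d(lat1), np.atleast_1d(lon1)]))
    b = np.deg2rad(np.column_stack([np.atleast_1d(lat2), np.atleast_1d(lon2)]))
    return haversine_distances(a, b) * EARTH_RADIUS_KM


@dataclass
class EmpiricalVariogram:
    """Binned semivariances vs great-circle lag distance."""

    lag_centers: np.ndarray  # km
    semivariances: np.ndarray  # squared units of the variable; NaN if bin empty
    pair_counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_km": self.lag_centers,
                             "semivariance": self.semivariances,
                             "pairs": self.pair_counts})


@dataclass
class VariogramFit:
    """Fitted bounded variogram model.

    ``practical_range`` is the 95 %-of-sill distance: 3a for the exponential,
    sqrt(3)a for the Gaussian and a for the spherical model.  ``identifiable``
    is False for pure-nugget structure (no finite range).
    """

    model: str
    nugget: float
    partial_sill: float
    range_param: float
    practical_range: float
    goodness: float  # weighted residual sum of squares
    converged: bool = True
    identifiable: bool = True

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def curve(self, h) -> np.ndarray:
        return variogram_model(self.model)(np.asarray(h, float),
                                           self.nugget, self.partial_sill, self.range_param)


def _gamma_exponential(h, c0, c, a):
    return c0 + c * (1.0 - np.exp(-h / a))


def _gamma_gaussian(h, c0, c, a):
    return c0 + c * (1.0 - np.exp(-((h / a) ** 2)))


def _gamma_spherical(h, c0, c, a):
    h = np.asarray(h, float)
    g = np.where(h >= a, c0 + c, c0 + c * (1.5 * h / a - 0.5 * (h / a) ** 3))
    return np.where(h == 0, c0, g)


def _gamma_nugget(h, c0, c, a):  # noqa: ARG001 - uniform signature
    return np.full_like(np.asarray(h, float), c0)


_GAMMA = {"exponential": _gamma_exponential, "gaussian": _gamma_gaussian,
          "spherical": _gamma_spherical, "nugget": _gamma_nugget}

#: multiplier turning the range parameter into the 95 %-of-sill practical range
_PRACTICAL = {"exponential": 3.0, "gaussian": np.sqrt(3.0), "spherical": 1.0}


def variogram_model(name: str):
    try:
        return _GAMMA[name]
    except KeyError:
        raise ValueError(f"unknown variogram model {name!r}; choose from {MODELS}")


def sample_random_points(field, n: int, seed: int) -> pd.DataFrame:
    """Uniformly sample ``n`` valid cells (or rows) with their values.

    ``field`` is either a 2-D DataArray with ``lon``/``lat`` coords (NaN cells
    invalid) or a DataFrame with lon/lat/value columns.  Deterministic under
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    if isinstance(field, xr.DataArray):
        vals = field.values
        valid = np.flatnonzero(np.isfinite(vals))
        if n > valid.size:
            raise ValueError(f"requested {n} points but only {valid.size} valid cells")
        pick = rng.choice(valid, size=n, replace=False)
        ii, jj = np.unravel_index(pick, vals.shape)
        lat = field["lat"].values[ii]
        lon = field["lon"].values[jj]
        return pd.DataFrame({"lon": lon, "lat": lat, "value": vals[ii, jj]})
    df = pd.DataFrame(field)
    ok = df.index[np.isfinite(df["value"].to_numpy(float))]
    if n > ok.size:
        raise ValueError(f"requested {n} points but only {ok.size} valid rows")
    pick = rng.choice(ok.to_numpy(), size=n, replace=False)
    return df.loc[pick, ["lon", "lat", "value"]].reset_index(drop=True)


def detrend_surface(points: pd.DataFrame, order: int = 2) -> pd.DataFrame:
    """Residuals of ``value`` against a polynomial surface in (lon, lat).

    Removes large-scale deterministic drift before variography so the
    variogram measures the stochastic component; ``order`` 0 returns the
    points unchanged apart from mean-centering being skipped.
    """
    if order <= 0:
        return points
    x = points["lon"].to_numpy(float)
    y = points["lat"].to_numpy(float)
    x = (x - x.mean()) / max(x.std(), 1e-12)
    y = (y - y.mean()) / max(y.std(), 1e-12)
    cols = [np.ones_like(x)]
    for total in range(1, order + 1):
        for i in range(total + 1):
            cols.append(x ** (total - i) * y ** i)
    X = np.column_stack(cols)
    z = points["value"].to_numpy(float)
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    out = points.copy()
    out["value"] = z - X @ beta
    return out


def empirical_variogram(points: pd.DataFrame, lag_width_km: float = 25.0,
                        max_lag_km: float = 500.0,
                        chunk: int = 512) -> EmpiricalVariogram:
    """Matheron estimator gamma(h) = sum (z_i - z_j)^2 / (2 N_h), binned by distance.

    Pair distances are great-circle km; computation is chunked so 10,000-point
    clouds stay within memory.  Empty bins carry count 0 and NaN semivariance.
    """
    if lag_width_km <= 0:
        raise ValueError("lag_width_km must be positive")
    lon = points["lon"].to_numpy(float)
    lat = points["lat"].to_numpy(float)
    z = points["value"].to_numpy(float)
    npts = lon.size
    if npts < 2:
        raise ValueError("need at least 2 points")
    nbins = int(np.ceil(max_lag_km / lag_width_km))
    edges = np.arange(nbins + 1) * lag_width_km
    sq_sum = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=np.int64)
    for start in range(0, npts, chunk):
        stop = min(start + chunk, npts)
        d = great_circle_km(lon[start:stop], lat[start:stop], lon, lat)
        dz2 = (z[start:stop, None] - z[None, :]) ** 2
        # keep each unordered pair once: global column index > global row index
        cols = np.arange(npts)[None, :]
        rows = np.arange(start, stop)[:, None]
        mask = (cols > rows) & (d < edges[-1])
        idx = np.floor_divide(d[mask], lag_width_km).astype(np.int64)
        np.add.at(sq_sum, idx, dz2[mask])
        np.add.at(counts, idx, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, sq_sum / (2.0 * counts), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return EmpiricalVariogram(centers, gamma, counts)


def fit_variogram_model(vg: EmpiricalVariogram, model: str = "exponential",
                        nugget_tol_frac: float = 0.05) -> VariogramFit:
    """Weighted least squares fit of (nugget, partial sill, range).

    Weights are the per-lag pair counts.  A fit whose partial sill is below
    ``nugget_tol_frac`` of the total sill is flagged not-identifiable (pure
    nugget: no finite range).
    """
    ok = (vg.pair_counts > 0) & np.isfinite(vg.semivariances)
    h = vg.lag_centers[ok]
    g = vg.semivariances[ok]
    w = vg.pair_counts[ok].astype(float)
    if ok.sum() < 4:
        raise ValueError("need at least 4 populated lags to fit a variogram model")
    gmax = max(g.max(), 1e-12)
    if model == "nugget":
        c0 = float(np.average(g, weights=w))
        wrss = float(np.sum(w * (g - c0) ** 2))
        return VariogramFit("nugget", c0, 0.0, np.inf, np.inf, wrss, identifiable=False)
    fn = variogram_model(model)
    p0 = [max(g[0], 1e-6 * gmax), max(gmax - g[0], 1e-6 * gmax), h.max() / 4.0]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # range capped at 3x the largest lag: nothing beyond is identifiable
            popt, _ = curve_fit(fn, h, g, p0=p0, sigma=1.0 / np.sqrt(w),
                                bounds=([0, 0, 1e-6], [10 * gmax, 10 * gmax, 3 * h.max()]),
                                maxfev=20000)
        converged = True
    except RuntimeError:
        logger.warning("variogram fit did not converge for model %s", model)
        popt, converged = p0, False
    c0, c, a = (float(x) for x in popt)
    wrss = float(np.sum(w * (g - fn(h, c0, c, a)) ** 2))
    identifiable = converged and c > nugget_tol_frac * max(c0 + c, 1e-12)
    pr = _PRACTICAL[model] * a if identifiable else np.nan
    return VariogramFit(model, c0, c, a, pr, wrss,
                        converged=converged, identifiable=identifiable)


# ---------------------------------------------------------------------------
# correlation-structure selection (intercept-only spatial GLS, ML + AICc)


def _correlation_matrix(family: str, d: np.ndarray, prange: float, nugget_frac: float) -> np.ndarray:
    """Correlation matrix with the given 95 %-practical-range parameterisation."""
    if family == "none":
        return np.eye(d.shape[0])
    if family == "exponential":
        rho = np.exp(-3.0 * d / prange)
    elif family == "gaussian":
        rho = np.exp(-3.0 * (d / prange) ** 2)
    elif family == "spherical":
        x = np.minimum(d / prange, 1.0)
        rho = 1.0 - 1.5 * x + 0.5 * x ** 3
    else:
        raise ValueError(f"unknown correlation family {family!r}")
    R = (1.0 - nugget_frac) * rho
    np.fill_diagonal(R, 1.0)
    return R


def _profile_neg_loglik(R: np.ndarray, y: np.ndarray) -> float:
    n = y.size
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        return np.inf
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    ones = np.linalg.solve(L, np.ones(n))
    yw = np.linalg.solve(L, y)
    mu = float(ones @ yw / (ones @ ones))
    r = yw - mu * ones
    sigma2 = float(r @ r) / n
    if sigma2 <= 0:
        return np.inf
    return 0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)


def select_correlation_structure(points: pd.DataFrame,
                                 candidates=("none", "exponential", "gaussian", "spherical"),
                                 ) -> str:
    """Pick the residual correlation family by small-sample AICc.

    Fits an intercept-only Gaussian model under each candidate structure by
    maximum likelihood (profiling the mean and variance, optimising the
    practical range and nugget fraction) and returns the AICc-minimising
    family.  Singular fits are excluded with a warning.
    """
    if len(candidates) == 1:
        return candidates[0]
    lon = points["lon"].to_numpy(float)
    lat = points["lat"].to_numpy(float)
    y = points["value"].to_numpy(float)
    n = y.size
    if n < 50:
        raise ValueError("need at least 50 points for structure selection")
    d = great_circle_km(lon, lat, lon, lat)
    dmax = d.max()
    scores = {}
    for fam in candidates:
        k = 2 if fam == "none" else 4  # mean, variance (+ range, nugget frac)
        if fam == "none":
            nll = _profile_neg_loglik(np.eye(n), y)
        else:
            def obj(theta, fam=fam):
                prange = np.exp(theta[0])
                nf = 1.0 / (1.0 + np.exp(-theta[1]))
                return _profile_neg_loglik(_correlation_matrix(fam, d, prange, nf), y)
            best = None
            for pr0 in (dmax / 10, dmax / 3):
                res = minimize(obj, x0=[np.log(pr0), -2.0], method="Nelder-Mead",
                               options={"xatol": 1e-3, "fatol": 1e-4, "maxiter": 300})
                if best is None or res.fun < best.fun:
                    best = res
            nll = best.fun
        if not np.isfinite(nll) or n - k - 1 <= 0:
            logger.warning("excluding singular fit for family %s", fam)
            continue
        aicc = 2 * nll + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        scores[fam] = aicc
    if not scores:
        raise RuntimeError("no correlation structure produced a valid fit")
    return min(scores, key=scores.get)
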