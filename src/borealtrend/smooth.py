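"""Semiparametric profile fits of plot trends against a predictor.

The model is a penalized cubic B-spline smooth of the predictor, fitted
separately within each stratum (disturbance category, or disturbance x
vegetation combination) but sharing one smoothing penalty, with a
transect-level random intercept and exponentially decaying residual spatial
correlation.  Estimation is two-stage feasible GLS:

1. penalized OLS with the penalty weight chosen by GCV;
2. variance components from the stage-1 residuals (transect intercept
   variance from transect means, spatial nugget/sill/practical range from a
   residual variogram), then a whitened penalized GLS refit.

Curves and pointwise standard errors are returned on an even predictor grid
per stratum.  The B-spline basis and its difference penalty come from
statsmodels; the penalized GLS solve is explicit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from statsmodels.gam.smooth_basis import BSplines

from .spatial import empirical_variogram, fit_variogram_model, great_circle_km

logger = logging.getLogger(__name__)

MIN_STRATUM_SIZE = 10


@dataclass
class SmoothModelSpec:
    """Configuration of one smooth profile model."""

    response: str = "slope_abs"
    predictor: str = "sbd"
    strata: str | None = "disturbance_category"  # None = single stratum
    basis_dim: int = 10
    random_group: str | None = "transect_id"
    correlation: str | None = "exponential"  # None = independent residuals
    correlation_range_km: float | None = None  # None = estimate from residuals
    n_grid: int = 50
    lambda_grid: tuple = tuple(np.logspace(-8, 6, 29))

    def __post_init__(self):
        if self.basis_dim < 4:
            raise ValueError("basis_dim must be at least 4")


@dataclass
class FittedProfile:
    """Per-stratum fitted curve +/- SE with fit diagnostics."""

    curves: pd.DataFrame  # columns: stratum, grid, fit, se
    diagnostics: dict = field(default_factory=dict)

    @property
    def degenerate(self) -> bool:
        return bool(self.diagnostics.get("degenerate", False))

    def stratum_curve(self, stratum) -> pd.DataFrame:
        return self.curves[self.curves["stratum"] == stratum].reset_index(drop=True)


def _design(x: np.ndarray, groups: np.ndarray, basis_dim: int):
    """Block design matrix: one B-spline basis block per stratum, shared knots."""
    bs = BSplines(x.reshape(-1, 1), df=[basis_dim], degree=[3], include_intercept=True)
    B = bs.basis
    S1 = bs.penalty_matrices[0]
    labels = pd.unique(groups)
    p = B.shape[1]
    X = np.zeros((x.size, p * labels.size))
    for k, lab in enumerate(labels):
        m = groups == lab
        X[m, k * p:(k + 1) * p] = B[m]
    S = np.kron(np.eye(labels.size), S1)
    return X, S, bs, list(labels), p


def _penalized_gls(Xw, yw, S, lambda_grid):
    """Solve the ridge-type system for each lambda; pick by GCV."""
    XtX = Xw.T @ Xw
    Xty = Xw.T @ yw
    n = yw.size
    best = None
    for lam in lambda_grid:
        A = XtX + lam * S
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            continue
        beta = Ainv @ Xty
        edf = float(np.trace(Ainv @ XtX))
        rss = float(np.sum((yw - Xw @ beta) ** 2))
        denom = max(n - edf, 1e-8)
        gcv = n * rss / denom ** 2
        if best is None or gcv < best["gcv"]:
            best = {"lam": lam, "beta": beta, "Ainv": Ainv, "edf": edf,
                    "rss": rss, "gcv": gcv}
    if best is None:
        raise np.linalg.LinAlgError("penalized GLS failed for every penalty weight")
    return best


def _residual_covariance(resid, lon, lat, transects, correlation, range_km):
    """Feasible covariance of the stage-1 residuals.

    Spatial part from a residual variogram (nugget + partial sill +
    exponential practical range), transect random-intercept variance from the
    excess variance of transect means.  Returns a dense n x n matrix.
    """
    n = resid.size
    sigma2 = float(np.var(resid, ddof=1))
    V = np.zeros((n, n))
    c0, c, prange = sigma2, 0.0, np.inf
    if correlation is not None:
        pts = pd.DataFrame({"lon": lon, "lat": lat, "value": resid})
        max_lag = min(500.0, 0.5 * great_circle_km(lon.min(), lat.min(),
                                                   lon.max(), lat.max())[0, 0])
        lag = max(max_lag / 20.0, 1.0)
        try:
            vg = empirical_variogram(pts, lag_width_km=lag, max_lag_km=max_lag)
            fit = fit_variogram_model(vg, correlation)
            if fit.identifiable:
                c0, c = fit.nugget, fit.partial_sill
                prange = range_km or fit.practical_range
        except (ValueError, RuntimeError):
            logger.warning("residual variogram fit failed; assuming independence")
        if np.isfinite(prange) and c > 0:
            d = great_circle_km(lon, lat, lon, lat)
            V += c * np.exp(-3.0 * d / prange)
        np.fill_diagonal(V, c0 + c)
    else:
        np.fill_diagonal(V, sigma2)
    tau2 = 0.0
    if transects is not None:
        tdf = pd.DataFrame({"t": transects, "r": resid})
        gm = tdf.groupby("t")["r"].agg(["mean", "count"])
        if len(gm) > 1:
            within = c0 if correlation is not None else sigma2
            tau2 = max(0.0, float(np.var(gm["mean"], ddof=1))
                       - within * float(np.mean(1.0 / gm["count"])))
        if tau2 > 0:
            same = np.equal.outer(np.asarray(transects), np.asarray(transects))
            V += tau2 * same
    return V, {"nugget": c0, "partial_sill": c, "practical_range_km": prange,
               "transect_var": tau2}


def fit_smooth_by_stratum(plots: pd.DataFrame, spec: SmoothModelSpec) -> FittedProfile:
    """Fit the stratified smooth profile model and predict curves +/- SE.

    Strata with fewer than ``MIN_STRATUM_SIZE`` usable plots are dropped with
    a warning; a constant predictor (or response) yields a flagged degenerate
    fit rather than an exception.
    """
    cols = [spec.response, spec.predictor, "lon", "lat"]
    if spec.strata:
        cols.append(spec.strata)
    if spec.random_group:
        cols.append(spec.random_group)
    df = plots.dropna(subset=[c for c in cols if c in plots.columns]).copy()
    y = df[spec.response].to_numpy(float)
    x = df[spec.predictor].to_numpy(float)
    if x.size < MIN_STRATUM_SIZE or np.ptp(x) == 0:
        return FittedProfile(pd.DataFrame(columns=["stratum", "grid", "fit", "se"]),
                             {"degenerate": True,
                              "reason": "constant or insufficient predictor"})
    groups = (df[spec.strata].to_numpy() if spec.strata
              else np.full(x.size, "all", dtype=object))
    sizes = pd.Series(groups).value_counts()
    keep_labels = sizes[sizes >= MIN_STRATUM_SIZE].index
    dropped = sizes[sizes < MIN_STRATUM_SIZE].index.tolist()
    if dropped:
        logger.warning("dropping strata below minimum size: %s", dropped)
    m = np.isin(groups, keep_labels)
    df, y, x, groups = df[m], y[m], x[m], groups[m]
    if x.size < MIN_STRATUM_SIZE:
        return FittedProfile(pd.DataFrame(columns=["stratum", "grid", "fit", "se"]),
                             {"degenerate": True, "reason": "all strata too small"})

    X, S, bs, labels, p = _design(x, groups, spec.basis_dim)
    # stage 1: penalized OLS
    stage1 = _penalized_gls(X, y, S, spec.lambda_grid)
    resid = y - X @ stage1["beta"]
    # stage 2: whiten with the feasible residual covariance and refit
    lon = df["lon"].to_numpy(float)
    lat = df["lat"].to_numpy(float)
    transects = df[spec.random_group].to_numpy() if (
        spec.random_group and spec.random_group in df.columns) else None
    V, vparts = _residual_covariance(resid, lon, lat, transects,
                                     spec.correlation, spec.correlation_range_km)
    try:
        L = np.linalg.cholesky(V + 1e-10 * np.trace(V) / V.shape[0] * np.eye(V.shape[0]))
        Xw = solve_triangular(L, X, lower=True)
        yw = solve_triangular(L, y, lower=True)
    except np.linalg.LinAlgError:
        logger.warning("covariance not positive definite; falling back to OLS weights")
        Xw, yw = X, y
    fit = _penalized_gls(Xw, yw, S, spec.lambda_grid)
    n = yw.size
    sigma2_hat = fit["rss"] / max(n - fit["edf"], 1.0)
    cov_beta = sigma2_hat * fit["Ainv"]

    rows = []
    for k, lab in enumerate(labels):
        xs = x[groups == lab]
        grid = np.linspace(xs.min(), xs.max(), spec.n_grid)
        Bg = bs.transform(grid.reshape(-1, 1))
        block = slice(k * p, (k + 1) * p)
        mu = Bg @ fit["beta"][block]
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Bg, cov_beta[block, block], Bg), 0.0))
        rows.append(pd.DataFrame({"stratum": lab, "grid": grid, "fit": mu, "se": se}))
    curves = pd.concat(rows, ignore_index=True)
    resid_w = yw - Xw @ fit["beta"]
    diagnostics = {
        "n": int(n), "edf": fit["edf"], "lambda": fit["lam"], "gcv": fit["gcv"],
        "sigma2_whitened": sigma2_hat, "dropped_strata": dropped,
        "residual_mean": float(resid_w.mean()), "residual_sd": float(resid_w.std(ddof=1)),
        **vparts,
    }
    return FittedProfile(curves, diagnostics)


def fit_single_predictor_models(plots: pd.DataFrame, predictors: list[str],
                                base_spec: SmoothModelSpec | None = None,
                                ) -> dict[str, FittedProfile]:
    """One smooth fit per predictor, identical stratum/correlation settings.

    Mirrors the one-model-per-variable strategy used when predictors are too
    collinear for a joint model.
    """
    base = base_spec or SmoothModelSpec()
    out = {}
    for pred in predictors:
        if pred not in plots.columns:
            raise KeyError(f"predictor {pred!r} not in plot table")
        spec = SmoothModelSpec(**{**base.__dict__, "predictor": pred,
                                  "lambda_grid": base.lambda_grid})
        out[pred] = fit_smooth_by_stratum(plots, spec)
    return out


def collinearity_screen(plots: pd.DataFrame, fields: list[str],
                        threshold: float = 0.7) -> pd.DataFrame:
    """Pairwise Pearson correlations with a high-|r| flag column.

    A light-weight stand-in for an exploratory ordination: it reports, for
    every field pair, the correlation and whether it exceeds ``threshold``.
    """
    if len(fields) < 2:
        raise ValueError("need at least 2 fields")
    corr = plots[fields].corr()
    rows = []
    for i, a in enumerate(fields):
        for b in fields[i + 1:]:
            r = float(corr.loc[a, b])
            rows.append({"field_a": a, "field_b": b, "r": r,
                         "flagged": bool(abs(r) >= threshold)})
    return pd.DataFrame(rows)
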