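"""Seeded synthetic landscape generator.

Produces a desk-scale stand-in for the continental input rasters: an annual
tree-cover stack carrying a known SBD-dependent trend profile g(sbd), AR(1)
interannual noise, a spatially correlated (exponential-covariance) static
field, patchy fire/harvest disturbances with years 1985-2019, a class-coded
land-cover grid, coarse climate stacks with a linear warming trend, elevation,
and the two biome boundary polylines.  Every generated bundle is accompanied
by a ground-truth ledger sufficient to score pipeline estimates.

Cover is assembled per pixel and year as::

    cover_t(x) = clip( baseline(sbd(x)) + g(sbd(x)) * (t - t0)
                       + spatial_field(x) + ar1_t(x) + disturbance(x, t),
                       0, 100 )

The generator is deterministic: identical config and seed give bit-identical
arrays (stage RNGs are spawned from one SeedSequence).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import xarray as xr
from scipy import fft as sfft
from scipy.interpolate import PchipInterpolator

from .sampling import BiomeBoundaries, FIRE, HARVEST

KM_PER_DEG = 111.195  # great-circle km per degree of latitude


@dataclass
class LandscapeConfig:
    """Generator configuration; defaults define the standard study conditions.

    The default domain is 15 x 10 degrees (lon x lat) at 0.01 degree
    resolution (a desk-scale stand-in for 250 m continental rasters), with
    20 cover years,
    an asymmetric trend profile (southern losses, northern-interior gains),
    AR(1) interannual noise, a 90 km practical-range spatial field, and a
    ~0.04 degC/yr warming trend since 1980.
    """

    lon_min: float = -115.0
    lon_max: float = -100.0
    lat_min: float = 51.0
    lat_max: float = 61.0
    resolution: float = 0.01  # degrees
    year_start: int = 2000
    year_end: int = 2019

    # boundary geometry: two latitudes plus a sinusoidal wiggle
    boundary_south_lat: float = 53.5
    boundary_north_lat: float = 58.5
    boundary_wiggle_amp: float = 0.6  # degrees
    boundary_wiggle_periods: float = 1.5

    # trend profile g(sbd) in percent/yr, interpolated through control points
    trend_profile: tuple = ((-1.5, 0.0), (-1.25, 0.0), (-1.0, -0.13),
                            (0.5, 0.22), (1.0, 0.05), (1.25, 0.0), (1.5, 0.0))
    # baseline cover (percent) vs sbd: densest in the interior, thinning
    # toward both boundaries so trend-driven threshold crossings can occur
    baseline_profile: tuple = ((-1.5, 5.0), (-1.2, 8.0), (-1.0, 14.0),
                               (-0.5, 35.0), (0.0, 45.0), (0.5, 35.0),
                               (1.0, 12.0), (1.5, 4.0))

    ar1_rho: float = 0.3
    temporal_sd: float = 2.0  # percent, marginal sd of the AR(1) noise
    spatial_range_km: float = 90.0  # practical (95 %) range of the static field
    spatial_sd: float = 3.0  # percent
    # spatially correlated local deviations of the trend itself (percent/yr);
    # this is what gives the trend field a finite autocorrelation range
    trend_field_sd: float = 0.06
    trend_field_range_km: float = 110.0
    # noise amplitude scales with baseline cover (variance of a bounded
    # percent-cover product shrinks toward the 0 % floor); amp = clip(
    # baseline / noise_cover_scale, noise_amp_floor, 1)
    noise_cover_scale: float = 25.0
    noise_amp_floor: float = 0.15

    # disturbances: random circular patches
    patch_density_per_deg2: float = 0.5
    patch_radius_deg: tuple = (0.05, 0.30)  # uniform radius range
    fire_fraction: float = 0.7
    disturbance_years: tuple = (1985, 2019)
    fire_drop: float = 30.0  # percent cover lost at the event
    harvest_drop: float = 40.0
    recovery_rate_south: float = 1.0  # percent/yr at sbd = -1.5 (slower south)
    recovery_rate_north: float = 2.5  # percent/yr at sbd = +1.5

    # climate (coarse grid): MAT linear in latitude + warming trend since 1980
    climate_resolution: float = 0.25
    climate_year_start: int = 1980
    mat_at_south_edge: float = 2.0  # degC at lat_min
    mat_lapse_per_deg: float = -0.6  # degC per degree latitude northward
    warming_per_year: float = 0.04  # degC/yr
    mat_noise_sd: float = 0.25
    map_at_south_edge: float = 700.0  # mm
    map_lapse_per_deg: float = -25.0
    map_trend_per_year: float = 0.0
    map_noise_sd: float = 25.0

    elevation_base: float = 350.0
    elevation_lapse_per_deg: float = 15.0
    elevation_relief: float = 120.0

    # land cover: cover-dependent classes plus excluded-class patches
    water_fraction: float = 0.02
    wetland_fraction: float = 0.01

    seed: int = 0

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Everything needed to score a pipeline estimate of the synthetic truth."""

    sbd: xr.DataArray  # per-pixel true standardised boundary distance
    true_trend: xr.DataArray  # g(sbd(x)), percent/yr, disturbance excluded
    disturbances: pd.DataFrame  # patch ledger: type, year, lon, lat, radius
    trend_profile: PchipInterpolator  # callable g(sbd)
    baseline_profile: PchipInterpolator
    climate_trend: float  # true warming rate, degC/yr


@dataclass
class LandscapeBundle:
    """In-memory raster bundle mirroring the on-disk layout."""

    cover: xr.DataArray  # (year, lat, lon), percent
    landcover: xr.DataArray  # (lat, lon), class codes
    dist_type: xr.DataArray  # (lat, lon), 0/1/2
    dist_year: xr.DataArray  # (lat, lon), 0 = none
    mat: xr.DataArray  # (year, lat, lon) coarse annual mean temperature
    map_: xr.DataArray  # (year, lat, lon) coarse annual precipitation
    elevation: xr.DataArray  # (lat, lon), m
    boundaries: BiomeBoundaries
    truth: GroundTruth
    config: LandscapeConfig
    clip_fraction: float = 0.0


def _profile(points) -> PchipInterpolator:
    pts = np.asarray(points, float)
    return PchipInterpolator(pts[:, 0], pts[:, 1], extrapolate=False)


def _eval_profile(f: PchipInterpolator, x: np.ndarray) -> np.ndarray:
    lo, hi = f.x[0], f.x[-1]
    y = f(np.clip(x, lo, hi))
    return np.asarray(y, float)


def make_boundaries(cfg: LandscapeConfig, n_vertices: int = 201) -> BiomeBoundaries:
    lons = np.linspace(cfg.lon_min, cfg.lon_max, n_vertices)
    phase = 2 * np.pi * cfg.boundary_wiggle_periods * (lons - cfg.lon_min) / (cfg.lon_max - cfg.lon_min)
    south = cfg.boundary_south_lat + cfg.boundary_wiggle_amp * np.sin(phase)
    north = cfg.boundary_north_lat + cfg.boundary_wiggle_amp * np.sin(phase + 0.9)
    return BiomeBoundaries(lons, south, north)


def sbd_grid(cfg: LandscapeConfig, boundaries: BiomeBoundaries,
             lons: np.ndarray, lats: np.ndarray) -> np.ndarray:
    """Continuous per-pixel SBD: linear between the boundaries, +/-0.5 over the
    20-plot (1 degree) extension span beyond them, capped at +/-1.5."""
    s = boundaries.south(lons)[None, :]
    n = boundaries.north(lons)[None, :]
    lat2 = lats[:, None]
    interior = -1.0 + 2.0 * (lat2 - s) / (n - s)
    ext_span = 1.0  # degrees covered by 20 extension plots of 0.05 degrees
    sbd = np.where(lat2 < s, -1.0 - 0.5 * (s - lat2) / ext_span, interior)
    sbd = np.where(lat2 > n, 1.0 + 0.5 * (lat2 - n) / ext_span, sbd)
    return np.clip(sbd, -1.5, 1.5)


def spatial_field(ny: int, nx: int, dy_km: float, dx_km: float,
                  practical_range_km: float, sd: float, rng: np.random.Generator,
                  ) -> np.ndarray:
    """Stationary Gaussian field with exponential covariance, via circulant
    embedding on the doubled torus (FFT).  Negative embedding eigenvalues are
    clipped to zero (their mass is negligible for these parameters)."""
    if sd == 0:
        return np.zeros((ny, nx))
    if practical_range_km <= 0:
        raise ValueError("practical_range_km must be positive")
    My, Mx = 2 * ny, 2 * nx
    wy = np.minimum(np.arange(My), My - np.arange(My)) * dy_km
    wx = np.minimum(np.arange(Mx), Mx - np.arange(Mx)) * dx_km
    d = np.sqrt(wy[:, None] ** 2 + wx[None, :] ** 2).astype(np.float32)
    cov = (sd * sd * np.exp(-3.0 * d / practical_range_km)).astype(np.complex64)
    lam = sfft.fft2(cov).real
    lam = np.sqrt(np.maximum(lam, 0.0))
    noise = (rng.standard_normal((My, Mx), dtype=np.float32)
             + 1j * rng.standard_normal((My, Mx), dtype=np.float32))
    z = sfft.ifft2((lam * noise).astype(np.complex64)) * np.sqrt(My * Mx)
    return np.ascontiguousarray(z.real[:ny, :nx]).astype(np.float32)


def disturbance_effect(dist_year: np.ndarray, dist_type: np.ndarray,
                       sbd: np.ndarray, years: np.ndarray,
                       cfg: LandscapeConfig,
                       drop_cap: np.ndarray | None = None) -> np.ndarray:
    """Additive cover term (year, ...) for disturbed pixels.

    A step drop at the event year followed by linear recovery whose rate
    increases with SBD (slower recovery toward the south), clamped at zero
    once recovered.  Pixels with no event contribute zero.  ``drop_cap``
    (e.g. the local baseline cover) limits the drop to the cover actually
    present.
    """
    drop = np.where(dist_type == FIRE, cfg.fire_drop,
                    np.where(dist_type == HARVEST, cfg.harvest_drop, 0.0))
    if drop_cap is not None:
        drop = np.minimum(drop, np.maximum(drop_cap, 0.0))
    frac = (np.clip(sbd, -1.5, 1.5) + 1.5) / 3.0
    rate = cfg.recovery_rate_south + frac * (cfg.recovery_rate_north - cfg.recovery_rate_south)
    out = np.zeros((years.size,) + dist_year.shape, dtype=np.float32)
    for k, t in enumerate(years):
        dt = t - dist_year
        active = (dist_type > 0) & (dt >= 0)
        remaining = np.maximum(drop - rate * dt, 0.0)
        out[k] = np.where(active, -remaining, 0.0)
    return out


def _rasterize_patches(cfg: LandscapeConfig, lons: np.ndarray, lats: np.ndarray,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Random circular disturbance patches -> (type grid, year grid, ledger)."""
    ny, nx = lats.size, lons.size
    area = (cfg.lon_max - cfg.lon_min) * (cfg.lat_max - cfg.lat_min)
    n_patches = int(round(cfg.patch_density_per_deg2 * area))
    tgrid = np.zeros((ny, nx), dtype=np.int16)
    ygrid = np.zeros((ny, nx), dtype=np.int16)
    rows = []
    res = cfg.resolution
    coslat = np.cos(np.deg2rad((cfg.lat_min + cfg.lat_max) / 2))
    for pid in range(n_patches):
        cx = rng.uniform(cfg.lon_min, cfg.lon_max)
        cy = rng.uniform(cfg.lat_min, cfg.lat_max)
        r = rng.uniform(*cfg.patch_radius_deg)
        ptype = FIRE if rng.uniform() < cfg.fire_fraction else HARVEST
        year = int(rng.integers(cfg.disturbance_years[0], cfg.disturbance_years[1] + 1))
        j0 = max(0, int((cx - r / coslat - cfg.lon_min) / res) - 1)
        j1 = min(nx, int((cx + r / coslat - cfg.lon_min) / res) + 2)
        i0 = max(0, int((cy - r - cfg.lat_min) / res) - 1)
        i1 = min(ny, int((cy + r - cfg.lat_min) / res) + 2)
        if i0 >= i1 or j0 >= j1:
            continue
        dlon = (lons[j0:j1] - cx) * coslat
        dlat = lats[i0:i1] - cy
        inside = (dlat[:, None] ** 2 + dlon[None, :] ** 2) <= r * r
        tgrid[i0:i1, j0:j1][inside] = ptype
        ygrid[i0:i1, j0:j1][inside] = year
        rows.append({"patch_id": pid, "type": "fire" if ptype == FIRE else "harvest",
                     "year": year, "lon": cx, "lat": cy, "radius_deg": r})
    ledger = pd.DataFrame(rows, columns=["patch_id", "type", "year", "lon", "lat", "radius_deg"])
    return tgrid, ygrid, ledger


def _landcover_grid(cfg: LandscapeConfig, baseline: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Class codes from baseline cover, with random excluded-class patches."""
    ny, nx = baseline.shape
    jitter = rng.normal(0.0, 3.0, size=baseline.shape)
    c = baseline + jitter
    lc = np.full((ny, nx), 10, dtype=np.int16)  # non-woody
    lc[c >= 8] = 11  # shrubs
    lc[c >= 15] = 15  # unknown forest
    lc[c >= 22] = 13  # mixed
    lc[c >= 30] = 12  # needleleaf
    # sprinkle broadleaf into the warmer (southern) mixed zone
    broad = (c >= 22) & (c < 35) & (rng.uniform(size=c.shape) < 0.15)
    lc[broad] = 14
    # excluded-class patches (water / wetland) as random disks
    area = (cfg.lon_max - cfg.lon_min) * (cfg.lat_max - cfg.lat_min)
    for code, fraction in ((0, cfg.water_fraction), (3, cfg.wetland_fraction)):
        covered = 0.0
        while covered < fraction * area:
            cy = rng.uniform(0, ny)
            cx = rng.uniform(0, nx)
            r = rng.uniform(2.0, 12.0)  # pixels
            ii = np.arange(max(0, int(cy - r) - 1), min(ny, int(cy + r) + 2))
            jj = np.arange(max(0, int(cx - r) - 1), min(nx, int(cx + r) + 2))
            if ii.size == 0 or jj.size == 0:
                continue
            inside = ((ii[:, None] - cy) ** 2 + (jj[None, :] - cx) ** 2) <= r * r
            block = lc[ii[0]:ii[-1] + 1, jj[0]:jj[-1] + 1]
            block[inside] = code
            covered += inside.sum() * cfg.resolution ** 2
    return lc


def _climate_stacks(cfg: LandscapeConfig, rng: np.random.Generator,
                    ) -> tuple[xr.DataArray, xr.DataArray]:
    res = cfg.climate_resolution
    lons = np.arange(cfg.lon_min + res / 2, cfg.lon_max, res)
    lats = np.arange(cfg.lat_min + res / 2, cfg.lat_max, res)
    years = np.arange(cfg.climate_year_start, cfg.year_end + 1)
    t_axis = (years - cfg.climate_year_start).astype(float)
    mat0 = cfg.mat_at_south_edge + cfg.mat_lapse_per_deg * (lats - cfg.lat_min)
    map0 = cfg.map_at_south_edge + cfg.map_lapse_per_deg * (lats - cfg.lat_min)
    shape = (years.size, lats.size, lons.size)
    mat = (mat0[None, :, None] + cfg.warming_per_year * t_axis[:, None, None]
           + rng.normal(0, cfg.mat_noise_sd, shape))
    mapp = (map0[None, :, None] + cfg.map_trend_per_year * t_axis[:, None, None]
            + rng.normal(0, cfg.map_noise_sd, shape))
    mapp = np.maximum(mapp, 0.0)
    coords = {"year": years, "lat": lats, "lon": lons}
    dims = ("year", "lat", "lon")
    return (xr.DataArray(mat.astype(np.float32), coords=coords, dims=dims, name="mat"),
            xr.DataArray(mapp.astype(np.float32), coords=coords, dims=dims, name="map"))


def generate_landscape(cfg: LandscapeConfig | None = None,
                       seed: int | None = None) -> LandscapeBundle:
    """Generate the full synthetic bundle (rasters + ground truth) for a config.

    ``seed`` overrides ``cfg.seed`` when given.  All stage RNGs are spawned
    from one SeedSequence, so outputs are bit-identical for identical inputs.
    """
    cfg = cfg or LandscapeConfig()
    if seed is not None:
        cfg = LandscapeConfig(**{**cfg.to_dict(), "seed": seed})
    if cfg.lon_max <= cfg.lon_min or cfg.lat_max <= cfg.lat_min or cfg.resolution <= 0:
        raise ValueError("degenerate domain")
    res = cfg.resolution
    lons = np.arange(cfg.lon_min + res / 2, cfg.lon_max, res)
    lats = np.arange(cfg.lat_min + res / 2, cfg.lat_max, res)
    years = cfg.years
    ss = np.random.SeedSequence(cfg.seed)
    rng_field, rng_ar1, rng_dist, rng_lc, rng_clim, rng_elev, rng_trend = (
        np.random.default_rng(s) for s in ss.spawn(7))

    boundaries = make_boundaries(cfg)
    sbd = sbd_grid(cfg, boundaries, lons, lats)
    g_prof = _profile(cfg.trend_profile)
    b_prof = _profile(cfg.baseline_profile)
    g = _eval_profile(g_prof, sbd)
    baseline = _eval_profile(b_prof, sbd)

    coslat = np.cos(np.deg2rad((cfg.lat_min + cfg.lat_max) / 2))
    dy_km = res * KM_PER_DEG
    dx_km = res * KM_PER_DEG * coslat
    field_static = spatial_field(lats.size, lons.size, dy_km, dx_km,
                                 cfg.spatial_range_km, cfg.spatial_sd, rng_field)

    dist_type, dist_year, ledger = _rasterize_patches(cfg, lons, lats, rng_dist)
    dist_term = disturbance_effect(dist_year, dist_type, sbd, years, cfg,
                                   drop_cap=baseline)

    # noise amplitude shrinks toward the 0 % cover floor
    amp = np.clip(baseline / cfg.noise_cover_scale, cfg.noise_amp_floor, 1.0
                  ).astype(np.float32)
    base32 = baseline.astype(np.float32)
    trend_noise = amp * spatial_field(lats.size, lons.size, dy_km, dx_km,
                                      cfg.trend_field_range_km, cfg.trend_field_sd,
                                      rng_trend)
    g32 = (g + trend_noise).astype(np.float32)
    field32 = (field_static * amp).astype(np.float32)

    # AR(1) interannual noise with marginal sd = temporal_sd
    rho, sd = cfg.ar1_rho, cfg.temporal_sd
    shape = (lats.size, lons.size)
    cover = np.empty((years.size,) + shape, dtype=np.float32)
    eps_sd = np.float32(sd * np.sqrt(1 - rho * rho)) if sd > 0 else np.float32(0)
    ar = (sd * rng_ar1.standard_normal(shape, dtype=np.float32)) if sd > 0 \
        else np.zeros(shape, dtype=np.float32)
    t0 = years[0]
    n_clipped = 0
    for k, t in enumerate(years):
        if k > 0 and sd > 0:
            ar = np.float32(rho) * ar + eps_sd * rng_ar1.standard_normal(shape, dtype=np.float32)
        raw = base32 + g32 * np.float32(t - t0) + field32 + ar * amp + dist_term[k]
        np.clip(raw, 0.0, 100.0, out=cover[k])
        n_clipped += int(np.count_nonzero(raw != cover[k]))
    clip_fraction = n_clipped / cover.size

    landcover = _landcover_grid(cfg, baseline, rng_lc)
    mat, mapp = _climate_stacks(cfg, rng_clim)

    lat2 = lats[:, None]
    lon2 = lons[None, :]
    elev = (cfg.elevation_base + cfg.elevation_lapse_per_deg * (lat2 - cfg.lat_min)
            + cfg.elevation_relief * (np.sin(0.8 * lon2) * np.cos(0.6 * lat2))
            + rng_elev.normal(0, 5.0, shape))

    coords2 = {"lat": lats, "lon": lons}
    dims2 = ("lat", "lon")
    truth = GroundTruth(
        sbd=xr.DataArray(sbd, coords=coords2, dims=dims2, name="sbd"),
        true_trend=xr.DataArray(np.asarray(g32, float), coords=coords2, dims=dims2,
                                name="true_trend"),
        disturbances=ledger,
        trend_profile=g_prof,
        baseline_profile=b_prof,
        climate_trend=cfg.warming_per_year,
    )
    return LandscapeBundle(
        cover=xr.DataArray(cover, coords={"year": years, **coords2},
                           dims=("year", "lat", "lon"), name="cover"),
        landcover=xr.DataArray(landcover, coords=coords2, dims=dims2, name="landcover"),
        dist_type=xr.DataArray(dist_type, coords=coords2, dims=dims2, name="dist_type"),
        dist_year=xr.DataArray(dist_year, coords=coords2, dims=dims2, name="dist_year"),
        mat=mat, map_=mapp,
        elevation=xr.DataArray(elev.astype(np.float32), coords=coords2, dims=dims2,
                               name="elevation"),
        boundaries=boundaries,
        truth=truth,
        config=cfg,
        clip_fraction=clip_fraction,
    )
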