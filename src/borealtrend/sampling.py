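"""Transect sampling design over a biome delimited by two boundary polylines.

South-north transects are drawn at random longitudes subject to a minimum
great-circle spacing (informed by the fitted variogram range), tiled with
0.05 degree plots between the boundary crossings plus 20 extension plots
beyond each, and every plot is given a standardised boundary distance (SBD):
-1 at the southern crossing, +1 at the northern crossing, linear in plot
index between them, and +/-0.025 per extension plot out to +/-1.5.

Plot-level aggregation applies the land-cover exclusion rules, the
largest-disturbed-area classification into five disturbance categories, and
attaches climate/elevation covariates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .spatial import EARTH_RADIUS_KM
from .trend_stats import AnnualSeries, estimate_trend

PLOT_CELL_DEG = 0.05
EXTENSION_PLOTS = 20
SBD_STEP = 0.025
SBD_CAP = 1.5

# land-cover class codes; excluded classes sort below retained ones so the
# bincount tie-break (lowest code) errs on the side of exclusion
LANDCOVER_CODES = {
    0: "water", 1: "urban", 2: "cropland", 3: "wetlands", 4: "bare", 5: "snow_ice",
    10: "non_woody", 11: "shrubs", 12: "needleleaf", 13: "mixed",
    14: "broadleaf", 15: "unknown_forest",
}
EXCLUDED_CODES = frozenset({0, 1, 2, 3, 4, 5})
VEGETATION_CLASSES = ("non_woody", "shrubs", "needleleaf", "mixed",
                      "broadleaf", "unknown_forest")

DISTURBANCE_CATEGORIES = (
    "fire_2000_2019", "harvest_2000_2019",
    "fire_1985_1999", "harvest_1985_1999", "undisturbed",
)
FIRE, HARVEST = 1, 2  # codes on the disturbance-type grid (0 = none)


@dataclass
class BiomeBoundaries:
    """Southern and northern biome boundary polylines (lon, lat degrees).

    Latitudes at arbitrary longitudes are linear interpolations of the stored
    vertices; the northern boundary must lie strictly north of the southern
    one at every stored longitude.
    """

    lons: np.ndarray
    south_lats: np.ndarray
    north_lats: np.ndarray

    def __post_init__(self):
        self.lons = np.asarray(self.lons, float)
        self.south_lats = np.asarray(self.south_lats, float)
        self.north_lats = np.asarray(self.north_lats, float)
        if not (self.lons.shape == self.south_lats.shape == self.north_lats.shape):
            raise ValueError("boundary arrays must share shape")
        if np.any(np.diff(self.lons) <= 0):
            raise ValueError("boundary longitudes must be increasing")
        if np.any(self.north_lats <= self.south_lats):
            raise ValueError("northern boundary must be north of southern boundary everywhere")

    def south(self, lon):
        return np.interp(lon, self.lons, self.south_lats)

    def north(self, lon):
        return np.interp(lon, self.lons, self.north_lats)

    @property
    def lon_range(self) -> tuple[float, float]:
        return float(self.lons[0]), float(self.lons[-1])

    def to_geojson(self) -> dict:
        def line(lats, which):
            return {"type": "Feature", "properties": {"boundary": which},
                    "geometry": {"type": "LineString",
                                 "coordinates": [[float(x), float(y)]
                                                 for x, y in zip(self.lons, lats)]}}
        return {"type": "FeatureCollection", "crs": {"type": "name",
                "properties": {"name": "urn:ogc:def:crs:OGC:1.3:CRS84"}},
                "features": [line(self.south_lats, "south"), line(self.north_lats, "north")]}

    @classmethod
    def from_geojson(cls, obj: dict | str) -> "BiomeBoundaries":
        if isinstance(obj, str):
            obj = json.loads(obj)
        lines = {}
        for feat in obj["features"]:
            coords = np.asarray(feat["geometry"]["coordinates"], float)
            lines[feat["properties"]["boundary"]] = coords
        s, n = lines["south"], lines["north"]
        if not np.array_equal(s[:, 0], n[:, 0]):
            raise ValueError("boundary polylines must share longitudes")
        return cls(s[:, 0], s[:, 1], n[:, 1])


@dataclass(frozen=True)
class Transect:
    id: int
    lon: float  # snapped to the 0.05 degree plot lattice


def _snap_to_lattice(x: float, cell: float = PLOT_CELL_DEG) -> float:
    return (np.floor(x / cell) + 0.5) * cell


def draw_transects(boundaries: BiomeBoundaries, min_spacing_km: float, seed: int,
                   n_candidates: int = 4000) -> list[Transect]:
    """Random transect longitudes accepted greedily under a minimum spacing.

    Candidate longitudes are uniform over the boundary domain; a candidate is
    kept when its great-circle distance (evaluated at the mid-domain latitude)
    to every accepted transect is at least ``min_spacing_km``.  Deterministic
    under ``seed``.
    """
    if min_spacing_km <= 0:
        raise ValueError("min_spacing_km must be positive")
    lo, hi = boundaries.lon_range
    if hi <= lo:
        raise ValueError("empty longitudinal domain")
    mid_lat = float(np.mean([boundaries.south((lo + hi) / 2), boundaries.north((lo + hi) / 2)]))
    rng = np.random.default_rng(seed)
    candidates = rng.uniform(lo, hi, size=n_candidates)
    # exact great-circle distance between equal-latitude points
    cosphi = np.cos(np.deg2rad(mid_lat))

    def gc_km(dlon_deg):
        return 2 * EARTH_RADIUS_KM * np.arcsin(cosphi * np.abs(np.sin(np.deg2rad(dlon_deg) / 2)))

    accepted: list[float] = []
    for lon in candidates:
        if not accepted or np.min(gc_km(np.asarray(accepted) - lon)) >= min_spacing_km:
            accepted.append(float(lon))
    if not accepted:  # cannot happen for a nonempty domain, first candidate always fits
        raise RuntimeError("domain too narrow for a single transect")
    accepted.sort()
    return [Transect(i, _snap_to_lattice(lon)) for i, lon in enumerate(accepted)]


def standardize_boundary_distance(row_indices, i_south: int, i_north: int,
                                  step: float = SBD_STEP, cap: float = SBD_CAP) -> np.ndarray:
    """SBD for lattice rows of one transect given the two crossing rows.

    Interior rows (1-indexed i of N, endpoints at the crossings) map to
    -1 + 2(i-1)/(N-1); the k-th extension row beyond a boundary maps to
    +/-(1 + step*k), capped at +/-``cap``.
    """
    rows = np.asarray(row_indices, dtype=int)
    N = i_north - i_south + 1
    if N < 2:
        raise ValueError("need at least 2 interior plots between the crossings")
    sbd = np.empty(rows.shape, float)
    interior = (rows >= i_south) & (rows <= i_north)
    sbd[interior] = -1.0 + 2.0 * (rows[interior] - i_south) / (N - 1)
    south_ext = rows < i_south
    sbd[south_ext] = -(1.0 + step * (i_south - rows[south_ext]))
    north_ext = rows > i_north
    sbd[north_ext] = 1.0 + step * (rows[north_ext] - i_north)
    return np.clip(sbd, -cap, cap)


def build_plots(transect: Transect, boundaries: BiomeBoundaries,
                extension_plots: int = EXTENSION_PLOTS,
                cell: float = PLOT_CELL_DEG) -> pd.DataFrame:
    """Contiguous 0.05 degree plots along the transect, south to north.

    Covers every lattice cell between the boundary crossings (inclusive of the
    cells containing the crossings) plus ``extension_plots`` cells beyond each
    boundary; returns one row per plot with center coordinates and SBD.
    """
    lon_c = _snap_to_lattice(transect.lon, cell)
    s_lat = float(boundaries.south(lon_c))
    n_lat = float(boundaries.north(lon_c))
    i_south = int(np.floor(s_lat / cell))
    i_north = int(np.floor(n_lat / cell))
    if i_north - i_south + 1 < 2:
        raise ValueError("transect does not cross both boundaries with distinct plots")
    rows = np.arange(i_south - extension_plots, i_north + extension_plots + 1)
    sbd = standardize_boundary_distance(rows, i_south, i_north)
    return pd.DataFrame({
        "plot_id": [f"t{transect.id:03d}_p{k:03d}" for k in range(rows.size)],
        "transect_id": transect.id,
        "lon": lon_c,
        "lat": (rows + 0.5) * cell,
        "row": rows,
        "sbd": sbd,
        "interior": (rows >= i_south) & (rows <= i_north),
    })


# ---------------------------------------------------------------------------
# plot-level raster aggregation


def _footprint_slices(da: xr.DataArray, lon: float, lat: float,
                      cell: float = PLOT_CELL_DEG) -> tuple[slice, slice]:
    """Index slices of the half-open plot cell [lon0, lon0+cell) x [lat0, lat0+cell)."""
    lons = da["lon"].values
    lats = da["lat"].values
    lon0, lat0 = lon - cell / 2, lat - cell / 2
    j0, j1 = np.searchsorted(lons, [lon0, lon0 + cell])
    i0, i1 = np.searchsorted(lats, [lat0, lat0 + cell])
    return slice(i0, i1), slice(j0, j1)


def aggregate_plot(cover_stack: xr.DataArray, landcover: xr.DataArray,
                   lon: float, lat: float,
                   cell: float = PLOT_CELL_DEG) -> tuple[AnnualSeries | None, str | None]:
    """Annual cover means over retained pixels, plus the plot's vegetation class.

    The dominant class is the mode of all pixel classes in the footprint; the
    plot is excluded (returns ``(None, None)``) when that mode is one of the
    excluded classes (urban, cropland, wetlands, bare, water, snow/ice) or no
    retained pixel remains.  Otherwise cover is averaged over retained pixels
    only and the class name of the dominant retained type is returned.
    """
    isl, jsl = _footprint_slices(landcover, lon, lat, cell)
    classes = landcover.values[isl, jsl].ravel()
    if classes.size == 0:
        return None, None
    counts = np.bincount(classes.astype(int), minlength=16)
    dominant = int(np.argmax(counts))
    if dominant in EXCLUDED_CODES:
        return None, None
    retained = ~np.isin(classes, list(EXCLUDED_CODES)).reshape(
        landcover.values[isl, jsl].shape)
    if not retained.any():
        return None, None
    isl_c, jsl_c = _footprint_slices(cover_stack.isel(year=0), lon, lat, cell)
    block = cover_stack.values[:, isl_c, jsl_c]
    series = block[:, retained].mean(axis=1)
    years = cover_stack["year"].values.astype(float)
    return AnnualSeries(years, series.astype(float)), LANDCOVER_CODES[dominant]


def classify_disturbance(dist_type: xr.DataArray, dist_year: xr.DataArray,
                         lon: float, lat: float, cell: float = PLOT_CELL_DEG,
                         recent: tuple[int, int] = (2000, 2019),
                         early: tuple[int, int] = (1985, 1999),
                         ) -> tuple[str, int | None, float, float]:
    """Five-way disturbance category from per-pixel type and year grids.

    Any disturbed pixel makes the plot disturbed irrespective of extent; the
    winning type is the one with the larger disturbed-area fraction (ties go
    to fire), the recorded year is the winning type's largest-area event year
    (ties to the earliest), and the category crosses type with the recent /
    early period.  Events before ``early[0]`` count as undisturbed.
    """
    isl, jsl = _footprint_slices(dist_type, lon, lat, cell)
    types = dist_type.values[isl, jsl].ravel()
    years = dist_year.values[isl, jsl].ravel()
    n = types.size
    if n == 0:
        return "undisturbed", None, 0.0, 0.0
    in_window = years >= early[0]
    frac_fire = float(np.mean((types == FIRE) & in_window))
    frac_harv = float(np.mean((types == HARVEST) & in_window))
    if frac_fire == 0.0 and frac_harv == 0.0:
        return "undisturbed", None, 0.0, 0.0
    win_type = FIRE if frac_fire >= frac_harv else HARVEST
    win_years = years[(types == win_type) & in_window]
    vals, counts = np.unique(win_years, return_counts=True)
    year = int(vals[np.argmax(counts)])  # np.unique sorts: ties -> earliest
    period = "2000_2019" if year >= recent[0] else "1985_1999"
    name = "fire" if win_type == FIRE else "harvest"
    return f"{name}_{period}", year, frac_fire, frac_harv


def _nearest_cell_index(stack: xr.DataArray, lon: float, lat: float) -> tuple[int, int]:
    i = int(np.argmin(np.abs(stack["lat"].values - lat)))
    j = int(np.argmin(np.abs(stack["lon"].values - lon)))
    return i, j


def attach_covariates(plots: pd.DataFrame, mat_stack: xr.DataArray,
                      map_stack: xr.DataArray, elevation: xr.DataArray,
                      windows=((1980, 2019), (2000, 2019))) -> pd.DataFrame:
    """Mean annual temperature/precipitation, their trends, and elevation.

    Climate values come from the nearest coarse climate cell to the plot
    center; means and pre-whitened Sen trends are computed per window.
    Elevation is the plot-footprint mean.  Results are cached per climate
    cell, since many plots share one coarse cell.
    """
    out = plots.copy()
    years = mat_stack["year"].values.astype(float)
    cache: dict[tuple[int, int], dict[str, float]] = {}
    cols: dict[str, list] = {}
    for _, row in plots.iterrows():
        key = _nearest_cell_index(mat_stack, row["lon"], row["lat"])
        if key not in cache:
            i, j = key
            t_series = mat_stack.values[:, i, j].astype(float)
            p_series = map_stack.values[:, i, j].astype(float)
            rec = {}
            for (y0, y1) in windows:
                m = (years >= y0) & (years <= y1)
                tag = f"{y0}_{y1}"
                rec[f"mat_{tag}"] = float(t_series[m].mean())
                rec[f"map_{tag}"] = float(p_series[m].mean())
                rec[f"mat_trend_{tag}"] = estimate_trend(years[m], t_series[m]).slope_abs
                rec[f"map_trend_{tag}"] = estimate_trend(years[m], p_series[m]).slope_abs
            cache[key] = rec
        isl, jsl = _footprint_slices(elevation, row["lon"], row["lat"])
        elev_block = elevation.values[isl, jsl]
        rec = dict(cache[key])
        rec["elevation"] = float(np.nanmean(elev_block)) if elev_block.size else np.nan
        for k, v in rec.items():
            cols.setdefault(k, []).append(v)
    for k, v in cols.items():
        out[k] = v
    return out
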