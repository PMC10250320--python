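"""File formats: GeoTIFF rasters, GeoJSON boundaries, CSV tables, bundles.

Rasters are written as GeoTIFFs in geographic WGS84 with explicit nodata:
tifffile handles the TIFF container and the georeferencing is written
directly as the standard GeoTIFF tags (ModelPixelScale, ModelTiepoint, a
minimal GeoKey directory declaring EPSG:4326, and GDAL's nodata tag).
Stacks (cover, climate) are multi-page TIFFs with the year axis recorded in
the image description.  Arrays are stored north-up; in memory, latitude
coordinates are ascending.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import xarray as xr
import yaml

from .landscape import GroundTruth, LandscapeBundle, LandscapeConfig, _profile
from .sampling import BiomeBoundaries

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

# GeoKey directory: version 1.1.0, 3 keys -> geographic model, pixel-is-area,
# geographic CS = EPSG 4326
_GEO_KEYS = (1, 1, 0, 3,
             1024, 0, 1, 2,
             1025, 0, 1, 1,
             2048, 0, 1, 4326)


def _geo_extratags(lon: np.ndarray, lat: np.ndarray, nodata) -> list:
    dlon = float(lon[1] - lon[0]) if lon.size > 1 else 1.0
    dlat = float(lat[1] - lat[0]) if lat.size > 1 else 1.0
    # upper-left corner of the north-up raster (edge, not center)
    ul_lon = float(lon[0] - dlon / 2)
    ul_lat = float(lat[-1] + dlat / 2)
    tags = [
        (_TAG_PIXEL_SCALE, "d", 3, (abs(dlon), abs(dlat), 0.0), True),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, ul_lon, ul_lat, 0.0), True),
        (_TAG_GEO_KEYS, "H", len(_GEO_KEYS), _GEO_KEYS, True),
    ]
    if nodata is not None:
        nd = str(nodata).encode()
        tags.append((_TAG_GDAL_NODATA, "s", len(nd), nd, True))
    return tags


def write_geotiff(path, da: xr.DataArray, nodata: float | None = None) -> None:
    """Write a 2-D (lat, lon) or 3-D (year, lat, lon) DataArray as GeoTIFF.

    NaNs are replaced by ``nodata`` when given.  3-D stacks become multi-page
    files with their year axis in the JSON image description.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lon = da["lon"].values
    lat = da["lat"].values
    data = da.values
    if data.ndim == 2:
        data = data[None, ...]
    # store north-up
    data = data[:, ::-1, :]
    if nodata is not None:
        data = np.where(np.isfinite(data), data, nodata)
    desc = {"dims": list(da.dims)}
    if "year" in da.dims:
        desc["years"] = [int(y) for y in da["year"].values]
    tags = _geo_extratags(lon, lat, nodata)
    with tifffile.TiffWriter(path) as tif:
        for k in range(data.shape[0]):
            tif.write(np.ascontiguousarray(data[k]), extratags=tags,
                      description=json.dumps(desc) if k == 0 else None)


def read_geotiff(path) -> xr.DataArray:
    """Read a GeoTIFF written by :func:`write_geotiff` back into a DataArray."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        pages = tif.pages
        first = pages[0]
        arr = np.stack([p.asarray() for p in pages]) if len(pages) > 1 \
            else first.asarray()[None, ...]
        tags = {t.code: t.value for t in first.tags.values()}
        desc = {}
        if first.description:
            try:
                desc = json.loads(first.description)
            except (json.JSONDecodeError, TypeError):
                desc = {}
    sx, sy, _ = tags[_TAG_PIXEL_SCALE]
    _, _, _, ul_lon, ul_lat, _ = tags[_TAG_TIEPOINT]
    nrow, ncol = arr.shape[-2:]
    lon = ul_lon + sx * (np.arange(ncol) + 0.5)
    lat_desc = ul_lat - sy * (np.arange(nrow) + 0.5)  # north-up rows
    nodata = tags.get(_TAG_GDAL_NODATA)
    data = arr[:, ::-1, :].astype(float) if np.issubdtype(arr.dtype, np.floating) \
        else arr[:, ::-1, :]
    if nodata is not None:
        nd = float(str(nodata).strip("\x00 "))
        if np.issubdtype(data.dtype, np.floating):
            data = np.where(data == nd, np.nan, data)
    lat = lat_desc[::-1]
    if "years" in desc:
        return xr.DataArray(data, coords={"year": np.asarray(desc["years"]),
                                          "lat": lat, "lon": lon},
                            dims=("year", "lat", "lon"))
    return xr.DataArray(data[0], coords={"lat": lat, "lon": lon}, dims=("lat", "lon"))


def write_table(path, df: pd.DataFrame) -> None:
    """UTF-8 CSV with '.' decimal and full float precision (round-trips 1e-9)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from exc


def write_boundaries(path, boundaries: BiomeBoundaries) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(boundaries.to_geojson()))


def read_boundaries(path) -> BiomeBoundaries:
    return BiomeBoundaries.from_geojson(json.loads(Path(path).read_text()))


def write_bundle(bundle: LandscapeBundle, out_dir) -> Path:
    """Write a landscape bundle to the on-disk layout.

    ``cover/YYYY.tif`` per year, single- or multi-page GeoTIFFs for the other
    grids, ``boundaries.geojson``, the disturbance ledger as ``truth.csv``
    plus ground-truth rasters, and the config as ``config.yaml``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for year in bundle.cover["year"].values:
        write_geotiff(out / "cover" / f"{int(year)}.tif",
                      bundle.cover.sel(year=year), nodata=-9999.0)
    write_geotiff(out / "landcover.tif", bundle.landcover)
    write_geotiff(out / "disturbance_type.tif", bundle.dist_type)
    write_geotiff(out / "disturbance_year.tif", bundle.dist_year)
    write_geotiff(out / "mat.tif", bundle.mat, nodata=-9999.0)
    write_geotiff(out / "map.tif", bundle.map_, nodata=-9999.0)
    write_geotiff(out / "elevation.tif", bundle.elevation, nodata=-9999.0)
    write_boundaries(out / "boundaries.geojson", bundle.boundaries)
    write_table(out / "truth.csv", bundle.truth.disturbances)
    write_geotiff(out / "truth_sbd.tif", bundle.truth.sbd, nodata=-9999.0)
    write_geotiff(out / "truth_trend.tif", bundle.truth.true_trend, nodata=-9999.0)
    meta = {"config": bundle.config.to_dict(), "clip_fraction": bundle.clip_fraction}
    (out / "config.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    return out


def read_bundle(in_dir) -> LandscapeBundle:
    """Read a bundle directory written by :func:`write_bundle`."""
    src = Path(in_dir)
    meta = yaml.safe_load((src / "config.yaml").read_text())
    cfg = LandscapeConfig(**{k: tuple(map(tuple, v)) if k.endswith("_profile")
                             else (tuple(v) if isinstance(v, list) else v)
                             for k, v in meta["config"].items()})
    years = sorted(int(p.stem) for p in (src / "cover").glob("*.tif"))
    cover = xr.concat([read_geotiff(src / "cover" / f"{y}.tif") for y in years],
                      dim=pd.Index(years, name="year"))
    truth = GroundTruth(
        sbd=read_geotiff(src / "truth_sbd.tif"),
        true_trend=read_geotiff(src / "truth_trend.tif"),
        disturbances=read_table(src / "truth.csv"),
        trend_profile=_profile(cfg.trend_profile),
        baseline_profile=_profile(cfg.baseline_profile),
        climate_trend=cfg.warming_per_year,
    )
    return LandscapeBundle(
        cover=cover.astype(np.float32),
        landcover=read_geotiff(src / "landcover.tif"),
        dist_type=read_geotiff(src / "disturbance_type.tif"),
        dist_year=read_geotiff(src / "disturbance_year.tif"),
        mat=read_geotiff(src / "mat.tif"),
        map_=read_geotiff(src / "map.tif"),
        elevation=read_geotiff(src / "elevation.tif"),
        boundaries=read_boundaries(src / "boundaries.geojson"),
        truth=truth,
        config=cfg,
        clip_fraction=float(meta.get("clip_fraction", 0.0)),
    )
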