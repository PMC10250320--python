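"""Transect design, SBD, plot aggregation, disturbance classification."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from borealtrend.sampling import (BiomeBoundaries, Transect, aggregate_plot,
                                  attach_covariates, build_plots,
                                  classify_disturbance, draw_transects,
                                  standardize_boundary_distance)
from borealtrend.spatial import great_circle_km


def flat_boundaries(lon0=-110.0, lon1=-100.0, south=54.0, north=58.0):
    lons = np.linspace(lon0, lon1, 11)
    return BiomeBoundaries(lons, np.full(11, south), np.full(11, north))


def grid2d(values, lon0=-110.0, lat0=54.0, res=0.01):
    values = np.asarray(values)
    ny, nx = values.shape
    return xr.DataArray(values,
                        coords={"lat": lat0 + res * (np.arange(ny) + 0.5),
                                "lon": lon0 + res * (np.arange(nx) + 0.5)},
                        dims=("lat", "lon"))


class TestBoundaries:
    def test_geojson_round_trip(self, small_bundle):
        b = small_bundle.boundaries
        back = BiomeBoundaries.from_geojson(b.to_geojson())
        np.testing.assert_allclose(back.south_lats, b.south_lats)
        np.testing.assert_allclose(back.north_lats, b.north_lats)

    def test_inverted_boundaries_rejected(self):
        with pytest.raises(ValueError, match="north"):
            BiomeBoundaries([0, 1], [60.0, 60.0], [55.0, 55.0])


class TestDrawTransects:
    def test_spacing_wider_than_domain_gives_one_transect(self):
        b = flat_boundaries()
        assert len(draw_transects(b, 5000.0, seed=0)) == 1

    def test_pigeonhole_bound_and_min_spacing(self):
        # ~1,000 km wide domain at ~56 N: 16.1 degrees of longitude
        b = flat_boundaries(lon0=-116.1, lon1=-100.0)
        ts = draw_transects(b, 133.0, seed=42)
        assert 1 <= len(ts) <= 8  # floor(1000 / 133) + 1
        mid = 56.0
        for a in ts:
            for c in ts:
                if a.id < c.id:
                    d = great_circle_km(a.lon, mid, c.lon, mid)[0, 0]
                    assert d >= 133.0 * 0.99  # lattice snap may shave < 0.05 deg

    def test_deterministic_under_seed(self):
        b = flat_boundaries()
        assert draw_transects(b, 150.0, seed=9) == draw_transects(b, 150.0, seed=9)

    def test_invalid_spacing_rejected(self):
        with pytest.raises(ValueError):
            draw_transects(flat_boundaries(), -5.0, seed=0)


class TestBuildPlots:
    def test_counts_interior_plus_extensions(self):
        # crossings 10 lattice rows apart -> 10 interior plots
        b = flat_boundaries(south=54.01, north=54.46)
        plots = build_plots(Transect(0, -105.0), b, extension_plots=20)
        assert plots["interior"].sum() == 10
        assert len(plots) == 10 + 40

    def test_extension_zero_gives_interior_only(self):
        b = flat_boundaries(south=54.01, north=54.46)
        plots = build_plots(Transect(0, -105.0), b, extension_plots=0)
        assert len(plots) == 10 and plots["interior"].all()

    def test_extension_span_is_about_111_km(self):
        b = flat_boundaries()
        plots = build_plots(Transect(0, -105.0), b, extension_plots=20)
        ext = plots[~plots["interior"]]
        north_ext = ext[ext["sbd"] > 0]
        span_deg = north_ext["lat"].max() - north_ext["lat"].min() + 0.05
        assert span_deg * 111.195 == pytest.approx(111.2, rel=0.01)

    def test_no_crossing_raises(self):
        b = flat_boundaries(south=54.0, north=54.02)  # same lattice row
        with pytest.raises(ValueError):
            build_plots(Transect(0, -105.0), b)


class TestSBD:
    def test_boundary_plots_map_to_unity(self):
        rows = np.arange(0, 21)
        sbd = standardize_boundary_distance(rows, i_south=0, i_north=20)
        assert sbd[0] == -1.0 and sbd[-1] == 1.0

    def test_midpoint_symmetry(self):
        sbd = standardize_boundary_distance([2], i_south=0, i_north=4)
        assert sbd[0] == 0.0  # i = 3 of N = 5

    def test_twentieth_extension_reaches_cap(self):
        sbd = standardize_boundary_distance([40], i_south=0, i_north=20)
        assert sbd[0] == 1.5  # 1 + 20 * 0.025
        sbd = standardize_boundary_distance([-20], i_south=0, i_north=20)
        assert sbd[0] == -1.5

    def test_strictly_increasing_with_latitude(self, small_bundle):
        ts = draw_transects(small_bundle.boundaries, 200.0, seed=3)
        for t in ts:
            plots = build_plots(t, small_bundle.boundaries)
            assert (plots["lat"].diff().dropna() > 0).all()
            sbd_diff = plots["sbd"].diff().dropna()
            # strictly increasing except at the +/-1.5 cap
            capped = plots["sbd"].abs().eq(1.5)
            assert (sbd_diff[~capped.iloc[1:].to_numpy()] > 0).all()
            assert plots["sbd"].between(-1.5, 1.5).all()

    def test_single_interior_plot_rejected(self):
        with pytest.raises(ValueError):
            standardize_boundary_distance([0], i_south=0, i_north=0)


class TestAggregatePlot:
    def cover_stack(self, pixel_values, years=3):
        base = grid2d(pixel_values)
        return xr.concat([base] * years, dim=pd.Index(range(2000, 2000 + years),
                                                      name="year"))

    def test_uniform_cover(self):
        cover = self.cover_stack(np.full((5, 5), 37.0))
        lc = grid2d(np.full((5, 5), 12))
        series, veg = aggregate_plot(cover, lc, -109.975, 54.025)
        assert veg == "needleleaf"
        np.testing.assert_allclose(series.values, 37.0)

    def test_water_dominant_plot_excluded(self):
        cover = self.cover_stack(np.full((5, 5), 40.0))
        codes = np.full((5, 5), 0)  # water everywhere
        codes[0, 0] = 12
        series, veg = aggregate_plot(cover, grid2d(codes), -109.975, 54.025)
        assert series is None and veg is None

    def test_mean_over_retained_pixels_only(self):
        vals = np.full((1, 3), np.nan)
        vals[0] = [40.0, 60.0, 80.0]
        cover = self.cover_stack(vals)
        codes = np.array([[12, 12, 0]])  # third pixel is water
        series, veg = aggregate_plot(cover, grid2d(codes), -109.975, 54.005)
        np.testing.assert_allclose(series.values, 50.0)
        assert veg == "needleleaf"


class TestClassifyDisturbance:
    # 10 x 10 grid at 0.005 degrees spans exactly one 0.05-degree plot
    CENTER = (-109.975, 54.025)

    def make_grids(self, types, years):
        return (grid2d(np.asarray(types), res=0.005),
                grid2d(np.asarray(years), res=0.005))

    def test_largest_area_wins_even_if_older(self):
        # fire on 10 % of pixels (2005) vs harvest on 30 % (1998)
        types = np.zeros((10, 10), dtype=int)
        years = np.zeros((10, 10), dtype=int)
        types[:1, :], years[:1, :] = 1, 2005  # 10 pixels fire
        types[1:4, :], years[1:4, :] = 2, 1998  # 30 pixels harvest
        tg, yg = self.make_grids(types, years)
        cat, year, f_fire, f_harv = classify_disturbance(tg, yg, *self.CENTER)
        assert cat == "harvest_1985_1999"
        assert year == 1998
        assert (f_fire, f_harv) == (0.1, 0.3)

    def test_untouched_plot_is_undisturbed(self):
        tg, yg = self.make_grids(np.zeros((10, 10), int), np.zeros((10, 10), int))
        cat, year, f_fire, f_harv = classify_disturbance(tg, yg, *self.CENTER)
        assert cat == "undisturbed" and year is None
        assert f_fire == 0.0 and f_harv == 0.0

    def test_any_sign_rule_one_percent_fire(self):
        types = np.zeros((10, 10), dtype=int)
        years = np.zeros((10, 10), dtype=int)
        types[0, 0], years[0, 0] = 1, 2010
        tg, yg = self.make_grids(types, years)
        cat, year, f_fire, _ = classify_disturbance(tg, yg, *self.CENTER)
        assert cat == "fire_2000_2019" and year == 2010
        assert f_fire == pytest.approx(0.01)

    def test_all_five_categories_reachable(self):
        cases = [
            (1, 2010, "fire_2000_2019"), (2, 2005, "harvest_2000_2019"),
            (1, 1990, "fire_1985_1999"), (2, 1999, "harvest_1985_1999"),
        ]
        for code, yr, expected in cases:
            types = np.full((10, 10), code)
            years = np.full((10, 10), yr)
            tg, yg = self.make_grids(types, years)
            cat, _, _, _ = classify_disturbance(tg, yg, *self.CENTER)
            assert cat == expected

    def test_tie_goes_to_fire(self):
        types = np.zeros((10, 10), dtype=int)
        years = np.zeros((10, 10), dtype=int)
        types[0, :], years[0, :] = 1, 2004
        types[1, :], years[1, :] = 2, 2006
        tg, yg = self.make_grids(types, years)
        cat, year, _, _ = classify_disturbance(tg, yg, *self.CENTER)
        assert cat.startswith("fire") and year == 2004


class TestCovariates:
    def climate_stack(self, values):
        years = np.arange(1980, 2020)
        arr = np.broadcast_to(np.asarray(values)[:, None, None],
                              (40, 3, 3)).astype(float)
        return xr.DataArray(arr, coords={"year": years,
                                         "lat": [54.0, 55.0, 56.0],
                                         "lon": [-106.0, -105.0, -104.0]},
                            dims=("year", "lat", "lon"))

    def test_uniform_temperature(self):
        plots = pd.DataFrame({"lon": [-105.0], "lat": [55.0]})
        mat = self.climate_stack(np.full(40, 2.0))
        mapp = self.climate_stack(np.zeros(40))
        elev = grid2d(np.full((300, 300), 100.0), lon0=-107.0, lat0=53.0)
        out = attach_covariates(plots, mat, mapp, elev)
        assert out.loc[0, "mat_1980_2019"] == pytest.approx(2.0)
        assert out.loc[0, "map_1980_2019"] == 0.0
        assert out.loc[0, "map_trend_1980_2019"] == 0.0
        assert out.loc[0, "elevation"] == pytest.approx(100.0)

    def test_exact_warming_ramp_recovered(self):
        ramp = 2.0 + 0.04 * np.arange(40)
        plots = pd.DataFrame({"lon": [-105.0], "lat": [55.0]})
        mat = self.climate_stack(ramp)
        mapp = self.climate_stack(np.full(40, 500.0))
        elev = grid2d(np.full((300, 300), 0.0), lon0=-107.0, lat0=53.0)
        out = attach_covariates(plots, mat, mapp, elev)
        assert out.loc[0, "mat_trend_1980_2019"] == pytest.approx(0.04)
        assert out.loc[0, "mat_trend_2000_2019"] == pytest.approx(0.04)
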