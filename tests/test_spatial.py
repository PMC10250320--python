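"""Variograms, model fits and correlation-structure selection."""

import numpy as np
import pandas as pd
import pytest

from borealtrend.landscape import spatial_field
from borealtrend.spatial import (EmpiricalVariogram, detrend_surface,
                                 empirical_variogram, fit_variogram_model,
                                 great_circle_km, sample_random_points,
                                 select_correlation_structure, variogram_model)


def grid_points(n_side, spacing_deg, lat0=55.0, lon0=-110.0, values=None, rng=None):
    lon, lat = np.meshgrid(lon0 + spacing_deg * np.arange(n_side),
                           lat0 + spacing_deg * np.arange(n_side))
    vals = values.ravel() if values is not None else rng.normal(size=lon.size)
    return pd.DataFrame({"lon": lon.ravel(), "lat": lat.ravel(), "value": vals})


class TestEmpiricalVariogram:
    def test_constant_field_has_zero_semivariance(self, rng):
        pts = grid_points(10, 0.1, values=np.full((10, 10), 3.0))
        vg = empirical_variogram(pts, lag_width_km=10, max_lag_km=100)
        assert np.all(vg.semivariances[vg.pair_counts > 0] == 0)

    def test_single_pair(self):
        pts = pd.DataFrame({"lon": [-100.0, -100.0], "lat": [55.0, 55.05],
                            "value": [0.0, 2.0]})
        vg = empirical_variogram(pts, lag_width_km=10, max_lag_km=20)
        populated = vg.pair_counts > 0
        assert populated.sum() == 1
        assert vg.semivariances[populated][0] == pytest.approx(2.0)  # (2-0)^2 / 2

    def test_white_noise_is_flat_at_sigma2(self, rng):
        pts = grid_points(40, 0.05, rng=rng)  # unit-variance white noise
        vg = empirical_variogram(pts, lag_width_km=15, max_lag_km=120)
        dense = vg.pair_counts >= 500
        assert dense.sum() >= 4
        np.testing.assert_allclose(vg.semivariances[dense], 1.0, rtol=0.10)

    def test_invariant_under_point_permutation(self, rng):
        pts = grid_points(12, 0.1, rng=rng)
        shuffled = pts.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = empirical_variogram(pts, 20, 200)
        b = empirical_variogram(shuffled, 20, 200)
        np.testing.assert_array_equal(a.pair_counts, b.pair_counts)
        np.testing.assert_allclose(a.semivariances, b.semivariances, equal_nan=True)

    def test_empty_bins_reported_missing(self):
        pts = pd.DataFrame({"lon": [-100.0, -100.0], "lat": [55.0, 55.05],
                            "value": [0.0, 1.0]})
        vg = empirical_variogram(pts, lag_width_km=2, max_lag_km=20)
        empty = vg.pair_counts == 0
        assert empty.any() and np.isnan(vg.semivariances[empty]).all()


class TestVariogramFit:
    def test_noiseless_exponential_inversion(self):
        h = np.arange(12.5, 500, 25.0)
        gamma = 0.01 + 0.15 * (1 - np.exp(-h / 44.0))
        vg = EmpiricalVariogram(h, gamma, np.full(h.size, 1000))
        fit = fit_variogram_model(vg, "exponential")
        assert fit.nugget == pytest.approx(0.01, abs=1e-4)
        assert fit.partial_sill == pytest.approx(0.15, abs=1e-3)
        assert fit.range_param == pytest.approx(44.0, rel=1e-2)
        assert fit.practical_range == pytest.approx(132.0, rel=1e-2)

    def test_pure_nugget_not_identifiable(self, rng):
        h = np.arange(12.5, 500, 25.0)
        gamma = np.full(h.size, 0.2) + rng.normal(0, 1e-4, h.size)
        vg = EmpiricalVariogram(h, gamma, np.full(h.size, 1000))
        fit = fit_variogram_model(vg, "exponential")
        assert not fit.identifiable and np.isnan(fit.practical_range)

    def test_nugget_only_model(self):
        h = np.arange(12.5, 200, 25.0)
        vg = EmpiricalVariogram(h, np.full(h.size, 0.3), np.full(h.size, 100))
        fit = fit_variogram_model(vg, "nugget")
        assert fit.nugget == pytest.approx(0.3)
        assert not fit.identifiable

    @pytest.mark.parametrize("model", ["exponential", "gaussian", "spherical"])
    def test_fitted_curves_monotone(self, model):
        h = np.linspace(0, 300, 301)
        curve = variogram_model(model)(h, 0.05, 0.2, 60.0)
        assert np.all(np.diff(curve) >= -1e-12)
        assert np.all(curve >= 0)

    def test_practical_range_conventions(self):
        # 95 %-of-sill distance per model family
        assert variogram_model("exponential")(3 * 50.0, 0.0, 1.0, 50.0) == pytest.approx(0.95, abs=0.01)
        assert variogram_model("gaussian")(np.sqrt(3) * 50.0, 0.0, 1.0, 50.0) == pytest.approx(0.95, abs=0.01)
        assert variogram_model("spherical")(50.0, 0.0, 1.0, 50.0) == pytest.approx(1.0)


class TestGaussianField:
    def test_zero_sd_gives_zero_field(self, rng):
        f = spatial_field(20, 30, 2.0, 2.0, 90.0, 0.0, rng)
        assert not f.any()

    def test_marginal_variance(self):
        rng = np.random.default_rng(99)
        f = spatial_field(256, 256, 4.0, 4.0, 60.0, 2.0, rng)
        assert f.std() == pytest.approx(2.0, rel=0.10)

    def test_variogram_recovers_practical_range(self):
        rng = np.random.default_rng(4)
        # 2 km pixels, 90 km practical range
        f = spatial_field(220, 220, 2.0, 2.0, 90.0, 1.0, rng)
        lat = 55.0 + (2.0 / 111.195) * np.arange(220)
        lon = -110.0 + (2.0 / (111.195 * np.cos(np.deg2rad(55)))) * np.arange(220)
        lon2, lat2 = np.meshgrid(lon, lat)
        pick = np.random.default_rng(5).choice(lon2.size, 2500, replace=False)
        pts = pd.DataFrame({"lon": lon2.ravel()[pick], "lat": lat2.ravel()[pick],
                            "value": f.ravel()[pick]})
        fit = fit_variogram_model(empirical_variogram(pts, 10, 200), "exponential")
        assert fit.practical_range == pytest.approx(90.0, rel=0.30)
        # sill consistency: nugget + partial sill matches the field variance
        assert fit.sill == pytest.approx(float(f.var()), rel=0.15)


class TestSamplePoints:
    def test_zero_points(self, small_bundle):
        import xarray as xr
        field = small_bundle.truth.true_trend
        assert len(sample_random_points(field, 0, seed=1)) == 0

    def test_deterministic_under_seed(self, small_bundle):
        field = small_bundle.truth.true_trend
        a = sample_random_points(field, 200, seed=3)
        b = sample_random_points(field, 200, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_sample_mean_consistent_with_field_mean(self, small_bundle):
        field = small_bundle.truth.true_trend
        pts = sample_random_points(field, 10_000, seed=11)
        se = float(field.std()) / np.sqrt(len(pts))
        assert abs(pts["value"].mean() - float(field.mean())) < 3 * se

    def test_oversampling_raises(self):
        import xarray as xr
        da = xr.DataArray(np.ones((3, 3)), coords={"lat": [1, 2, 3], "lon": [1, 2, 3]},
                          dims=("lat", "lon"))
        with pytest.raises(ValueError):
            sample_random_points(da, 10, seed=0)


class TestStructureSelection:
    def test_single_candidate_returned(self, rng):
        pts = grid_points(8, 0.2, rng=rng)
        assert select_correlation_structure(pts, candidates=("spherical",)) == "spherical"

    def test_iid_noise_prefers_no_structure(self):
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(1000 + seed)
            pts = grid_points(9, 0.3, rng=rng)
            if select_correlation_structure(pts) == "none":
                wins += 1
        assert wins >= 3

    def test_exponential_field_detected(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(2000 + seed)
            f = spatial_field(30, 30, 10.0, 10.0, 120.0, 1.0, rng)
            f = f + rng.normal(0, 0.3, f.shape)  # nugget
            pick = rng.choice(f.size, 150, replace=False)
            lat = 55.0 + (10.0 / 111.195) * np.arange(30)
            lon = -110.0 + (10.0 / (111.195 * np.cos(np.deg2rad(55)))) * np.arange(30)
            lon2, lat2 = np.meshgrid(lon, lat)
            pts = pd.DataFrame({"lon": lon2.ravel()[pick], "lat": lat2.ravel()[pick],
                                "value": f.ravel()[pick]})
            if select_correlation_structure(pts) != "none":
                hits += 1
        assert hits >= 4


class TestDetrend:
    def test_removes_polynomial_surface(self, rng):
        pts = grid_points(15, 0.2, rng=rng)
        x = pts["lon"] - pts["lon"].mean()
        y = pts["lat"] - pts["lat"].mean()
        pts["value"] = 2.0 + 3.0 * x + 0.5 * y * y
        out = detrend_surface(pts, order=2)
        assert np.abs(out["value"]).max() < 1e-8

    def test_order_zero_is_identity(self, rng):
        pts = grid_points(5, 0.2, rng=rng)
        out = detrend_surface(pts, order=0)
        pd.testing.assert_frame_equal(out, pts)


def test_great_circle_matches_known_distance():
    # one degree of latitude is ~111.2 km
    d = great_circle_km(-100.0, 55.0, -100.0, 56.0)[0, 0]
    assert d == pytest.approx(111.2, rel=0.01)
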