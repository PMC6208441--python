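"""RTLSR kernels, window inversion, and rolling BAR NDVI."""

import numpy as np
import pandas as pd
import pytest

from gramirice import brdf
from gramirice.synth import (
    SceneConfig,
    _paddy_curve,
    geostationary_schedule,
    synth_angular_observations,
)


def _reference_ross_thick(sza, vza, raa):
    """Independent transcription of the published volumetric kernel."""
    ts, tv, phi = np.radians([sza, vza, raa])
    xi = np.arccos(np.cos(ts) * np.cos(tv) + np.sin(ts) * np.sin(tv) * np.cos(phi))
    return ((np.pi / 2 - xi) * np.cos(xi) + np.sin(xi)) / (np.cos(ts) + np.cos(tv)) - np.pi / 4


class TestKernels:
    def test_ross_thick_vanishes_at_double_nadir(self):
        for raa in (0.0, 45.0, 180.0):
            assert brdf.ross_thick_kernel(0.0, 0.0, raa) == pytest.approx(0.0, abs=1e-12)

    def test_li_sparse_nadir_closed_form(self):
        # at nadir both primed angles are 0: O = t/pi*2 with cos t = 0 -> O = 1,
        # k = 1 - 1 - 1 + 0.5*(1+1)*1*1 = 0
        assert brdf.li_sparse_reciprocal_kernel(0.0, 0.0, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_ross_thick_matches_independent_transcription(self):
        assert brdf.ross_thick_kernel(45.0, 45.0, 90.0) == pytest.approx(
            _reference_ross_thick(45.0, 45.0, 90.0), abs=1e-12
        )

    def test_reciprocity_on_random_angles(self):
        rng = np.random.default_rng(42)
        sza = rng.uniform(0, 80, 100)
        vza = rng.uniform(0, 80, 100)
        raa = rng.uniform(0, 360, 100)
        for kern in (brdf.ross_thick_kernel, brdf.li_sparse_reciprocal_kernel):
            np.testing.assert_allclose(kern(sza, vza, raa), kern(vza, sza, raa), atol=1e-12)

    def test_li_sparse_overlap_clamped_finite(self):
        # extreme grazing geometry drives the overlap argument past 1
        val = brdf.li_sparse_reciprocal_kernel(80.0, 80.0, 180.0)
        assert np.isfinite(val)

    def test_angle_domain_errors(self):
        with pytest.raises(ValueError):
            brdf.ross_thick_kernel(95.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            brdf.li_sparse_reciprocal_kernel(0.0, 90.0, 0.0)


class TestInversion:
    def test_noiseless_round_trip(self, true_kernel_params, window_schedule):
        obs = synth_angular_observations(true_kernel_params, window_schedule, noise_sd=0.0)
        for band in ("red", "nir"):
            fit = brdf.fit_kernel_params(obs, band)
            truth = true_kernel_params[band]
            assert fit.quality_flag == "full"
            assert fit.f_iso == pytest.approx(truth.f_iso, abs=1e-8)
            assert fit.f_geo == pytest.approx(truth.f_geo, abs=1e-8)
            assert fit.f_vol == pytest.approx(truth.f_vol, abs=1e-8)

    def test_ols_matches_normal_equation_oracle(self, true_kernel_params, window_schedule):
        obs = synth_angular_observations(true_kernel_params, window_schedule, noise_sd=0.01, seed=5)
        fit = brdf.fit_kernel_params(obs, "red")
        X = np.column_stack(
            [
                np.ones(len(obs)),
                brdf.li_sparse_reciprocal_kernel(obs["sza"], obs["vza"], obs["raa"]),
                brdf.ross_thick_kernel(obs["sza"], obs["vza"], obs["raa"]),
            ]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ obs["red"].to_numpy())
        np.testing.assert_allclose([fit.f_iso, fit.f_geo, fit.f_vol], beta, atol=1e-10)

    def test_identical_geometry_is_rank_deficient(self):
        obs = pd.DataFrame(
            {"doy": np.arange(10), "sza": 40.0, "vza": 40.0, "raa": 90.0, "red": 0.2, "nir": 0.4}
        )
        assert brdf.fit_kernel_params(obs, "red").quality_flag == "failed"

    def test_single_sample_refused(self, true_kernel_params, window_schedule):
        obs = synth_angular_observations(true_kernel_params, window_schedule.iloc[:1], 0.0)
        assert brdf.fit_kernel_params(obs, "red").quality_flag == "failed"

    def test_low_count_flagged_fill(self, true_kernel_params, window_schedule):
        obs = synth_angular_observations(true_kernel_params, window_schedule.iloc[::30], 0.0)
        fit = brdf.fit_kernel_params(obs, "red")
        assert 3 <= fit.n_obs < 7
        assert fit.quality_flag == "fill"

    def test_noise_error_shrinks_with_more_observations(self, true_kernel_params):
        sched_small = geostationary_schedule(doys=np.arange(180, 184))
        sched_big = geostationary_schedule(doys=np.arange(172, 204))
        truth = np.array([0.20, 0.02, 0.10])

        def rmse(sched):
            errs = []
            for seed in range(30):
                obs = synth_angular_observations(true_kernel_params, sched, 0.01, seed=seed)
                f = brdf.fit_kernel_params(obs, "red")
                errs.append((np.array([f.f_iso, f.f_geo, f.f_vol]) - truth) ** 2)
            return np.sqrt(np.mean(errs))

        assert rmse(sched_big) < rmse(sched_small)


class TestBar:
    def test_isotropic_surface_returns_f_iso(self):
        p = brdf.KernelParams(0.3, 0.0, 0.0, "red")
        for geom in ((0, 0, 0), (40, 100, 45), (70, 120, 10)):
            assert brdf.bar_reflectance(p, *geom) == pytest.approx(0.3, abs=1e-12)

    def test_fixed_view_differs_from_nadir_convention(self, true_kernel_params):
        p = true_kernel_params["red"]
        fixed_view = brdf.bar_reflectance(p, fixed_vza=40.0, fixed_raa=100.0, mean_sza=45.0)
        nadir = brdf.bar_reflectance(p, fixed_vza=0.0, fixed_raa=0.0, mean_sza=45.0)
        assert fixed_view != pytest.approx(nadir, abs=1e-6)

    def test_bar_round_trip_at_evaluation_geometry(self, true_kernel_params, window_schedule):
        obs = synth_angular_observations(true_kernel_params, window_schedule, 0.0)
        fit = brdf.fit_kernel_params(obs, "nir")
        row = obs.iloc[10]
        forward = row["nir"]
        assert brdf.bar_reflectance(
            fit, fixed_vza=row["vza"], fixed_raa=row["raa"], mean_sza=row["sza"]
        ) == pytest.approx(forward, abs=1e-10)

    def test_failed_params_give_nan(self):
        p = brdf.KernelParams(np.nan, np.nan, np.nan, "red", quality_flag="failed")
        assert np.isnan(brdf.bar_reflectance(p, 40, 100, 45))


class TestNdvi:
    @pytest.mark.parametrize(
        "red,nir,expected", [(0.05, 0.05, 0.0), (0.05, 0.45, 0.8), (0.45, 0.05, -0.8)]
    )
    def test_arithmetic(self, red, nir, expected):
        assert brdf.compute_ndvi(red, nir) == pytest.approx(expected)

    def test_zero_sum_is_missing(self):
        assert np.isnan(brdf.compute_ndvi(0.0, 0.0))


def _ndvi_observations(config, doys):
    """Angular observations of an isotropic surface tracking a phenology curve.

    Band depths are linear in the curve with a constant red+nir sum, so the
    surface's instantaneous NDVI is the (scaled) generating curve itself:
    NDVI(t) = curve(t) / 1.2.
    """
    sched = geostationary_schedule(doys=doys)
    curve = _paddy_curve(sched["doy"].to_numpy(), config)
    obs = sched.copy()
    obs["red"] = 0.05 + 0.25 * (1.0 - curve)
    obs["nir"] = 0.05 + 0.25 * (1.0 + curve)
    return obs


def _ndvi_truth(doys, config):
    """The generating surface's instantaneous NDVI at the given days."""
    return _paddy_curve(np.asarray(doys, dtype=float), config) / 1.2


class TestRollingBar:
    def test_tracks_generating_phenology(self):
        cfg = SceneConfig(noise_sd=0.0, cloud_gap_prob=0.0)
        obs = _ndvi_observations(cfg, np.arange(100, 300))
        series = brdf.rolling_bar_ndvi(obs)
        truth = _ndvi_truth(series["doy"].to_numpy(), cfg)
        ok = series["quality"] == "full"
        assert ok.mean() > 0.9
        assert np.nanmax(np.abs(series.loc[ok, "ndvi"].to_numpy() - truth[ok])) < 0.01

    def test_gap_days_fill_flagged(self):
        cfg = SceneConfig(noise_sd=0.0, cloud_gap_prob=0.0)
        doys = np.concatenate([np.arange(100, 180), np.arange(200, 260)])
        obs = _ndvi_observations(cfg, doys)
        series = brdf.rolling_bar_ndvi(obs)
        inside = series[(series["doy"] >= 189) & (series["doy"] <= 191)]
        outside = series[(series["doy"] >= 150) & (series["doy"] <= 170)]
        assert (inside["quality"] == "fill").all()
        assert (outside["quality"] == "full").all()

    def test_translation_equivariance(self):
        cfg = SceneConfig(noise_sd=0.0, cloud_gap_prob=0.0)
        obs = _ndvi_observations(cfg, np.arange(150, 200))
        shifted = obs.assign(doy=obs["doy"] + 1)
        a = brdf.rolling_bar_ndvi(obs)
        b = brdf.rolling_bar_ndvi(shifted)
        np.testing.assert_allclose(a["doy"].to_numpy() + 1, b["doy"].to_numpy())
        np.testing.assert_allclose(a["ndvi"].to_numpy(), b["ndvi"].to_numpy(), atol=1e-12)

    def test_empty_input(self):
        out = brdf.rolling_bar_ndvi(pd.DataFrame(columns=["doy", "sza", "vza", "raa", "red", "nir"]))
        assert out.empty

    def test_isotropic_surface_constant_series(self):
        sched = geostationary_schedule(doys=np.arange(120, 170))
        obs = sched.assign(red=0.1, nir=0.4)
        series = brdf.rolling_bar_ndvi(obs)
        full = series[series["quality"] == "full"]
        np.testing.assert_allclose(full["ndvi"].to_numpy(), 0.6, atol=1e-9)
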