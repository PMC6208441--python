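"""Synthetic scene generation for every pipeline input.

The generators emulate the observing conditions of a geostationary optical
sensor over a monsoon rice region: a double-logistic paddy NDVI season
(transplanting ~DOY 140 on flooded fields, mid-season peak, harvest ~DOY 270)
with Bernoulli cloud gaps and an optional contiguous monsoon block;
multi-angle reflectance forward-modelled from known RTLSR kernel weights over
the diurnal sun sweep at a fixed view angle; hourly clear/cloudy insolation;
sinusoidal Tmax/Tmin weather with summer-peaking cloudiness; and a labelled
landscape where paddies occupy low-elevation, low-slope, high-wetness cells.

Every generator is a pure function of (config, seed): one global seed expands
to per-pixel substreams through numpy's SeedSequence-style list seeding, so
grids are reproducible independently of pixel processing order. True
generating parameters are returned in a TruthRecord for parameter-recovery
tests; pipeline stages never read it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import solar
from .brdf import KernelParams, li_sparse_reciprocal_kernel, ross_thick_kernel
from .classify import terrain_variables
from .grami import CropConstants, GramiParams, VICalibration, simulate_season, vi_from_lai
from .insolation import AtmosState, clear_sky_components

__all__ = [
    "SceneConfig",
    "TruthRecord",
    "SyntheticScene",
    "synth_ndvi_series",
    "synth_angular_observations",
    "geostationary_schedule",
    "synth_weather",
    "synth_landscape",
    "synth_vi_observations",
]


@dataclass(frozen=True)
class SceneConfig:
    grid_rows: int = 50
    grid_cols: int = 50
    paddy_fraction: float = 0.3
    transplant_doy: int = 140
    harvest_doy: int = 270
    peak_ndvi: float = 0.85
    base_ndvi: float = 0.10
    cloud_gap_prob: float = 0.3
    noise_sd: float = 0.03
    seed: int = 7

    def __post_init__(self):
        if not (0.0 <= self.base_ndvi < self.peak_ndvi <= 1.0):
            raise ValueError("require 0 <= base_ndvi < peak_ndvi <= 1")
        if self.transplant_doy >= self.harvest_doy:
            raise ValueError("transplant_doy must precede harvest_doy")
        if not (0.0 <= self.paddy_fraction <= 1.0 and 0.0 <= self.cloud_gap_prob <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")


@dataclass
class TruthRecord:
    """Generating truth, stored beside the data; read only by tests."""

    kernel_params_true: dict | None = None
    grami_params_true: GramiParams | None = None
    labels_true: np.ndarray | None = None
    yield_true: np.ndarray | None = None

    def to_json(self) -> str:
        payload = {}
        if self.kernel_params_true is not None:
            payload["kernel_params_true"] = {
                b: asdict(p) if isinstance(p, KernelParams) else p
                for b, p in self.kernel_params_true.items()
            }
        if self.grami_params_true is not None:
            payload["grami_params_true"] = asdict(self.grami_params_true)
        if self.labels_true is not None:
            payload["labels_true"] = self.labels_true.tolist()
        if self.yield_true is not None:
            payload["yield_true"] = np.asarray(self.yield_true).tolist()
        return json.dumps(payload)


def _rng(seed: int, *stream: int) -> np.random.Generator:
    """Counter-based substream: the same (seed, stream) always yields the same RNG."""
    return np.random.default_rng([int(seed)] + [int(s) for s in stream])


# ---------------------------------------------------------------------------
# NDVI phenology


def _double_logistic(t, base, peak, t1, t2, r1=0.12, r2=0.12):
    """Amplitude-normalised double logistic: the annual daily maximum equals `peak` exactly.

    The normalising maximum is taken over the full year so the curve is a
    fixed function of DOY, independent of which days it is evaluated on.
    """

    def g(x):
        return 1.0 / (1.0 + np.exp(-r1 * (x - t1))) - 1.0 / (1.0 + np.exp(-r2 * (x - t2)))

    gmax = g(np.arange(1.0, 366.0)).max()
    if gmax <= 0:
        return np.full_like(np.asarray(t, dtype=float), base)
    return base + (peak - base) * g(np.asarray(t, dtype=float)) / gmax


def _paddy_curve(doys, config: SceneConfig, peak=None):
    peak = config.peak_ndvi if peak is None else peak
    return _double_logistic(
        doys, config.base_ndvi, peak, config.transplant_doy + 25, config.harvest_doy - 20
    )


def _nonpaddy_curve(doys, config: SceneConfig, peak=0.65):
    """Upland vegetation: green by May, partially senesced before rice harvest."""
    return _double_logistic(doys, 0.30, peak, 105.0, config.harvest_doy - 45, r1=0.08, r2=0.06)


def _crop_curve(doys, rng):
    """Upland rainfed crop: near-paddy summer season but never flooded.

    Seasonality (green-up/senescence dates, rates, peak) is drawn from the
    same monsoon growing season as rice, so phenology-shape descriptors carry
    little class information by construction; what distinguishes it from
    paddy is the un-flooded spring surface (higher base NDVI around
    transplanting) and, upstream, where on the terrain it occurs.
    """
    return _double_logistic(
        doys,
        0.22 + rng.normal(0, 0.03),
        0.85 + rng.normal(0, 0.06),
        160.0 + rng.normal(0, 10.0),
        248.0 + rng.normal(0, 10.0),
        r1=0.11 + rng.normal(0, 0.02),
        r2=0.12 + rng.normal(0, 0.02),
    )


def _broadleaf_curve(doys, rng):
    """Hillside grassland/shrub: paddy-like summer season on an un-flooded surface."""
    return _double_logistic(
        doys,
        0.28 + rng.normal(0, 0.03),
        0.85 + rng.normal(0, 0.05),
        162.0 + rng.normal(0, 9.0),
        252.0 + rng.normal(0, 9.0),
        r1=0.12 + rng.normal(0, 0.02),
        r2=0.12 + rng.normal(0, 0.02),
    )


def _paddy_pixel_curve(doys, config, rng):
    """Rice paddy with per-pixel jitter of transplanting/harvest and peak.

    Around transplanting the field is flooded, so NDVI dips toward the
    water signal — the contrast the paddy classification index is built on.
    """
    t_transplant = config.transplant_doy + rng.normal(0, 4.0)
    curve = _double_logistic(
        doys,
        config.base_ndvi + rng.normal(0, 0.02),
        config.peak_ndvi + rng.normal(0, 0.05),
        t_transplant + 25.0,
        config.harvest_doy - 20 + rng.normal(0, 5.0),
        r1=0.12,
        r2=0.12,
    )
    flood_dip = (0.10 + rng.normal(0, 0.02)) * np.exp(
        -0.5 * ((np.asarray(doys, dtype=float) - t_transplant) / 10.0) ** 2
    )
    return curve - flood_dip


def synth_ndvi_series(
    config: SceneConfig,
    pixel_kind: str = "paddy",
    pixel_id: int = 0,
    monsoon_block: bool = False,
    doys=None,
) -> pd.DataFrame:
    """Daily NDVI series with cloud gaps and Gaussian noise for one pixel.

    Paddy pixels follow the rice double-logistic; non-paddy a broadleaf-like
    curve. Observations are removed independently with cloud_gap_prob; the
    monsoon_block option additionally removes a contiguous 20-day window
    centred mid-season (the failure mode that motivates gap-tolerant
    calibration). Returns DataFrame(doy, ndvi); empty when every day is lost.
    """
    if doys is None:
        doys = np.arange(1, 366, dtype=float)
    else:
        doys = np.asarray(doys, dtype=float)
    if pixel_kind == "paddy":
        curve = _paddy_curve(doys, config)
    elif pixel_kind == "nonpaddy":
        curve = _nonpaddy_curve(doys, config)
    else:
        raise ValueError(f"unknown pixel_kind {pixel_kind!r}")
    rng = _rng(config.seed, 101, pixel_id)
    ndvi = curve + rng.normal(0.0, config.noise_sd, size=doys.shape)
    keep = rng.random(doys.shape) >= config.cloud_gap_prob
    if monsoon_block:
        mid = 0.5 * (config.transplant_doy + config.harvest_doy)
        keep &= ~((doys >= mid - 10) & (doys < mid + 10))
    return pd.DataFrame({"doy": doys[keep], "ndvi": np.clip(ndvi[keep], -1.0, 1.0)})


# ---------------------------------------------------------------------------
# Multi-angle reflectance


def geostationary_schedule(
    doys=None, hours=(9, 10, 11, 12, 13, 14, 15, 16), latitude=38.5, fixed_vza=40.0, view_azimuth=175.0
) -> pd.DataFrame:
    """Sun/view geometry of a geostationary diurnal acquisition schedule.

    Fixed view zenith/azimuth; the solar zenith and relative azimuth sweep
    through each day's hours, giving the angular diversity the inversion
    needs. `doy` records the fractional acquisition time (day + hour/24) so
    rolling windows see the true sample times.
    """
    if doys is None:
        doys = np.arange(1, 366)
    rows = []
    for d in np.atleast_1d(doys):
        for h in hours:
            sza = float(solar.solar_zenith_deg(d, h, latitude))
            if sza >= 85.0:
                continue
            saz = float(solar.solar_azimuth_deg(d, h, latitude))
            raa = abs((saz - view_azimuth + 180.0) % 360.0 - 180.0)
            rows.append((float(d) + h / 24.0, sza, fixed_vza, raa))
    return pd.DataFrame(rows, columns=["doy", "sza", "vza", "raa"])


def synth_angular_observations(
    true_params: dict,
    geometry_schedule: pd.DataFrame,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Forward-model reflectance from known kernel weights on a geometry schedule.

    `true_params` maps band name ('red', 'nir') to KernelParams. Returns the
    schedule with reflectance columns appended (the observation CSV layout).
    """
    sched = geometry_schedule.reset_index(drop=True)
    k_geo = li_sparse_reciprocal_kernel(sched["sza"].to_numpy(), sched["vza"].to_numpy(), sched["raa"].to_numpy())
    k_vol = ross_thick_kernel(sched["sza"].to_numpy(), sched["vza"].to_numpy(), sched["raa"].to_numpy())
    rng = _rng(seed, 202)
    out = sched.copy()
    for band, col in (("red", "red"), ("nir", "nir")):
        p = true_params[band]
        rho = p.f_iso + p.f_geo * np.atleast_1d(k_geo) + p.f_vol * np.atleast_1d(k_vol)
        if noise_sd > 0:
            rho = rho + rng.normal(0.0, noise_sd, size=rho.shape)
        out[col] = rho
    return out


# ---------------------------------------------------------------------------
# Weather


def synth_weather(
    year_length: int = 365,
    latitude: float = 38.0,
    seed: int = 0,
    aod: float = 0.15,
    water_vapour: float = 1.5,
    ozone: float = 0.3,
) -> pd.DataFrame:
    """Daily Tmax/Tmin and insolation for a temperate monsoon year.

    Temperatures are a sinusoid with Gaussian day-to-day anomalies; daily
    insolation integrates the hourly clear-sky model, damped by stochastic
    cloudiness whose frequency peaks June-September.
    """
    if not (-90.0 <= latitude <= 90.0):
        raise ValueError("latitude must lie in [-90, 90]")
    rng = _rng(seed, 303)
    doys = np.arange(1, year_length + 1)
    tmean = 10.0 + 13.0 * np.sin(2.0 * np.pi * (doys - 110.0) / 365.0)
    tmean = tmean + rng.normal(0.0, 2.0, size=doys.shape)
    half_range = 0.5 * (8.0 + rng.normal(0.0, 1.0, size=doys.shape).clip(-3.0, 3.0))
    half_range = np.maximum(half_range, 0.5)

    # clear-sky daily totals from the hourly physical model
    hours = np.arange(5, 20)
    clear_daily = np.empty(year_length)
    for i, d in enumerate(doys):
        szas = solar.solar_zenith_deg(float(d), hours.astype(float), latitude)
        e0 = float(solar.earth_sun_factor(float(d)))
        total = 0.0
        for z in szas:
            if z < 90.0:
                total += clear_sky_components(
                    AtmosState(aod, water_vapour, ozone, float(z), e0)
                ).S_T
        clear_daily[i] = total * 3600.0 * 1e-6

    monsoon = np.exp(-0.5 * ((doys - 212.0) / 45.0) ** 2)  # peaks late July
    p_cloud = 0.25 + 0.35 * monsoon
    cloudy = rng.random(year_length) < p_cloud
    factor = np.where(
        cloudy, rng.uniform(0.2, 0.7, year_length), rng.uniform(0.92, 1.0, year_length)
    )
    return pd.DataFrame(
        {
            "doy": doys,
            "tmax": tmean + half_range,
            "tmin": tmean - half_range,
            "insolation": clear_daily * factor,
        }
    )


# ---------------------------------------------------------------------------
# Landscape


@dataclass
class SyntheticScene:
    config: SceneConfig
    dem: np.ndarray
    slope_deg: np.ndarray
    wetness_index: np.ndarray
    labels: np.ndarray  # 1 = paddy
    doys: np.ndarray
    ndvi: np.ndarray  # (rows, cols, n_days) with NaN at cloud gaps
    truth: TruthRecord = field(repr=False, default=None)


def synth_landscape(config: SceneConfig, cell_size: float = 500.0) -> SyntheticScene:
    """Labelled landscape with terrain covariates and per-pixel NDVI series.

    The DEM is smoothed fractal-like noise plus a regional tilt; paddy pixels
    are placed by thresholding a suitability score that favours low elevation,
    low slope and high wetness (plus noise), at the quantile that realises
    paddy_fraction. Each pixel carries a daily NDVI series of its class with
    independent gaps and noise.
    """
    rows, cols = config.grid_rows, config.grid_cols
    rng = _rng(config.seed, 404)
    dem = gaussian_filter(rng.normal(0.0, 1.0, (rows, cols)), sigma=6.0)
    dem = 200.0 + 400.0 * (dem - dem.min()) / max(float(np.ptp(dem)), 1e-9)
    dem = dem + 150.0 * np.linspace(0, 1, rows)[:, None]  # regional tilt
    terr = terrain_variables(dem, cell_size)

    def z(x):
        return (x - x.mean()) / max(x.std(), 1e-9)

    score = -1.4 * z(dem) - 0.4 * z(terr.slope_deg) + 1.0 * z(terr.wetness_index)
    score = score + rng.normal(0.0, 0.2, score.shape)
    if config.paddy_fraction <= 0.0:
        labels = np.zeros((rows, cols), dtype=int)
    elif config.paddy_fraction >= 1.0:
        labels = np.ones((rows, cols), dtype=int)
    else:
        thresh = np.quantile(score, 1.0 - config.paddy_fraction)
        labels = (score > thresh).astype(int)

    doys = np.arange(1, 366, dtype=float)
    n_days = doys.size
    ndvi = np.empty((rows, cols, n_days))
    for r in range(rows):
        for c in range(cols):
            prng = _rng(config.seed, 505, r * cols + c)
            if labels[r, c]:
                base = _paddy_pixel_curve(doys, config, prng)
            elif prng.random() < 0.6:
                base = _crop_curve(doys, prng)  # upland dry-field crop
            else:
                base = _broadleaf_curve(doys, prng)  # forest on the hills
            series = base + prng.normal(0.0, config.noise_sd, n_days)
            series[prng.random(n_days) < config.cloud_gap_prob] = np.nan
            ndvi[r, c] = np.clip(series, -1.0, 1.0)

    truth = TruthRecord(labels_true=labels.copy())
    return SyntheticScene(
        config=config,
        dem=dem,
        slope_deg=terr.slope_deg,
        wetness_index=terr.wetness_index,
        labels=labels,
        doys=doys,
        ndvi=ndvi,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# GRAMI forward observations


def synth_vi_observations(
    params: GramiParams,
    constants: CropConstants,
    weather: pd.DataFrame,
    cal: VICalibration,
    transplant_doy: int = 136,
    obs_every: int = 5,
    noise_sd: float = 0.0,
    gap_prob: float = 0.0,
    monsoon_block: bool = False,
    seed: int = 0,
):
    """VI observations forward-generated by the crop model itself.

    Simulates the season at the true parameters, converts LAI to VI through
    the log-log calibration, samples every `obs_every` days, then applies
    noise, Bernoulli gaps, and optionally a contiguous 20-day monsoon gap
    centred mid-season. Returns (obs_doy, obs_vi, yield_true).
    """
    traj, yield_true, _ = simulate_season(params, constants, weather, transplant_doy)
    traj = traj.groupby("doy", as_index=False).last()
    sel = traj.iloc[:: max(obs_every, 1)]
    doy = sel["doy"].to_numpy(dtype=float)
    vi = vi_from_lai(sel["lai"].to_numpy(), cal)
    rng = _rng(seed, 606)
    if noise_sd > 0:
        vi = vi + rng.normal(0.0, noise_sd, size=vi.shape)
    keep = rng.random(doy.shape) >= gap_prob
    if monsoon_block:
        mid = 0.5 * (doy.min() + doy.max())
        keep &= ~((doy >= mid - 10) & (doy < mid + 10))
    return doy[keep], vi[keep], yield_true
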