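"""Semi-empirical kernel-driven BRDF model and BRDF-adjusted reflectance (BAR).

Surface reflectance is modelled as a linear combination of three scattering
modes (Ross-Thick Li-Sparse-Reciprocal, RTLSR):

    rho(theta_s, theta_v, phi) = f_iso + f_geo * k_geo + f_vol * k_vol

The kernel weights (f_iso, f_geo, f_vol) are estimated per pixel and band by
ordinary least squares over a 16-day rolling window of multi-angle
observations. For a geostationary sensor the angular sampling comes from the
diurnal sun sweep at a fixed view direction, so BAR is evaluated at the
pixel's fixed view geometry and the window-mean sun position (not normalised
to nadir as in the polar-orbiter NBAR convention).

Angles are degrees at every public interface; radians internally.
Relative azimuth phi = 0 deg is the forward-scattering direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AngularSample",
    "KernelParams",
    "ross_thick_kernel",
    "li_sparse_reciprocal_kernel",
    "fit_kernel_params",
    "bar_reflectance",
    "compute_ndvi",
    "rolling_bar_ndvi",
]

# Li-Sparse crown shape: relative height h/b and crown ellipse ratio b/r.
H_OVER_B = 2.0
B_OVER_R = 1.0

#: minimum observations for a full-quality inversion (16-day window heritage)
MIN_OBS_FULL = 7
#: minimum observations for the design matrix to be invertible at all
MIN_OBS_FIT = 3


@dataclass(frozen=True)
class AngularSample:
    """One reflectance observation with its sun/view geometry."""

    doy: float
    sza: float  # solar zenith, degrees, [0, 90)
    vza: float  # view zenith, degrees, [0, 90)
    raa: float  # relative azimuth, degrees (0 = forward scattering)
    reflectance_red: float
    reflectance_nir: float

    def __post_init__(self):
        if not (0.0 <= self.sza < 90.0 and 0.0 <= self.vza < 90.0):
            raise ValueError(f"zenith angles must lie in [0, 90): sza={self.sza}, vza={self.vza}")
        if not np.isfinite([self.sza, self.vza, self.raa]).all():
            raise ValueError("angles must be finite")


@dataclass
class KernelParams:
    """Fitted RTLSR kernel weights for one band and retrieval window."""

    f_iso: float
    f_geo: float
    f_vol: float
    band: str
    window_center_doy: float = np.nan
    n_obs: int = 0
    quality_flag: str = "full"  # {full, fill, failed}


def _check_angles(sza, vza):
    sza = np.asarray(sza, dtype=float)
    vza = np.asarray(vza, dtype=float)
    if np.any(sza < 0) or np.any(sza >= 90) or np.any(vza < 0) or np.any(vza >= 90):
        raise ValueError("zenith angles must lie in [0, 90) degrees")
    return sza, vza


def ross_thick_kernel(sza, vza, raa):
    """Ross-Thick volumetric scattering kernel.

    k_vol = [(pi/2 - xi) cos(xi) + sin(xi)] / (cos(ts) + cos(tv)) - pi/4,
    with scattering phase angle xi given by
    cos(xi) = cos(ts) cos(tv) + sin(ts) sin(tv) cos(raa).
    """
    sza, vza = _check_angles(sza, vza)
    ts, tv = np.deg2rad(sza), np.deg2rad(vza)
    phi = np.deg2rad(np.asarray(raa, dtype=float))
    cos_xi = np.cos(ts) * np.cos(tv) + np.sin(ts) * np.sin(tv) * np.cos(phi)
    xi = np.arccos(np.clip(cos_xi, -1.0, 1.0))
    k = ((np.pi / 2.0 - xi) * np.cos(xi) + np.sin(xi)) / (np.cos(ts) + np.cos(tv)) - np.pi / 4.0
    return k if k.ndim else float(k)


def li_sparse_reciprocal_kernel(sza, vza, raa):
    """Li-Sparse-Reciprocal geometric-optical kernel (h/b = 2, b/r = 1).

    Uses the standard primed-angle formulation with the crown overlap
    function O; the arccos argument of the overlap is clamped to [-1, 1] so
    the kernel stays finite for all admissible geometries.
    """
    sza, vza = _check_angles(sza, vza)
    phi = np.deg2rad(np.asarray(raa, dtype=float))
    tsp = np.arctan(B_OVER_R * np.tan(np.deg2rad(sza)))
    tvp = np.arctan(B_OVER_R * np.tan(np.deg2rad(vza)))
    cos_xi_p = np.cos(tsp) * np.cos(tvp) + np.sin(tsp) * np.sin(tvp) * np.cos(phi)
    sec_s = 1.0 / np.cos(tsp)
    sec_v = 1.0 / np.cos(tvp)
    d2 = np.tan(tsp) ** 2 + np.tan(tvp) ** 2 - 2.0 * np.tan(tsp) * np.tan(tvp) * np.cos(phi)
    cos_t = (
        H_OVER_B
        * np.sqrt(np.maximum(d2 + (np.tan(tsp) * np.tan(tvp) * np.sin(phi)) ** 2, 0.0))
        / (sec_s + sec_v)
    )
    t = np.arccos(np.clip(cos_t, -1.0, 1.0))
    overlap = (1.0 / np.pi) * (t - np.sin(t) * np.cos(t)) * (sec_s + sec_v)
    k = overlap - sec_s - sec_v + 0.5 * (1.0 + cos_xi_p) * sec_s * sec_v
    return k if k.ndim else float(k)


def _design_matrix(sza, vza, raa):
    k_geo = np.atleast_1d(li_sparse_reciprocal_kernel(sza, vza, raa))
    k_vol = np.atleast_1d(ross_thick_kernel(sza, vza, raa))
    return np.column_stack([np.ones_like(k_geo), k_geo, k_vol])


def _as_obs_frame(samples) -> pd.DataFrame:
    if isinstance(samples, pd.DataFrame):
        return samples
    return pd.DataFrame(
        {
            "doy": [s.doy for s in samples],
            "sza": [s.sza for s in samples],
            "vza": [s.vza for s in samples],
            "raa": [s.raa for s in samples],
            "red": [s.reflectance_red for s in samples],
            "nir": [s.reflectance_nir for s in samples],
        }
    )


def fit_kernel_params(samples, band: str, min_obs: int = MIN_OBS_FULL) -> KernelParams:
    """Invert the RTLSR model for one band by OLS on [1, k_geo, k_vol].

    quality_flag is 'full' when n_obs >= min_obs and the fit is physically
    sane (f_iso >= 0); 'fill' when a fit exists but should be replaced by the
    nearest previous full window; 'failed' when n_obs < 3 or the geometry is
    rank-deficient. Grid callers never see an exception from a bad window.
    """
    obs = _as_obs_frame(samples)
    col = {"red": "red", "nir": "nir"}[band]
    obs = obs[np.isfinite(obs[col])]
    n = len(obs)
    center = float(obs["doy"].mean()) if n else np.nan
    failed = KernelParams(np.nan, np.nan, np.nan, band, center, n, "failed")
    if n < MIN_OBS_FIT:
        return failed
    X = _design_matrix(obs["sza"].to_numpy(), obs["vza"].to_numpy(), obs["raa"].to_numpy())
    if np.linalg.matrix_rank(X) < 3:
        return failed
    coef, *_ = np.linalg.lstsq(X, obs[col].to_numpy(), rcond=None)
    f_iso, f_geo, f_vol = (float(c) for c in coef)
    if not np.isfinite(coef).all():
        return failed
    quality = "full" if (n >= min_obs and f_iso >= 0.0) else "fill"
    return KernelParams(f_iso, f_geo, f_vol, band, center, n, quality)


def bar_reflectance(params: KernelParams, fixed_vza: float, fixed_raa: float, mean_sza: float) -> float:
    """Evaluate the fitted BRDF at the fixed view geometry and mean sun angle.

    This is the geostationary BAR convention: the view direction stays at the
    sensor's fixed angle; only the sun is normalised to the window mean.
    """
    if params.quality_flag == "failed":
        return float("nan")
    k_geo = li_sparse_reciprocal_kernel(mean_sza, fixed_vza, fixed_raa)
    k_vol = ross_thick_kernel(mean_sza, fixed_vza, fixed_raa)
    return params.f_iso + params.f_geo * k_geo + params.f_vol * k_vol


def compute_ndvi(red, nir):
    """(NIR - Red) / (NIR + Red), clipped to [-1, 1]; NaN where the sum <= 0."""
    red = np.asarray(red, dtype=float)
    nir = np.asarray(nir, dtype=float)
    denom = red + nir
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(denom > 0, (nir - red) / denom, np.nan)
    ndvi = np.clip(ndvi, -1.0, 1.0)
    return ndvi if ndvi.ndim else float(ndvi)


def rolling_bar_ndvi(
    observations,
    window: int = 16,
    min_obs: int = MIN_OBS_FULL,
    fixed_vza: float | None = None,
    fixed_raa: float | None = None,
) -> pd.DataFrame:
    """Daily BAR NDVI by a daily-rolling inversion over a 16-day window.

    For every day d in the observed DOY range the RTLSR model is fitted to
    the samples in [d-8, d+7] for red and NIR, evaluated as BAR, and combined
    into NDVI. BAR here is the fitted BRDF at the fixed view geometry averaged
    over the window's actual sun positions (the window-mean sun convention):

        BAR = f_iso + f_geo * mean(k_geo) + f_vol * mean(k_vol)

    For an OLS fit this equals the window-mean fitted reflectance, so any
    within-window phenology trend that leaks into the angular kernel weights
    cancels exactly at evaluation. Evaluating instead at the kernels of the
    mean angles does not cancel the leakage and biases NDVI by several 0.01
    during steep green-up/senescence.

    Windows without a full-quality fit inherit parameters (and evaluation
    kernels) from the nearest previous full window ('fill'); days with no
    usable parameters at all are NaN with quality 'failed'.

    Returns a DataFrame with columns (doy, ndvi, quality).
    """
    obs = _as_obs_frame(observations).sort_values("doy").reset_index(drop=True)
    if obs.empty:
        return pd.DataFrame(columns=["doy", "ndvi", "quality"])
    if fixed_vza is None:
        fixed_vza = float(obs["vza"].iloc[0])
    half_lo = window // 2  # [d-8, d+7] for window=16
    half_hi = window - half_lo - 1

    d0, d1 = int(np.floor(obs["doy"].min())), int(np.floor(obs["doy"].max()))
    rows = []
    last_full: dict[str, KernelParams] = {}
    last_kernels: tuple[float, float] | None = None
    for d in range(d0, d1 + 1):
        win = obs[(obs["doy"] >= d - half_lo) & (obs["doy"] < d + half_hi + 1)]
        fits = {b: fit_kernel_params(win, b, min_obs=min_obs) for b in ("red", "nir")}
        if all(f.quality_flag == "full" for f in fits.values()):
            quality = "full"
            vza = np.full(len(win), fixed_vza)
            raa = win["raa"].to_numpy() if fixed_raa is None else np.full(len(win), fixed_raa)
            kernels = (
                float(np.mean(li_sparse_reciprocal_kernel(win["sza"].to_numpy(), vza, raa))),
                float(np.mean(ross_thick_kernel(win["sza"].to_numpy(), vza, raa))),
            )
            last_full, last_kernels = fits, kernels
        elif last_full:
            quality = "fill"
            fits, kernels = last_full, last_kernels
        else:
            rows.append((d, np.nan, "failed"))
            continue
        k_geo, k_vol = kernels
        red = fits["red"].f_iso + fits["red"].f_geo * k_geo + fits["red"].f_vol * k_vol
        nir = fits["nir"].f_iso + fits["nir"].f_geo * k_geo + fits["nir"].f_vol * k_vol
        rows.append((d, compute_ndvi(red, nir), quality))
    return pd.DataFrame(rows, columns=["doy", "ndvi", "quality"])
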