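"""Physical surface solar insolation: clear-sky components and cloud attenuation.

Total insolation is S_T = S_I + S_R + S_A under clear sky (direct, Rayleigh
diffuse, aerosol diffuse), and S_T = (S_I + S_R + S_A) * CF under cloud, where
the cloud factor CF is inferred from the visible reflectance of the cloud top
normalised by the solar zenith angle: brighter (optically thicker) cloud
passes less radiation.

Broadband clear-sky parameterisation (normative definitions; Bird-style
transmittances with a Kasten-Young relative air mass m):

    S_I = S0 * E0 * cos(z) * tau_oz * tau_w * tau_r * tau_a
    S_R = S0 * E0 * cos(z) * tau_oz * tau_w * tau_a * (1 - tau_r) / 2
    S_A = S0 * E0 * cos(z) * tau_oz * tau_w * tau_r * (1 - tau_a) * 0.84

    tau_r  = exp(-0.0903 m^0.84 (1 + m - m^1.01))
    tau_oz = 1 - 0.1611 X (1 + 139.48 X)^-0.3035
               - 0.002715 X / (1 + 0.044 X + 0.0003 X^2),  X = ozone * m
    tau_w  = 1 - 2.4959 W / ((1 + 79.034 W)^0.6828 + 6.385 W),  W = wv * m
    tau_a  = exp(-m * aod_550 * (0.70 / 0.55)^-1.3)   (Angstrom alpha = 1.3,
             broadband effective wavelength 0.70 um)

with solar constant S0 = 1361 W m^-2 and earth-sun factor E0. Zenith angles
z >= 90 deg are night: every component is zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AtmosState",
    "InsolationResult",
    "clear_sky_components",
    "cloud_factor",
    "total_insolation",
    "daily_integration",
    "SOLAR_CONSTANT",
]

SOLAR_CONSTANT = 1361.0  # W m^-2

#: overcast floor of the cloud factor (thick cloud still transmits some light)
CF_FLOOR = 0.05
#: zenith-normalised visible reflectance treated as fully overcast
RHO_MAX = 0.9
#: default clear-surface visible reflectance for cloud discrimination
CLEAR_REFERENCE = 0.15
#: reflectance excess over the clear reference that flags a cloudy scene
CLOUD_THRESHOLD = 0.08


@dataclass(frozen=True)
class AtmosState:
    """Atmospheric column state for one insolation evaluation."""

    aod_550: float  # aerosol optical depth at 550 nm
    water_vapour: float  # precipitable water, cm
    ozone: float  # total column ozone, atm-cm
    sza: float  # solar zenith angle, degrees
    earth_sun_factor: float = 1.0

    def __post_init__(self):
        if self.aod_550 < 0 or self.water_vapour < 0 or self.ozone < 0:
            raise ValueError("atmospheric constituents must be non-negative")


@dataclass
class InsolationResult:
    S_I: float  # direct, W m^-2
    S_R: float  # Rayleigh diffuse, W m^-2
    S_A: float  # aerosol diffuse, W m^-2
    S_T: float  # total, W m^-2
    cloud_factor: float
    sky: str  # {clear, cloudy, night}


def _air_mass(sza_deg: float) -> float:
    """Kasten-Young (1989) relative optical air mass."""
    return 1.0 / (np.cos(np.deg2rad(sza_deg)) + 0.50572 * (96.07995 - sza_deg) ** -1.6364)


def clear_sky_components(atmos: AtmosState) -> InsolationResult:
    """Clear-sky direct and diffuse components (cloud_factor = 1)."""
    if atmos.sza >= 90.0:
        return InsolationResult(0.0, 0.0, 0.0, 0.0, 1.0, "night")
    m = _air_mass(atmos.sza)
    cosz = np.cos(np.deg2rad(atmos.sza))

    tau_r = np.exp(-0.0903 * m**0.84 * (1.0 + m - m**1.01))
    X = atmos.ozone * m
    tau_oz = (
        1.0
        - 0.1611 * X * (1.0 + 139.48 * X) ** -0.3035
        - 0.002715 * X / (1.0 + 0.044 * X + 0.0003 * X**2)
    )
    W = atmos.water_vapour * m
    tau_w = 1.0 - 2.4959 * W / ((1.0 + 79.034 * W) ** 0.6828 + 6.385 * W)
    tau_a = np.exp(-m * atmos.aod_550 * (0.70 / 0.55) ** -1.3)

    top = SOLAR_CONSTANT * atmos.earth_sun_factor * cosz * tau_oz * tau_w
    s_i = top * tau_r * tau_a
    s_r = top * tau_a * (1.0 - tau_r) / 2.0
    s_a = top * tau_r * (1.0 - tau_a) * 0.84
    s_i, s_r, s_a = (float(max(v, 0.0)) for v in (s_i, s_r, s_a))
    return InsolationResult(s_i, s_r, s_a, s_i + s_r + s_a, 1.0, "clear")


def cloud_factor(
    vis_reflectance: float,
    sza: float,
    clear_reference_reflectance: float = CLEAR_REFERENCE,
    rho_max: float = RHO_MAX,
    floor: float = CF_FLOOR,
) -> float:
    """Multiplicative cloud attenuation from visible reflectance and sun angle.

    Reflectances are zenith-normalised (rho' = rho / cos z) so that the same
    cloud viewed at a low sun reads as optically thicker. CF is 1 at or below
    the clear reference and falls linearly to the overcast floor at rho_max.
    """
    cosz = max(np.cos(np.deg2rad(min(sza, 89.9))), 1e-6)
    rho_n = vis_reflectance / cosz
    rho_clear = clear_reference_reflectance / cosz
    if rho_max <= rho_clear:
        return floor
    cf = 1.0 - (rho_n - rho_clear) / (rho_max - rho_clear)
    return float(np.clip(cf, floor, 1.0))


def total_insolation(
    atmos: AtmosState,
    vis_reflectance: float | None = None,
    cloud_mask: bool | None = None,
    clear_reference_reflectance: float = CLEAR_REFERENCE,
) -> InsolationResult:
    """Total insolation with cloud discrimination.

    cloud_mask, when given, decides the branch; otherwise a scene is cloudy
    when its visible reflectance exceeds the clear reference by more than
    CLOUD_THRESHOLD. Clear scenes use the clear-sky parameterisation as-is;
    cloudy scenes multiply every component's total by the cloud factor.
    """
    clear = clear_sky_components(atmos)
    if clear.sky == "night":
        return clear
    if cloud_mask is None:
        cloud_mask = (
            vis_reflectance is not None
            and vis_reflectance > clear_reference_reflectance + CLOUD_THRESHOLD
        )
    if not cloud_mask:
        return clear
    cf = cloud_factor(
        vis_reflectance if vis_reflectance is not None else RHO_MAX,
        atmos.sza,
        clear_reference_reflectance,
    )
    return InsolationResult(
        clear.S_I, clear.S_R, clear.S_A, clear.S_T * cf, cf, "cloudy"
    )


def daily_integration(hourly) -> float:
    """Integrate hourly insolation (W m^-2) to a daily total in MJ m^-2 d^-1.

    Each hourly value is the mean irradiance over its hour, so the daily total
    is sum(S_T) * 3600 * 1e-6. Accepts InsolationResult objects or numbers.
    """
    values = [h.S_T if isinstance(h, InsolationResult) else float(h) for h in hourly]
    if len(values) > 24:
        raise ValueError("at most 24 hourly values per day")
    if not values:
        warnings.warn("empty hourly series: daily insolation set to 0", stacklevel=2)
        return 0.0
    return float(np.sum(values) * 3600.0 * 1e-6)
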