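"""Solar geometry helpers: declination, zenith/azimuth angles, earth-sun distance.

Simple astronomical approximations (Spencer/Cooper-style), adequate for
degree-level geometry of a geostationary imaging schedule; not an ephemeris.
All angles in degrees at the interface.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "declination_deg",
    "earth_sun_factor",
    "solar_zenith_deg",
    "solar_azimuth_deg",
]


def declination_deg(doy):
    """Solar declination (degrees) from day of year (Cooper approximation)."""
    doy = np.asarray(doy, dtype=float)
    return 23.45 * np.sin(2.0 * np.pi * (284.0 + doy) / 365.0)


def earth_sun_factor(doy):
    """Eccentricity correction E0 = (r0/r)^2, ~[0.967, 1.033]."""
    doy = np.asarray(doy, dtype=float)
    return 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)


def solar_zenith_deg(doy, hour, latitude_deg):
    """Solar zenith angle (degrees) at local solar time `hour` (0-24)."""
    delta = np.deg2rad(declination_deg(doy))
    phi = np.deg2rad(np.asarray(latitude_deg, dtype=float))
    h = np.deg2rad(15.0 * (np.asarray(hour, dtype=float) - 12.0))
    cosz = np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.cos(h)
    return np.rad2deg(np.arccos(np.clip(cosz, -1.0, 1.0)))


def solar_azimuth_deg(doy, hour, latitude_deg):
    """Solar azimuth (degrees clockwise from north, 0-360)."""
    delta = np.deg2rad(declination_deg(doy))
    phi = np.deg2rad(np.asarray(latitude_deg, dtype=float))
    h = np.deg2rad(15.0 * (np.asarray(hour, dtype=float) - 12.0))
    z = np.deg2rad(solar_zenith_deg(doy, hour, latitude_deg))
    sinz = np.sin(z)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos_a = np.where(
            sinz > 1e-9,
            (np.sin(delta) - np.sin(phi) * np.cos(z)) / (np.cos(phi) * sinz),
            1.0,
        )
    a = np.rad2deg(np.arccos(np.clip(cos_a, -1.0, 1.0)))
    # afternoon (positive hour angle) -> western sky
    return np.where(np.sin(h) > 0, 360.0 - a, a)
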