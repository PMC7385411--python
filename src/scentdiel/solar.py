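"""Solar geometry and terrain-corrected sunset.

Sunset is the natural zero point for crepuscular pollinator activity, but at
a mountain site the sun disappears behind the local ridge well before it
reaches the astronomical horizon.  ``terrain_sunset`` therefore returns the
time at which the geometric solar elevation first drops below the elevation
angle of the ridge toward the sunset azimuth; with a ridge angle of zero it
falls back to the standard refraction-corrected sunset (solar elevation
-0.833 deg, the usual refraction + solar-radius convention).

Solar position uses the NOAA low-precision ephemeris approximations
(geometric mean longitude/anomaly, equation of center, apparent longitude,
mean obliquity, equation of time), accurate to about 0.1 deg in elevation
over 1900-2100 — ample for sunset times to well under a minute.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SolarContext",
    "solar_position",
    "solar_elevation",
    "terrain_sunset",
]

#: Geometric elevation of the solar center at standard sunset: 34 arcmin of
#: atmospheric refraction plus 16 arcmin solar semidiameter.
STANDARD_SUNSET_ELEVATION = -0.833


@dataclass(frozen=True)
class SolarContext:
    """Observation-site geometry for sunset computations.

    Parameters
    ----------
    latitude, longitude : float
        Site coordinates in decimal degrees (east and north positive).
    utc_offset : float
        Fixed local-time offset from UTC in hours (no daylight saving).
    ridge_elevation_angle : float
        Elevation angle (degrees) of the terrain horizon toward the median
        sunset azimuth; 0 means a free astronomical horizon.
    ridge_azimuth : float, optional
        Azimuth of the ridge sightline; informational only — the correction
        uses a single scalar elevation threshold.
    """

    latitude: float
    longitude: float
    utc_offset: float
    ridge_elevation_angle: float = 0.0
    ridge_azimuth: float | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of range: {self.longitude}")
        if not 0.0 <= self.ridge_elevation_angle < 90.0:
            raise ValueError(
                f"ridge elevation angle must be in [0, 90): {self.ridge_elevation_angle}"
            )


def _julian_day(when_utc: dt.datetime) -> float:
    y, m = when_utc.year, when_utc.month
    d = (
        when_utc.day
        + (when_utc.hour + when_utc.minute / 60.0 + when_utc.second / 3600.0) / 24.0
    )
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return int(365.25 * (y + 4716)) + int(30.6001 * (m + 1)) + d + b - 1524.5


def _solar_coords(jc: float) -> tuple[float, float]:
    """Return (declination deg, equation of time minutes) at Julian century jc."""
    l0 = (280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0
    m = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    e = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    mrad = np.deg2rad(m)
    c = (
        np.sin(mrad) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + np.sin(2 * mrad) * (0.019993 - 0.000101 * jc)
        + np.sin(3 * mrad) * 0.000289
    )
    true_long = l0 + c
    omega = np.deg2rad(125.04 - 1934.136 * jc)
    app_long = true_long - 0.00569 - 0.00478 * np.sin(omega)
    eps0 = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    eps = np.deg2rad(eps0 + 0.00256 * np.cos(omega))
    decl = np.rad2deg(np.arcsin(np.sin(eps) * np.sin(np.deg2rad(app_long))))
    y = np.tan(eps / 2.0) ** 2
    l0r = np.deg2rad(l0)
    eot = 4.0 * np.rad2deg(
        y * np.sin(2 * l0r)
        - 2.0 * e * np.sin(mrad)
        + 4.0 * e * y * np.sin(mrad) * np.cos(2 * l0r)
        - 0.5 * y * y * np.sin(4 * l0r)
        - 1.25 * e * e * np.sin(2 * mrad)
    )
    return float(decl), float(eot)


def solar_position(context: SolarContext, when: dt.datetime) -> tuple[float, float]:
    """Geometric solar elevation and azimuth (degrees) at a local datetime.

    ``when`` is interpreted in the context's fixed UTC offset if naive;
    an aware datetime is converted.  Azimuth is measured clockwise from
    north.  No refraction is applied (callers apply the -0.833 deg sunset
    convention explicitly where needed).
    """
    if not 1900 <= when.year <= 2100:
        raise ValueError("datetime outside supported range 1900-2100")
    if when.tzinfo is None:
        when_utc = when - dt.timedelta(hours=context.utc_offset)
    else:
        when_utc = when.astimezone(dt.timezone.utc).replace(tzinfo=None)
    jd = _julian_day(when_utc)
    jc = (jd - 2451545.0) / 36525.0
    decl, eot = _solar_coords(jc)
    minutes_utc = when_utc.hour * 60.0 + when_utc.minute + when_utc.second / 60.0
    true_solar_min = (minutes_utc + eot + 4.0 * context.longitude) % 1440.0
    hour_angle = true_solar_min / 4.0 - 180.0
    phi = np.deg2rad(context.latitude)
    drad = np.deg2rad(decl)
    hrad = np.deg2rad(hour_angle)
    sin_el = np.sin(phi) * np.sin(drad) + np.cos(phi) * np.cos(drad) * np.cos(hrad)
    elevation = np.rad2deg(np.arcsin(np.clip(sin_el, -1.0, 1.0)))
    cos_az = (np.sin(drad) - np.sin(phi) * sin_el) / (np.cos(phi) * np.cos(np.deg2rad(elevation)))
    az = np.rad2deg(np.arccos(np.clip(cos_az, -1.0, 1.0)))
    # morning sun east of the meridian (az < 180), afternoon west
    azimuth = az if hour_angle < 0 else 360.0 - az
    return float(elevation), float(azimuth)


def solar_elevation(context: SolarContext, when: dt.datetime) -> float:
    """Geometric solar elevation (degrees) at a local datetime."""
    return solar_position(context, when)[0]


def terrain_sunset(context: SolarContext, date: dt.date) -> dt.datetime:
    """Local time at which the sun drops behind the terrain horizon.

    On the descending branch of the solar arc, returns the first time the
    geometric elevation falls below ``ridge_elevation_angle``; with a ridge
    angle of zero the threshold is the standard refraction-corrected
    -0.833 deg instead.

    Raises
    ------
    ValueError
        If the sun never rises above the threshold on that date (e.g. a
        ridge angle above the day's maximum solar elevation).
    """
    threshold = (
        STANDARD_SUNSET_ELEVATION
        if context.ridge_elevation_angle == 0.0
        else context.ridge_elevation_angle
    )

    def elev_minus(minutes: float) -> float:
        when = dt.datetime.combine(date, dt.time(0)) + dt.timedelta(minutes=minutes)
        return solar_elevation(context, when) - threshold

    # locate local solar noon by coarse scan, then bracket the descent
    grid = np.arange(0.0, 1441.0, 10.0)
    elevs = np.array([elev_minus(m) for m in grid])
    i_noon = int(np.argmax(elevs))
    if elevs[i_noon] <= 0.0:
        raise ValueError(
            f"sun never rises above {threshold:.3f} deg on {date}; "
            "ridge angle exceeds the day's maximum solar elevation"
        )
    after = grid[i_noon:]
    vals = elevs[i_noon:]
    below = np.nonzero(vals < 0.0)[0]
    if below.size == 0:
        raise ValueError(f"sun does not descend below {threshold:.3f} deg on {date}")
    j = below[0]
    t_cross = brentq(elev_minus, after[j - 1], after[j], xtol=1e-4)
    return dt.datetime.combine(date, dt.time(0)) + dt.timedelta(minutes=float(t_cross))
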