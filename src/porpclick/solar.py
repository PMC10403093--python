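"""Sunrise/sunset from solar position (NOAA low-accuracy algorithm).

Implements the NOAA solar-calculator equations: Julian century, solar
geometric mean longitude/anomaly, equation of time and declination,
then the sunrise hour angle for a zenith of 90.833 deg (sun centre at
the geometric horizon plus standard atmospheric refraction and solar
semidiameter).  Accuracy is a minute or two over the study latitudes —
well inside the tolerance that matters for a day/night factor.
"""

from __future__ import annotations

import datetime as dt
import math

__all__ = ["sunrise_sunset", "UnsupportedLatitudeError"]

_ZENITH_OFFICIAL = 90.833  # degrees


class UnsupportedLatitudeError(ValueError):
    """Polar day/night: no sunrise/sunset on this date at this latitude."""


def _julian_day(date: dt.date) -> float:
    y, m, d = date.year, date.month, date.day
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + d + b - 1524.5


def _solar_noon_and_ha(date: dt.date, latitude: float, longitude: float):
    """Solar noon (minutes UTC) and sunrise hour angle (deg) for the date."""
    jd = _julian_day(date)
    # iterate once with the time-of-day refinement folded in via solar noon
    t = (jd - 2451545.0) / 36525.0

    l0 = (280.46646 + t * (36000.76983 + 0.0003032 * t)) % 360.0
    m = 357.52911 + t * (35999.05029 - 0.0001537 * t)
    e = 0.016708634 - t * (0.000042037 + 0.0000001267 * t)
    mr = math.radians(m)
    c = (
        math.sin(mr) * (1.914602 - t * (0.004817 + 0.000014 * t))
        + math.sin(2 * mr) * (0.019993 - 0.000101 * t)
        + math.sin(3 * mr) * 0.000289
    )
    true_long = l0 + c
    omega = 125.04 - 1934.136 * t
    app_long = true_long - 0.00569 - 0.00478 * math.sin(math.radians(omega))

    seconds = 21.448 - t * (46.8150 + t * (0.00059 - t * 0.001813))
    e0 = 23.0 + (26.0 + seconds / 60.0) / 60.0
    eps = e0 + 0.00256 * math.cos(math.radians(omega))

    decl = math.degrees(
        math.asin(math.sin(math.radians(eps)) * math.sin(math.radians(app_long)))
    )

    y = math.tan(math.radians(eps / 2.0)) ** 2
    l0r = math.radians(l0)
    eqtime = 4.0 * math.degrees(
        y * math.sin(2 * l0r)
        - 2.0 * e * math.sin(mr)
        + 4.0 * e * y * math.sin(mr) * math.cos(2 * l0r)
        - 0.5 * y * y * math.sin(4 * l0r)
        - 1.25 * e * e * math.sin(2 * mr)
    )

    lat_r = math.radians(latitude)
    decl_r = math.radians(decl)
    cos_ha = (
        math.cos(math.radians(_ZENITH_OFFICIAL))
        - math.sin(lat_r) * math.sin(decl_r)
    ) / (math.cos(lat_r) * math.cos(decl_r))
    if cos_ha > 1.0 or cos_ha < -1.0:
        raise UnsupportedLatitudeError(
            f"no sunrise/sunset at latitude {latitude} on {date} "
            "(polar day or night)"
        )
    ha = math.degrees(math.acos(cos_ha))
    solar_noon_utc_min = 720.0 - 4.0 * longitude - eqtime
    return solar_noon_utc_min, ha


def sunrise_sunset(
    date: dt.date,
    latitude: float,
    longitude: float,
    tz_offset_hours: float = 0.0,
) -> tuple[dt.datetime, dt.datetime]:
    """Local sunrise and sunset datetimes for one calendar date.

    ``tz_offset_hours`` converts from UTC (e.g. +9 for JST).  Raises
    :class:`UnsupportedLatitudeError` during polar day/night.
    """
    noon_min, ha = _solar_noon_and_ha(date, latitude, longitude)
    rise_min = noon_min - 4.0 * ha + tz_offset_hours * 60.0
    set_min = noon_min + 4.0 * ha + tz_offset_hours * 60.0
    base = dt.datetime(date.year, date.month, date.day)
    return (
        base + dt.timedelta(minutes=rise_min),
        base + dt.timedelta(minutes=set_min),
    )
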