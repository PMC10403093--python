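"""Environmental covariates for each detected click train.

Three constructions:

* a day/night factor from computed sunrise/sunset at the station
  coordinates (an override table of published (date, sunrise, sunset)
  rows takes precedence when supplied — e.g. to reproduce a specific
  almanac exactly);
* an rms noise level from the 1-minute windows flanking each click
  train (train samples excluded), expressed in dB re 1 uPa rms;
* nearest-in-time joins of sparsely sampled series (monthly salinity,
  5-minute temperature/flow bursts) onto click-train timestamps.

Vessel presence is an *input* label column (manual annotation or
simulation truth) — no vessel detector is implemented here.
"""

from __future__ import annotations

import datetime as dt
import warnings

import numpy as np
import pandas as pd

from .solar import UnsupportedLatitudeError, sunrise_sunset

__all__ = [
    "day_night",
    "noise_level_rms",
    "nearest_in_time_join",
    "build_env_table",
    "UnsupportedLatitudeError",
]


def day_night(
    timestamp: dt.datetime,
    latitude: float,
    longitude: float,
    tz_offset_hours: float = 0.0,
    overrides: pd.DataFrame | None = None,
) -> str:
    """'day' between sunrise and sunset (inclusive of sunrise), else 'night'.

    ``overrides``, if given, is a frame with columns ``date``,
    ``sunrise``, ``sunset`` (datetimes) that takes precedence over the
    computed solar times for matching dates.
    """
    date = timestamp.date()
    rise = sset = None
    if overrides is not None:
        hit = overrides[pd.to_datetime(overrides["date"]).dt.date == date]
        if len(hit):
            rise = pd.to_datetime(hit.iloc[0]["sunrise"]).to_pydatetime()
            sset = pd.to_datetime(hit.iloc[0]["sunset"]).to_pydatetime()
    if rise is None:
        rise, sset = sunrise_sunset(date, latitude, longitude, tz_offset_hours)
    return "day" if rise <= timestamp < sset else "night"


def noise_level_rms(
    waveform_upa: np.ndarray,
    rate: float,
    train_interval: tuple[float, float],
    t0: float = 0.0,
    window_s: float = 60.0,
    combine: str = "pooled",
) -> float:
    """rms noise level (dB re 1 uPa) around a click train.

    Takes the ``window_s`` stretch before the train start and after the
    train end (click-train samples excluded), removes the DC offset and
    combines the two windows — as a pooled rms of the concatenation by
    default, or as the mean of the two window levels
    (``combine="mean_of_levels"``).  Windows extending beyond the
    recording are truncated with a warning.
    """
    start, end = train_interval
    i_pre0 = int((start - window_s - t0) * rate)
    i_pre1 = int((start - t0) * rate)
    i_post0 = int((end - t0) * rate)
    i_post1 = int((end + window_s - t0) * rate)
    n = len(waveform_upa)
    if i_pre0 < 0 or i_post1 > n:
        warnings.warn(
            "less than the full noise window available; truncating",
            stacklevel=2,
        )
    pre = waveform_upa[max(i_pre0, 0) : max(i_pre1, 0)]
    post = waveform_upa[min(i_post0, n) : min(i_post1, n)]
    segs = [s for s in (pre, post) if len(s)]
    if not segs:
        raise ValueError("no audio available around the train interval")

    def _rms(x: np.ndarray) -> float:
        x = x - np.mean(x)
        return float(np.sqrt(np.mean(x * x)))

    if combine == "pooled":
        rms = _rms(np.concatenate(segs))
        if rms == 0.0:
            warnings.warn("digital silence; noise level is -inf", stacklevel=2)
            return float("-inf")
        return 20.0 * np.log10(rms)
    if combine == "mean_of_levels":
        levels = []
        for s in segs:
            r = _rms(s)
            if r == 0.0:
                warnings.warn("digital silence; noise level is -inf",
                              stacklevel=2)
                return float("-inf")
            levels.append(20.0 * np.log10(r))
        return float(np.mean(levels))
    raise ValueError(f"unknown combine mode {combine!r}")


def nearest_in_time_join(
    sample_times: np.ndarray,
    sample_values: np.ndarray,
    query_times: np.ndarray,
) -> np.ndarray:
    """For each query, the sample value with the nearest timestamp.

    Ties (a query exactly midway between two samples) resolve toward
    the earlier sample.  ``sample_times`` must be sorted and non-empty.
    """
    st = np.asarray(sample_times, dtype=float)
    if len(st) == 0:
        raise ValueError("sample series must be non-empty")
    if np.any(np.diff(st) < 0):
        raise ValueError("sample series must be sorted")
    sv = np.asarray(sample_values)
    q = np.atleast_1d(np.asarray(query_times, dtype=float))
    idx = np.searchsorted(st, q)
    idx = np.clip(idx, 1, len(st) - 1) if len(st) > 1 else np.zeros_like(idx)
    if len(st) == 1:
        return sv[np.zeros(len(q), dtype=int)]
    left = idx - 1
    d_left = np.abs(q - st[left])
    d_right = np.abs(st[idx] - q)
    choose_left = d_left <= d_right  # tie -> earlier
    return sv[np.where(choose_left, left, idx)]


def build_env_table(
    train_times: np.ndarray,
    *,
    latitude: float,
    longitude: float,
    tz_offset_hours: float = 9.0,
    epoch: dt.datetime | None = None,
    temperature: tuple[np.ndarray, np.ndarray] | None = None,
    flow: tuple[np.ndarray, np.ndarray] | None = None,
    salinity: tuple[np.ndarray, np.ndarray] | None = None,
    vessel_labels: np.ndarray | None = None,
    noise_levels: np.ndarray | None = None,
    sun_overrides: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the per-train environmental-covariate table.

    ``train_times`` are seconds relative to ``epoch`` (a datetime; if
    None, labels default to 'day').  The temperature/flow/salinity
    series are (times_s, values) pairs joined nearest-in-time.
    """
    n = len(train_times)
    out = pd.DataFrame({"time_s": np.asarray(train_times, dtype=float)})
    if epoch is not None:
        stamps = [epoch + dt.timedelta(seconds=float(t)) for t in train_times]
        out["day_night"] = [
            day_night(s, latitude, longitude, tz_offset_hours, sun_overrides)
            for s in stamps
        ]
    else:
        out["day_night"] = "day"
    for name, series in (
        ("temperature", temperature), ("flow", flow), ("salinity", salinity)
    ):
        if series is not None:
            out[name] = nearest_in_time_join(
                series[0], series[1], out["time_s"].to_numpy()
            )
    if vessel_labels is not None:
        if len(vessel_labels) != n:
            raise ValueError("one vessel label per train required")
        out["vessel"] = np.asarray(vessel_labels)
    if noise_levels is not None:
        out["noise_level"] = np.asarray(noise_levels, dtype=float)
    return out
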