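"""Bearing and range estimation from the stereo loggers.

Each stereo logger gives one signed time difference of arrival (TDOA)
per pulse across its 190-mm vertical baseline; the bearing relative to
the broadside plane is ``arcsin(c * tdoa / baseline)``, positive toward
the deeper hydrophone.  Two loggers 1 m apart on the array give two
bearings whose intersection in the vertical plane yields the source
range (referenced to the array midpoint, co-located with the calibrated
recorder, so it matches the transmission-loss path).

The module also hosts the porpoise-family pressure-ratio filter: the
ratio of the low-frequency-sensitive channel's peak-to-peak pressure to
the high-frequency-sensitive channel's must be >= 0.6 for a pulse to be
retained as Phocoenidae-like (NBHF clicks still register at ~0.7-0.8 on
the 70-kHz channel, while lower-frequency broadband clicks fall outside
the acceptance band).  The orientation is configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "Bearing",
    "RangeEstimate",
    "azimuth_from_tdoa",
    "species_pressure_ratio",
    "range_from_two_bearings",
    "TrainLocalizer",
]


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class Bearing:
    """Signed bearing (deg) off the broadside plane; positive = deeper."""

    azimuth_deg: float
    sensor_id: str = ""

    def __post_init__(self) -> None:
        if not -90.0 <= self.azimuth_deg <= 90.0:
            raise ValueError("azimuth must lie in [-90, 90] deg")


@dataclass(frozen=True)
class RangeEstimate:
    range_m: float
    geometry_ok: bool
    horizontal_m: float = float("nan")
    source_depth_offset_m: float = float("nan")


def azimuth_from_tdoa(
    tdoa_s: float,
    baseline_m: float,
    sound_speed_ms: float,
    sensor_id: str = "",
    clamp_tolerance: float = 0.05,
) -> Bearing:
    """Bearing from a stereo TDOA: ``arcsin(c * dt / d)`` in degrees.

    TDOAs exceeding the physical maximum ``d/c`` by at most
    ``clamp_tolerance`` (fractional, to absorb quantization) are clamped
    with a warning; beyond that a :class:`GeometryError` is raised.
    """
    x = sound_speed_ms * tdoa_s / baseline_m
    if abs(x) > 1.0:
        if abs(x) - 1.0 <= clamp_tolerance:
            warnings.warn(
                f"TDOA {tdoa_s:.3g} s slightly beyond the physical maximum; "
                "clamped to endfire",
                stacklevel=2,
            )
            x = float(np.sign(x))
        else:
            raise GeometryError(
                f"TDOA {tdoa_s:.3g} s exceeds baseline/c by more than "
                f"{clamp_tolerance:.0%}"
            )
    return Bearing(float(np.degrees(np.arcsin(x))), sensor_id)


def species_pressure_ratio(
    pp_high_ch: float,
    pp_low_ch: float,
    threshold: float = 0.6,
    orientation: str = "low_over_high",
) -> tuple[float, bool]:
    """Two-channel pressure ratio and the Phocoenidae pass flag.

    Returns ``(ratio, ratio >= threshold)``.  Default orientation is the
    low-frequency-sensitive channel over the high-frequency-sensitive
    one; a train passes iff its max-amplitude click passes.
    """
    if pp_high_ch <= 0 or pp_low_ch <= 0:
        raise ValueError("channel pressures must be > 0 for a defined ratio")
    if orientation == "low_over_high":
        ratio = pp_low_ch / pp_high_ch
    elif orientation == "high_over_low":
        ratio = pp_high_ch / pp_low_ch
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return ratio, ratio >= threshold


def range_from_two_bearings(
    bearing_top: Bearing,
    bearing_bottom: Bearing,
    vertical_baseline_m: float = 1.0,
    min_separation_deg: float = 0.5,
) -> RangeEstimate:
    """Two-bearing triangulation in the vertical plane.

    The two bearing lines are anchored at the two loggers,
    ``vertical_baseline_m`` apart; their intersection gives the source's
    horizontal stand-off and depth, converted to slant range from the
    array midpoint.  Bearings separated by less than
    ``min_separation_deg`` (near-parallel lines: unresolvable or distant
    source) yield ``geometry_ok=False`` rather than an error.
    """
    th_t = np.radians(bearing_top.azimuth_deg)
    th_b = np.radians(bearing_bottom.azimuth_deg)
    if abs(bearing_top.azimuth_deg - bearing_bottom.azimuth_deg) < min_separation_deg:
        return RangeEstimate(float("nan"), False)
    denom = np.tan(th_t) - np.tan(th_b)
    if denom <= 0:  # bottom bearing steeper than top: inconsistent geometry
        return RangeEstimate(float("nan"), False)
    x = vertical_baseline_m / denom
    z_off = x * np.tan(th_t) - vertical_baseline_m / 2.0  # rel. midpoint
    r = float(np.hypot(x, z_off))
    return RangeEstimate(r, True, float(x), float(z_off))


class TrainLocalizer(BaseEstimator, TransformerMixin):
    """Augment detected trains with bearings, species ratio and range.

    ``transform`` takes a run-state dict holding ``trains`` (list of
    ClickTrain from the deeper logger), ``events`` (full event stream)
    and ``sound_speed``/geometry, and returns the dict with a
    ``localized`` DataFrame added (one row per train: azimuths at the
    max-amplitude click, pressure ratio + pass flag, triangulated
    range).  Events from the second logger are matched by nearest time
    within ``match_tolerance_s``.
    """

    def __init__(
        self,
        stereo_baseline_m: float = 0.190,
        vertical_baseline_m: float = 1.0,
        match_tolerance_s: float = 1.5e-3,
        ratio_threshold: float = 0.6,
        ratio_orientation: str = "low_over_high",
        min_separation_deg: float = 0.5,
        primary_sensor: str = "atag_4m",
        secondary_sensor: str = "atag_3m",
    ):
        self.stereo_baseline_m = stereo_baseline_m
        self.vertical_baseline_m = vertical_baseline_m
        self.match_tolerance_s = match_tolerance_s
        self.ratio_threshold = ratio_threshold
        self.ratio_orientation = ratio_orientation
        self.min_separation_deg = min_separation_deg
        self.primary_sensor = primary_sensor
        self.secondary_sensor = secondary_sensor

    def fit(self, X=None, y=None):
        return self

    def transform(self, state: dict) -> dict:
        trains = state["trains"]
        events = state["events"]
        c = state["sound_speed"]
        other = events[events["sensor_id"] == self.secondary_sensor]
        other_t = other["time"].to_numpy()
        rows = []
        for tr in trains:
            i = tr.max_amplitude_index
            ev = tr.events.iloc[i]
            b_bot = azimuth_from_tdoa(
                ev["tdoa"], self.stereo_baseline_m, c, self.primary_sensor
            )
            ratio, sp_ok = species_pressure_ratio(
                ev["pp_ch1"], ev["pp_ch2"], self.ratio_threshold,
                self.ratio_orientation,
            )
            b_top = None
            matched = False
            if len(other_t):
                j = int(np.argmin(np.abs(other_t - ev["time"])))
                if abs(other_t[j] - ev["time"]) <= self.match_tolerance_s:
                    matched = True
                    b_top = azimuth_from_tdoa(
                        other.iloc[j]["tdoa"], self.stereo_baseline_m, c,
                        self.secondary_sensor,
                    )
            if b_top is not None:
                rng_est = range_from_two_bearings(
                    b_top, b_bot, self.vertical_baseline_m,
                    self.min_separation_deg,
                )
            else:
                rng_est = RangeEstimate(float("nan"), False)
            az_mean = (
                (b_top.azimuth_deg + b_bot.azimuth_deg) / 2.0
                if b_top is not None
                else b_bot.azimuth_deg
            )
            rows.append(
                {
                    "train_index": tr.train_index,
                    "azimuth_deg": az_mean,
                    "azimuth_top_deg": b_top.azimuth_deg if b_top else np.nan,
                    "azimuth_bottom_deg": b_bot.azimuth_deg,
                    "pressure_ratio": ratio,
                    "species_pass": bool(sp_ok),
                    "matched_both_atags": matched,
                    "range_m": rng_est.range_m,
                    "geometry_ok": bool(rng_est.geometry_ok),
                }
            )
        out = dict(state)
        out["localized"] = pd.DataFrame(
            rows,
            columns=[
                "train_index", "azimuth_deg", "azimuth_top_deg",
                "azimuth_bottom_deg", "pressure_ratio", "species_pass",
                "matched_both_atags", "range_m", "geometry_ok",
            ],
        )
        return out
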