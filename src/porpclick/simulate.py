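"""Synthetic NBHF click-scene generator.

Produces the three data products the analysis pipeline consumes, with
known ground truth:

* calibrated waveform segments (uPa, 576 kHz) as recorded by the
  broadband recorder on the array;
* A-tag-style *event streams*: one row per threshold-crossing pulse on
  each stereo sensor, carrying the event time (quantized to the
  instrument's 0.5-ms clock), the two channel peak-to-peak pressures
  (Pa) and the inter-hydrophone time difference (quantized to a
  configurable TDOA resolution);
* a truth table aligned 1:1 with the emitted clicks.

The click model is a Gaussian-enveloped tone pip — the standard
surrogate for narrow-band high-frequency porpoise clicks (energy
concentrated near 125-140 kHz, duration tens of microseconds).
Propagation applies spherical spreading plus Francois-Garrison
absorption, ``TL = 20 log10(r) + r * alpha``, per sensor; an optional
surface-reflection ghost and band-limited vessel noise can be mixed in.

The array mirrors a vertical coastal mooring: sensors at 2 m (current
meter), 3 m and 4 m (stereo pulse-event loggers with 190-mm baselines)
and 3.5 m (calibrated recorder).  All randomness flows from a single
seed; per-train substreams are derived deterministically so scenes are
byte-identical across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .seawater import WaterState, absorption_coefficient, sound_speed

__all__ = [
    "ArrayGeometry",
    "VesselNoise",
    "SurfaceGhost",
    "SceneConfig",
    "TrainWaveform",
    "SceneData",
    "synth_click",
    "render_scene",
    "synth_covariate_table",
]

UPA_PER_PA = 1.0e6


@dataclass(frozen=True)
class ArrayGeometry:
    """Vertical-array geometry and instrument clocking.

    ``sensor_depths`` lists, top to bottom: current meter, upper A-tag,
    recorder, lower A-tag.  Each A-tag is a vertically oriented stereo
    pair with hydrophones ``stereo_baseline`` apart, centred on its
    listed depth.
    """

    sensor_depths: tuple[float, ...] = (2.0, 3.0, 3.5, 4.0)
    stereo_baseline: float = 0.190
    waveform_rate: float = 576_000.0
    event_time_resolution: float = 5e-4
    tdoa_resolution: float = 2e-6

    def __post_init__(self) -> None:
        if self.stereo_baseline <= 0:
            raise ValueError("stereo_baseline must be > 0")
        if self.waveform_rate <= 0 or self.event_time_resolution <= 0:
            raise ValueError("rates must be > 0")
        if list(self.sensor_depths) != sorted(self.sensor_depths):
            raise ValueError("sensor_depths must be strictly increasing")

    @property
    def atag_depths(self) -> tuple[float, float]:
        return (self.sensor_depths[1], self.sensor_depths[3])

    @property
    def recorder_depth(self) -> float:
        return self.sensor_depths[2]

    @property
    def vertical_baseline(self) -> float:
        return self.sensor_depths[3] - self.sensor_depths[1]


@dataclass(frozen=True)
class VesselNoise:
    present: bool = False
    level_db: float = 110.0  # dB re 1 uPa rms, broadband
    cutoff_hz: float = 30_000.0  # low-frequency emphasis: lowpass corner


@dataclass(frozen=True)
class SurfaceGhost:
    enabled: bool = False
    # default inside the < 1 ms reflection-exclusion window even after
    # quantization to the 0.5 ms event clock
    delay_s: float = 4e-4  # arrival lag behind the direct path
    attenuation_db: float = 6.0
    # whether the ghost also triggers logger events (an off-axis surface
    # reflection may contaminate the recorder yet miss the event logger)
    in_events: bool = True


@dataclass(frozen=True)
class SceneConfig:
    """Declarative description of one synthetic scene.

    Per-train geometry may be given explicitly via ``source_positions``
    (horizontal range m, depth m, bearing deg); otherwise positions are
    drawn from the stated ranges.  ``train_ici_pattern``, if given, is
    the list of inter-click intervals used for every train (its length
    + 1 sets the click count); otherwise trains draw a constant ICI in
    ``ici_range_s`` with ``ici_jitter`` multiplicative jitter and a
    click count in ``n_clicks_range``.
    """

    source_level: float = 175.0  # dB re 1 uPa pp @ 1 m
    center_frequency: float = 134.0  # kHz
    envelope_sigma: float = 15e-6  # s
    n_trains: int = 10
    train_ici_pattern: tuple[float, ...] | None = None
    source_positions: tuple[tuple[float, float, float], ...] | None = None
    range_span: tuple[float, float] = (5.0, 50.0)
    depth_span: tuple[float, float] = (2.0, 6.0)
    ici_range_s: tuple[float, float] = (0.030, 0.060)
    ici_jitter: float = 0.02
    n_clicks_range: tuple[int, int] = (8, 16)
    amplitude_profile: str = "rise_fall"  # or "flat", "ramp"
    amplitude_floor: float = 0.35
    water: WaterState = field(default_factory=lambda: WaterState(21.0, 32.0, 3.5))
    ambient_noise_level: float = 85.0  # dB re 1 uPa rms, in-band
    vessel_noise: VesselNoise = field(default_factory=VesselNoise)
    surface_ghost: SurfaceGhost = field(default_factory=SurfaceGhost)
    detector_threshold_pa: float = 6.3  # zero-to-peak, A-tag
    clip_level_db: float = 172.0  # recorder clip, dB re 1 uPa
    low_channel_response: float = 0.75  # 70-kHz channel gain at the pip frequency
    event_amp_jitter: float = 0.01
    day_night_label: str = "day"
    pad_s: float = 0.15  # quiet lead-in/out around each train
    seed: int = 0

    def __post_init__(self) -> None:
        if not (120.0 <= self.source_level <= 210.0):
            raise ValueError("source_level outside [120, 210] dB pp")
        if not (100.0 <= self.center_frequency <= 160.0):
            raise ValueError("center_frequency outside NBHF band [100, 160] kHz")
        if self.train_ici_pattern is not None and any(
            i <= 0 for i in self.train_ici_pattern
        ):
            raise ValueError("all ICIs must be > 0")


@dataclass
class TrainWaveform:
    """Calibrated recorder segment covering one click train."""

    train_id: int
    t0: float  # absolute scene time of sample 0, s
    rate: float
    data: np.ndarray  # uPa, shape (n_samples,)

    def snippet(self, t_center: float, n_samples: int) -> np.ndarray:
        i = int(round((t_center - self.t0) * self.rate))
        half = n_samples // 2
        lo, hi = i - half, i - half + n_samples
        lo_c, hi_c = max(lo, 0), min(hi, len(self.data))
        out = np.zeros(n_samples)
        out[lo_c - lo : lo_c - lo + (hi_c - lo_c)] = self.data[lo_c:hi_c]
        return out


@dataclass
class SceneData:
    events: pd.DataFrame
    truth: pd.DataFrame
    waveforms: list[TrainWaveform]
    config: SceneConfig
    geometry: ArrayGeometry
    alpha_db_per_m: float
    sound_speed: float

    def waveform_for(self, train_id: int) -> TrainWaveform | None:
        for w in self.waveforms:
            if w.train_id == train_id:
                return w
        return None


def synth_click(
    center_frequency_khz: float,
    envelope_sigma_s: float,
    amplitude_pa: float,
    rate_hz: float,
    n_sigma: float = 6.0,
) -> np.ndarray:
    """Gaussian-enveloped tone pip, calibrated to a peak-to-peak amplitude.

    Returns a snippet (Pa) whose measured peak-to-peak amplitude equals
    ``2 * amplitude_pa`` (the waveform is rescaled after synthesis so the
    calibration is exact regardless of carrier/envelope phase) and whose
    spectral peak sits at ``center_frequency_khz``.
    """
    f = center_frequency_khz * 1e3
    if f >= rate_hz / 2:
        raise ValueError(
            f"carrier {f} Hz at or above Nyquist ({rate_hz / 2} Hz)"
        )
    if envelope_sigma_s * rate_hz < 8.0:
        raise ValueError("envelope_sigma too short for the sampling rate")
    if amplitude_pa == 0.0:
        n = 2 * int(np.ceil(n_sigma * envelope_sigma_s * rate_hz)) + 1
        return np.zeros(n)
    half = int(np.ceil(n_sigma * envelope_sigma_s * rate_hz))
    t = np.arange(-half, half + 1) / rate_hz
    w = np.exp(-(t * t) / (2.0 * envelope_sigma_s**2)) * np.cos(
        2.0 * np.pi * f * t
    )
    pp = w.max() - w.min()
    return w * (2.0 * amplitude_pa / pp)


def _profile(n: int, kind: str, floor: float) -> np.ndarray:
    """Per-click source-amplitude scan factors across a train."""
    if kind == "flat":
        return np.ones(n)
    if kind == "ramp":
        return np.linspace(floor, 1.0, n)
    if kind == "rise_fall":
        # symmetric rise-then-fall; interior maximum guaranteed for n >= 3
        h = np.hanning(n + 2)[1:-1]
        return floor + (1.0 - floor) * h
    raise ValueError(f"unknown amplitude_profile {kind!r}")


def _quantize(x: np.ndarray | float, step: float) -> np.ndarray | float:
    if step <= 0:
        return x
    return np.round(np.asarray(x) / step) * step


def _train_plan(cfg: SceneConfig, rng: np.random.Generator, k: int):
    """Geometry + timing for train k (deterministic given seed)."""
    if cfg.source_positions is not None:
        x, z, brg = cfg.source_positions[k % len(cfg.source_positions)]
    else:
        x = rng.uniform(*cfg.range_span)
        z = rng.uniform(*cfg.depth_span)
        brg = rng.uniform(-180.0, 180.0)
    if x <= 0:
        raise ValueError("source horizontal range must be > 0")
    if cfg.train_ici_pattern is not None:
        icis = np.asarray(cfg.train_ici_pattern, dtype=float)
    else:
        ici = rng.uniform(*cfg.ici_range_s)
        n = int(rng.integers(cfg.n_clicks_range[0], cfg.n_clicks_range[1] + 1))
        icis = ici * (1.0 + cfg.ici_jitter * rng.standard_normal(n - 1))
        icis = np.clip(icis, 1.5e-3, 0.199)
    return x, z, brg, icis


def render_scene(
    config: SceneConfig, geometry: ArrayGeometry | None = None
) -> SceneData:
    """Render a scene into waveforms, event streams and a truth table.

    Each emitted click is delayed by ``r/c`` and attenuated by
    ``20 log10(r) + r * alpha`` per sensor; the recorder waveform adds
    ambient (and optional vessel) noise and the optional surface ghost,
    then clips at the stated clip level.  Event streams hold one row per
    pulse whose zero-to-peak pressure on the A-tag's high-frequency
    channel exceeds the detector threshold, with times quantized to the
    event clock and TDOAs to the TDOA resolution.
    """
    geom = geometry or ArrayGeometry()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    train_seeds = rng.integers(0, 2**31 - 1, size=cfg.n_trains)

    c = sound_speed(cfg.water)
    alpha = absorption_coefficient(cfg.water, cfg.center_frequency)
    a_src_upa = 10.0 ** (cfg.source_level / 20.0) / 2.0  # zero-to-peak, uPa
    clip_upa = 10.0 ** (cfg.clip_level_db / 20.0)
    amb_upa = 10.0 ** (cfg.ambient_noise_level / 20.0)
    fs = geom.waveform_rate
    half_b = geom.stereo_baseline / 2.0
    z_mid = geom.recorder_depth

    pip = synth_click(
        cfg.center_frequency, cfg.envelope_sigma, 0.5, fs
    )  # unit pp=1 template
    npip = len(pip)

    events_rows: list[dict] = []
    truth_rows: list[dict] = []
    waveforms: list[TrainWaveform] = []
    t_scene = 0.0

    for k in range(cfg.n_trains):
        trng = np.random.default_rng(train_seeds[k])
        x, z, brg, icis = _train_plan(cfg, trng, k)
        n_clicks = len(icis) + 1
        emit = t_scene + cfg.pad_s + np.concatenate([[0.0], np.cumsum(icis)])
        prof = _profile(n_clicks, cfg.amplitude_profile, cfg.amplitude_floor)

        r_true = float(np.hypot(x, z - z_mid))
        az_true = float(np.degrees(np.arctan2(z - z_mid, x)))

        # --- recorder waveform -------------------------------------------
        dur = (emit[-1] - emit[0]) + 2 * cfg.pad_s
        nsamp = int(np.ceil(dur * fs)) + npip
        wav = trng.normal(0.0, amb_upa, nsamp)
        if cfg.vessel_noise.present:
            v_upa = 10.0 ** (cfg.vessel_noise.level_db / 20.0)
            b, a = sps.butter(
                4, cfg.vessel_noise.cutoff_hz / (fs / 2.0), btype="low"
            )
            vn = sps.lfilter(b, a, trng.standard_normal(nsamp))
            wav += vn * (v_upa / max(np.std(vn), 1e-30))

        r_rec = float(np.hypot(x, z - geom.recorder_depth))
        tl_rec = 20.0 * np.log10(r_rec) + r_rec * alpha
        a_rec = a_src_upa * 10.0 ** (-tl_rec / 20.0)
        t0_wav = emit[0] - cfg.pad_s
        for j in range(n_clicks):
            t_arr = emit[j] + r_rec / c
            i0 = int(round((t_arr - t0_wav) * fs)) - npip // 2
            amp = a_rec * prof[j]
            if 0 <= i0 and i0 + npip <= nsamp:
                wav[i0 : i0 + npip] += pip * (2.0 * amp)
            if cfg.surface_ghost.enabled:
                g0 = i0 + int(round(cfg.surface_ghost.delay_s * fs))
                gamp = amp * 10.0 ** (-cfg.surface_ghost.attenuation_db / 20.0)
                if 0 <= g0 and g0 + npip <= nsamp:
                    wav[g0 : g0 + npip] += pip * (2.0 * gamp)
        np.clip(wav, -clip_upa, clip_upa, out=wav)
        waveforms.append(TrainWaveform(k, t0_wav, fs, wav))

        # --- A-tag event streams -----------------------------------------
        for depth, sensor in zip(geom.atag_depths, ("atag_3m", "atag_4m")):
            r_up = np.hypot(x, z - (depth - half_b))
            r_dn = np.hypot(x, z - (depth + half_b))
            r_s = np.hypot(x, z - depth)
            tl = 20.0 * np.log10(r_s) + r_s * alpha
            a_pa = (a_src_upa / UPA_PER_PA) * 10.0 ** (-tl / 20.0)
            tdoa = (r_up - r_dn) / c  # >0 when source is deeper
            jit = 1.0 + cfg.event_amp_jitter * trng.standard_normal(n_clicks)
            arrivals = [
                (emit[j] + r_s / c, a_pa * prof[j] * jit[j], False)
                for j in range(n_clicks)
            ]
            if cfg.surface_ghost.enabled and cfg.surface_ghost.in_events:
                g = 10.0 ** (-cfg.surface_ghost.attenuation_db / 20.0)
                arrivals += [
                    (t + cfg.surface_ghost.delay_s, a * g, True)
                    for (t, a, _) in list(arrivals)
                ]
            for t_arr, amp, is_ghost in sorted(arrivals):
                if amp < cfg.detector_threshold_pa:
                    continue
                events_rows.append(
                    {
                        "time": float(
                            _quantize(t_arr, geom.event_time_resolution)
                        ),
                        "pp_ch1": 2.0 * amp,  # high-frequency channel, Pa pp
                        "pp_ch2": 2.0 * amp * cfg.low_channel_response,
                        "tdoa": float(_quantize(tdoa, geom.tdoa_resolution)),
                        "sensor_id": sensor,
                        "train_id": k,
                        "is_ghost": bool(is_ghost),
                    }
                )

        # --- truth --------------------------------------------------------
        rl_true = cfg.source_level - tl_rec
        is_buzz_train = bool(
            np.any(np.convolve((icis < 0.010).astype(int), np.ones(4), "valid") >= 4)
        ) if len(icis) >= 4 else False
        for j in range(n_clicks):
            truth_rows.append(
                {
                    "train_id": k,
                    "click_index": j,
                    "emit_time": float(emit[j]),
                    "range_true": r_true,
                    "azimuth_true": az_true,
                    "rl_true_pp_db": float(
                        rl_true + 20.0 * np.log10(prof[j])
                    ),
                    "ici_true": float(icis[j - 1]) if j > 0 else np.nan,
                    "is_buzz": is_buzz_train,
                    "vessel": bool(cfg.vessel_noise.present),
                    "day_night": cfg.day_night_label,
                }
            )
        t_scene = emit[-1] + 2 * cfg.pad_s + 0.3  # >200 ms gap between trains

    events = pd.DataFrame(
        events_rows,
        columns=[
            "time", "pp_ch1", "pp_ch2", "tdoa", "sensor_id", "train_id",
            "is_ghost",
        ],
    )
    if len(events) == 0:
        warnings.warn(
            "detector threshold above all received levels: empty event stream",
            stacklevel=2,
        )
    else:
        events = events.sort_values(["sensor_id", "time"], kind="mergesort")
        events = events.reset_index(drop=True)
    truth = pd.DataFrame(truth_rows)
    return SceneData(events, truth, waveforms, cfg, geom, alpha, c)


# ---------------------------------------------------------------------------
# Covariate/response table emulator for the GLM stage
# ---------------------------------------------------------------------------

_GAMMA_SHAPES = {"bw3": 8.0, "duration": 19.0, "ici": 3.5, "n_clicks": 2.0}
_GAMMA_BASE_MEANS = {"bw3": 25.0, "duration": 65.0, "ici": 41.0, "n_clicks": 21.0}
# log-link night effects mirroring the observed directions: wider bandwidth,
# shorter duration, shorter ICI at night.
_GAMMA_NIGHT_EFFECTS = {"bw3": 0.20, "duration": -0.20, "ici": -0.15, "n_clicks": 0.0}


def synth_covariate_table(
    n: int,
    effects: dict[str, float] | None = None,
    noise_sd: float = 5.0,
    seed: int = 0,
    asl_intercept: float = 174.0,
    gamma_night_effects: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-click covariate/response table with known statistical structure.

    Gaussian ASL responses follow the linear predictor
    ``asl_intercept + b_dn*night + b_v*vessel + b_int*night*vessel +
    b_T*(T - 21)`` with N(0, noise_sd) errors; the positive responses
    (-3 dB bandwidth, click duration, ICI, clicks per train) are
    gamma-distributed with log-link day/night effects.  Covariate spans
    match the observed field ranges (temperature 12-29 degC, flow 1-60
    cm/s, noise level ~117 +/- 2 dB).

    ``effects`` keys: ``day_night`` (dB, night minus day), ``vessel``
    (dB), ``interaction`` (dB), ``temperature_slope`` (dB/degC).
    """
    if n < 20:
        raise ValueError("n must be >= 20")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    eff = {"day_night": 0.0, "vessel": 0.0, "interaction": 0.0,
           "temperature_slope": 0.0}
    eff.update(effects or {})
    gnight = dict(_GAMMA_NIGHT_EFFECTS)
    gnight.update(gamma_night_effects or {})

    rng = np.random.default_rng(seed)
    night = rng.integers(0, 2, n)
    vessel = rng.integers(0, 2, n)
    temp = rng.uniform(12.0, 29.0, n)
    flow = rng.uniform(1.0, 60.0, n)
    noise_level = np.clip(rng.normal(117.0, 2.0, n), 112.0, 124.0)
    site = np.where(rng.integers(0, 2, n) == 1, "M", "S")

    mu_asl = (
        asl_intercept
        + eff["day_night"] * night
        + eff["vessel"] * vessel
        + eff["interaction"] * night * vessel
        + eff["temperature_slope"] * (temp - 21.0)
    )
    asl = mu_asl + rng.normal(0.0, noise_sd, n)

    out = {
        "day_night": np.where(night == 1, "night", "day"),
        "vessel": np.where(vessel == 1, "presence", "absence"),
        "temperature": temp,
        "flow": flow,
        "noise_level": noise_level,
        "site": site,
        "asl": asl,
    }
    for resp, base in _GAMMA_BASE_MEANS.items():
        shape = _GAMMA_SHAPES[resp]
        if shape <= 0:
            raise ValueError("gamma shape must be > 0")
        mu = np.exp(np.log(base) + gnight[resp] * night)
        out[resp] = rng.gamma(shape, mu / shape)
    return pd.DataFrame(out)
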