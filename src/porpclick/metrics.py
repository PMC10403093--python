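"""Click and click-train parameter extraction.

Seven quantities are measured per accepted on-axis click: apparent
source level (ASL), peak frequency, center frequency, -3 dB bandwidth,
click duration, the train's inter-click interval (ICI) around the
measured click, and the number of clicks per train.

ASL follows the passive sonar equation, ``ASL = RL + TL`` with
``TL = 20 log10(r) + r * alpha`` (spherical spreading plus
Francois-Garrison absorption).  Received level is peak-to-peak
re 1 uPa, consistent with the peak-to-peak SNR rule (an rms received
level is available via ``rl_convention="rms"``).

The *center frequency* here is the midpoint of the two -3 dB crossing
frequencies — a bespoke convention of this analysis chain, NOT the
spectral centroid — and the -3 dB bandwidth is the distance between
those crossings, found by walking outward from the spectral peak with
linear interpolation between FFT bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import get_window, hilbert
from sklearn.base import BaseEstimator, TransformerMixin

from .detect import ClickTrain

__all__ = [
    "ClickMetrics",
    "spectral_params",
    "click_duration",
    "asl",
    "train_ici",
    "ClickParameterExtractor",
]


class BandError(ValueError):
    """-3 dB crossings fall outside the analysis band."""


class DegenerateClickError(ValueError):
    """Click envelope never exceeds the background level."""


@dataclass(frozen=True)
class ClickMetrics:
    """The per-click measurement record (one row of the output table)."""

    asl: float  # dB re 1 uPa pp
    rl: float  # dB re 1 uPa pp
    tl: float  # dB
    peak_frequency: float  # kHz
    center_frequency: float  # kHz
    bw3: float  # kHz
    duration: float  # us
    ici: float  # ms
    n_clicks: int
    range_m: float

    def __post_init__(self) -> None:
        if not np.isclose(self.asl, self.rl + self.tl):
            raise ValueError("ASL must equal RL + TL exactly")
        if self.bw3 <= 0 or self.duration <= 0:
            raise ValueError("bandwidth and duration must be > 0")


def _cross(freqs, pdb, i_from, i_to, level):
    """Linear-interpolated frequency where pdb crosses ``level``."""
    step = 1 if i_to > i_from else -1
    prev = i_from
    for i in range(i_from + step, i_to + step, step):
        if pdb[i] < level:
            f0, f1 = freqs[prev], freqs[i]
            p0, p1 = pdb[prev], pdb[i]
            return f0 + (level - p0) * (f1 - f0) / (p1 - p0)
        prev = i
    return None


def spectral_params(
    snippet: np.ndarray,
    rate: float,
    nfft: int = 4096,
    window: str = "hann",
) -> tuple[float, float, float]:
    """Peak frequency, center frequency and -3 dB bandwidth, in kHz.

    The snippet is windowed, zero-padded to ``nfft`` (~140 Hz bins at
    576 kHz) and Fourier transformed.  The peak frequency is the argmax
    of the power spectrum; walking outward from it, the first crossings
    3 dB below the peak (linear interpolation between bins) give the
    band edges; the center frequency is their midpoint and the
    bandwidth their separation.
    """
    x = np.asarray(snippet, dtype=float)
    if len(x) < 512:
        # centre-pad to the analysis window so the taper does not bite
        # into a short pip and widen its measured bandwidth
        pad = 512 - len(x)
        x = np.pad(x, (pad // 2, pad - pad // 2))
    w = get_window(window, len(x))
    spec = np.abs(np.fft.rfft(x * w, n=max(nfft, len(x))))
    freqs = np.fft.rfftfreq(max(nfft, len(x)), d=1.0 / rate)
    with np.errstate(divide="ignore"):
        pdb = 20.0 * np.log10(np.maximum(spec, 1e-300))
    ipk = int(np.argmax(pdb))
    level = pdb[ipk] - 3.0
    f_lo = _cross(freqs, pdb, ipk, 0, level)
    f_hi = _cross(freqs, pdb, ipk, len(freqs) - 1, level)
    if f_lo is None or f_hi is None:
        raise BandError("-3 dB crossings outside the analysis band")
    peak = freqs[ipk] / 1e3
    return peak, (f_lo + f_hi) / 2.0 / 1e3, (f_hi - f_lo) / 1e3


def click_duration(
    snippet: np.ndarray,
    rate: float,
    background_level: float,
    multiplier: float = 1.0,
) -> float:
    """Click duration in microseconds.

    Duration is the time from when the analytic-signal envelope first
    exceeds ``multiplier * background_level`` to when it last does.
    """
    env = np.abs(hilbert(np.asarray(snippet, dtype=float)))
    thr = multiplier * background_level
    above = np.flatnonzero(env > thr)
    if len(above) == 0:
        raise DegenerateClickError(
            "envelope never exceeds the background level"
        )
    return (above[-1] - above[0]) / rate * 1e6


def asl(rl_db: float, range_m: float, alpha_db_per_m: float) -> tuple[float, float]:
    """Transmission loss and apparent source level.

    ``TL = 20 log10(r) + r * alpha``; ``ASL = RL + TL``.  Returns
    ``(tl, asl)`` in dB.
    """
    if range_m <= 0:
        raise ValueError("range must be > 0")
    if alpha_db_per_m < 0:
        raise ValueError("alpha must be >= 0")
    tl = 20.0 * np.log10(range_m) + range_m * alpha_db_per_m
    return tl, rl_db + tl


def train_ici(train: ClickTrain) -> float:
    """Mean of the ICIs flanking the max-amplitude click, in ms.

    The max-amplitude click must be interior to the train (guaranteed
    by the rise-then-fall screening criterion).
    """
    i = train.max_amplitude_index
    if i in (0, train.n_clicks - 1):
        raise ValueError(
            "max-amplitude click at the train edge; train should have been "
            "rejected by screening"
        )
    ici = train.ici_series
    return float((ici[i - 1] + ici[i]) / 2.0) * 1e3


def received_level_pp(snippet: np.ndarray) -> float:
    """Peak-to-peak received level, dB re 1 uPa (snippet in uPa)."""
    pp = float(np.max(snippet) - np.min(snippet))
    if pp <= 0:
        raise ValueError("non-positive peak-to-peak amplitude")
    return 20.0 * np.log10(pp)


class ClickParameterExtractor(BaseEstimator, TransformerMixin):
    """Run-state transformer: accepted on-axis clicks -> metrics table.

    Adds a ``metrics`` DataFrame (one row per accepted click) to the
    state.  ``alpha`` is re-evaluated at each click's measured peak
    frequency when a water state is available, else at the fallback
    frequency (134 kHz by default, the observed mean peak frequency).
    """

    def __init__(
        self,
        nfft: int = 4096,
        window: str = "hann",
        noise_span_s: float = 5e-3,
        duration_multiplier: float = 1.0,
        rl_convention: str = "pp",
        fallback_frequency_khz: float = 134.0,
        use_true_range: bool = False,
    ):
        self.nfft = nfft
        self.window = window
        self.noise_span_s = noise_span_s
        self.duration_multiplier = duration_multiplier
        self.rl_convention = rl_convention
        self.fallback_frequency_khz = fallback_frequency_khz
        self.use_true_range = use_true_range

    def fit(self, X=None, y=None):
        return self

    def transform(self, state: dict) -> dict:
        from .seawater import absorption_coefficient

        trains = {t.train_index: t for t in state["trains"]}
        water = state.get("water")
        alpha_fixed = state.get("alpha")
        rows = []
        for oa in state["onaxis"]:
            if not oa.accepted:
                continue
            tr = trains[oa.train_index]
            peak_f, center_f, bw3 = spectral_params(
                oa.snippet, oa.rate, self.nfft, self.window
            )
            # band invariant: the center sits inside the -3 dB band
            assert bw3 > 0 and abs(center_f - peak_f) <= bw3
            if water is not None:
                alpha = absorption_coefficient(water, peak_f)
            elif alpha_fixed is not None:
                alpha = alpha_fixed
            else:
                raise ValueError("state must carry 'water' or 'alpha'")
            if self.rl_convention == "pp":
                rl = received_level_pp(oa.snippet)
            elif self.rl_convention == "rms":
                x = oa.snippet - np.mean(oa.snippet)
                rl = 20.0 * np.log10(float(np.sqrt(np.mean(x * x))))
            else:
                raise ValueError(f"unknown rl_convention {self.rl_convention!r}")
            rng = oa.range_m
            if self.use_true_range and "true_ranges" in state:
                rng = state["true_ranges"][oa.train_index]
            tl, asl_db = asl(rl, rng, alpha)
            # background for the duration threshold: envelope pp of a
            # pre-click window, carried on the click when available
            noise = oa.noise_window
            if noise is None or len(noise) == 0:
                n_edge = max(int(0.05 * len(oa.snippet)), 8)
                noise = oa.snippet[:n_edge]
            bg = float(np.max(np.abs(hilbert(noise))))
            dur = click_duration(
                oa.snippet, oa.rate, bg, self.duration_multiplier
            )
            m = ClickMetrics(
                asl=asl_db, rl=rl, tl=tl,
                peak_frequency=peak_f, center_frequency=center_f, bw3=bw3,
                duration=dur, ici=train_ici(tr), n_clicks=tr.n_clicks,
                range_m=rng,
            )
            rows.append(
                {"train_index": oa.train_index, **m.__dict__}
            )
        out = dict(state)
        out["metrics"] = pd.DataFrame(
            rows,
            columns=[
                "train_index", "asl", "rl", "tl", "peak_frequency",
                "center_frequency", "bw3", "duration", "ici", "n_clicks",
                "range_m",
            ],
        )
        return out
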