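"""Physical properties of the recording medium.

Everything downstream of the sonar equation needs two numbers from the
water column: the sound speed ``c`` (for TDOA bearings and propagation
delays) and the frequency-dependent absorption coefficient ``alpha``
(for the transmission loss ``TL = 20 log10(r) + r * alpha``).

``alpha`` follows the Francois & Garrison empirical model, the standard
in underwater acoustics: three additive relaxation/viscosity terms for
boric acid, magnesium sulfate and pure water, each a function of
temperature, salinity, depth and pH.  The model is evaluated in dB/km
and returned in dB/m, the unit the transmission-loss formula uses.

Sound speed uses Mackenzie's (1981) nine-term empirical formula, valid
for T in [-2, 30] degC, S in [25, 40] PSU and depth to 8 km — amply
covering a shallow coastal mooring.  The formula choice is a package
decision (no single formula is canonical for shallow water); all
geometry takes ``c`` as a plain parameter so it is swappable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WaterState",
    "PropagationConstants",
    "absorption_coefficient",
    "sound_speed",
]


@dataclass(frozen=True)
class WaterState:
    """Temperature/salinity/depth/pH state of the water column.

    Parameters
    ----------
    temperature : float
        Water temperature, degC.  Valid range [-2, 40].
    salinity : float
        Practical salinity, PSU.  Valid range [0, 45].
    depth : float
        Depth of the propagation path, m (>= 0).
    ph : float
        Seawater pH; defaults to 8.0, typical of coastal seawater.
        Valid range [6, 9].
    """

    temperature: float
    salinity: float
    depth: float = 3.5
    ph: float = 8.0

    def __post_init__(self) -> None:
        if not (-2.0 <= self.temperature <= 40.0):
            raise ValueError(
                f"temperature {self.temperature!r} degC outside [-2, 40]"
            )
        if not (0.0 <= self.salinity <= 45.0):
            raise ValueError(f"salinity {self.salinity!r} PSU outside [0, 45]")
        if self.depth < 0.0:
            raise ValueError(f"depth {self.depth!r} m must be >= 0")
        if not (6.0 <= self.ph <= 9.0):
            raise ValueError(f"ph {self.ph!r} outside [6, 9]")


@dataclass(frozen=True)
class PropagationConstants:
    """Absorption (dB/m, at a stated frequency) and sound speed (m/s)."""

    alpha: float
    sound_speed: float
    frequency_khz: float = field(default=134.0)


def absorption_coefficient(state: WaterState, frequency_khz: float) -> float:
    """Francois-Garrison seawater absorption, dB per metre.

    Parameters
    ----------
    state : WaterState
    frequency_khz : float
        Acoustic frequency in kHz (> 0); NBHF clicks sit near 130 kHz.

    Returns
    -------
    float
        Total absorption coefficient in dB/m (boric-acid +
        magnesium-sulfate + pure-water contributions).
    """
    f = float(frequency_khz)
    if f < 0:
        raise ValueError(f"frequency {f!r} kHz must be >= 0")
    if f == 0.0:
        return 0.0

    T = state.temperature
    S = state.salinity
    D = state.depth
    pH = state.ph
    theta = T + 273.0

    # Sound speed surrogate used inside the FG fit (their own expression,
    # not Mackenzie's -- the model was calibrated with it).
    c = 1412.0 + 3.21 * T + 1.19 * S + 0.0167 * D

    # Boric acid
    a1 = (8.86 / c) * 10.0 ** (0.78 * pH - 5.0)
    f1 = 2.8 * np.sqrt(S / 35.0) * 10.0 ** (4.0 - 1245.0 / theta)

    # Magnesium sulfate
    a2 = 21.44 * (S / c) * (1.0 + 0.025 * T)
    p2 = 1.0 - 1.37e-4 * D + 6.2e-9 * D * D
    f2 = (8.17 * 10.0 ** (8.0 - 1990.0 / theta)) / (1.0 + 0.0018 * (S - 35.0))

    # Pure water (viscosity); two temperature branches
    if T <= 20.0:
        a3 = 4.937e-4 - 2.59e-5 * T + 9.11e-7 * T * T - 1.50e-8 * T**3
    else:
        a3 = 3.964e-4 - 1.146e-5 * T + 1.45e-7 * T * T - 6.5e-10 * T**3
    p3 = 1.0 - 3.83e-5 * D + 4.9e-10 * D * D

    f2_ = f * f
    alpha_db_km = (
        a1 * f1 * f2_ / (f1 * f1 + f2_)
        + a2 * p2 * f2 * f2_ / (f2 * f2 + f2_)
        + a3 * p3 * f2_
    )
    return alpha_db_km / 1000.0


def sound_speed(state: WaterState) -> float:
    """Sound speed in seawater, m/s (Mackenzie 1981)."""
    T = state.temperature
    S = state.salinity
    D = state.depth
    return (
        1448.96
        + 4.591 * T
        - 5.304e-2 * T * T
        + 2.374e-4 * T**3
        + 1.340 * (S - 35.0)
        + 1.630e-2 * D
        + 1.675e-7 * D * D
        - 1.025e-2 * T * (S - 35.0)
        - 7.139e-13 * T * D**3
    )


def propagation_constants(
    state: WaterState, frequency_khz: float = 134.0
) -> PropagationConstants:
    """Bundle ``alpha`` and ``c`` for a given state and frequency."""
    return PropagationConstants(
        alpha=absorption_coefficient(state, frequency_khz),
        sound_speed=sound_speed(state),
        frequency_khz=frequency_khz,
    )
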