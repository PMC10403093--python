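"""File I/O: calibrated WAV segments, tabular stage outputs, configs.

Waveforms are stored as float32 WAV with frames scaled to the recorder
clip level (so +/-1.0 in the file corresponds to the stated clip level,
dB re 1 uPa); the calibration lives in a JSON sidecar next to each WAV.
Tables are plain CSV.  Supplementary-style per-click tables (one row
per on-axis click with click, train and environmental parameters) are
read from CSV or XLSX with a configurable column mapping.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "write_calibrated_wav",
    "read_calibrated_wav",
    "read_clicks_table",
    "DEFAULT_COLUMN_MAP",
]


def write_calibrated_wav(
    path: str | Path,
    data_upa: np.ndarray,
    rate: float,
    clip_level_db: float = 172.0,
    t0: float = 0.0,
) -> None:
    path = Path(path)
    clip = 10.0 ** (clip_level_db / 20.0)
    frames = np.clip(np.asarray(data_upa) / clip, -1.0, 1.0).astype(np.float32)
    wavfile.write(path, int(rate), frames)
    sidecar = {
        "clip_level_db_re_1uPa": clip_level_db,
        "rate_hz": rate,
        "t0_s": t0,
        "unit": "full-scale = clip level",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_calibrated_wav(path: str | Path) -> tuple[np.ndarray, float, float]:
    """Returns (data in uPa, rate, t0)."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    rate, frames = wavfile.read(path)
    clip = 10.0 ** (meta["clip_level_db_re_1uPa"] / 20.0)
    return frames.astype(float) * clip, float(rate), float(meta.get("t0_s", 0.0))


# role -> column header in a supplementary-style export
DEFAULT_COLUMN_MAP = {
    "asl": "asl",
    "peak_frequency": "peak_frequency",
    "center_frequency": "center_frequency",
    "bw3": "bw3",
    "duration": "duration",
    "ici": "ici",
    "n_clicks": "n_clicks",
    "range_m": "range_m",
    "vessel": "vessel",
    "day_night": "day_night",
    "temperature": "temperature",
    "flow": "flow",
    "noise_level": "noise_level",
    "site": "site",
}


def read_clicks_table(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    site: str | None = None,
) -> pd.DataFrame:
    """Read a per-click parameter table from CSV or XLSX.

    ``column_map`` maps canonical roles (keys of
    :data:`DEFAULT_COLUMN_MAP`) to the file's column headers; unmapped
    roles absent from the file are simply omitted.  ``site`` adds a
    constant site column when the file does not carry one.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        raw = pd.read_excel(path)
    else:
        raw = pd.read_csv(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    cmap.update(column_map or {})
    out = {}
    for role, col in cmap.items():
        if col in raw.columns:
            out[role] = raw[col]
    df = pd.DataFrame(out)
    if site is not None and "site" not in df:
        df["site"] = site
    return df
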