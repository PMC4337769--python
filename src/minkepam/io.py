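"""Calibrated WAV I/O and selection-table (annotation) I/O.

WAV files are 16-bit PCM; the mapping between digital full scale and
absolute pressure is a calibration offset (dB re 1 µPa at full scale,
default 140) stored in a JSON sidecar next to the file, so waveforms
round-trip in µPa within quantization.  Selection tables are the
tab-separated annotation dialect standard in bioacoustics (Begin/End Time,
Low/High Freq, plus subtype and pulse-count annotation columns).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .scene import AcousticScene

__all__ = [
    "DEFAULT_FULL_SCALE_DB",
    "write_wav",
    "read_wav",
    "write_selection_table",
    "read_selection_table",
    "manifest_table",
]

DEFAULT_FULL_SCALE_DB = 140.0  # dB re 1 µPa at digital full scale

SELECTION_COLUMNS = [
    "Selection",
    "Begin Time (s)",
    "End Time (s)",
    "Low Freq (Hz)",
    "High Freq (Hz)",
    "Subtype",
    "N Pulses",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_wav(
    path: str | Path,
    samples_upa: np.ndarray,
    sample_rate_hz: float,
    full_scale_db: float = DEFAULT_FULL_SCALE_DB,
) -> Path:
    """Write a calibrated µPa waveform as 16-bit PCM + calibration sidecar."""
    path = Path(path)
    full_scale_upa = 10.0 ** (full_scale_db / 20.0)
    scaled = np.clip(samples_upa / full_scale_upa, -1.0, 1.0)
    wavfile.write(path, int(round(sample_rate_hz)), (scaled * 32767.0).astype(np.int16))
    _sidecar(path).write_text(
        json.dumps({"full_scale_db_re_1uPa": full_scale_db, "sample_rate_hz": sample_rate_hz})
    )
    return path


def read_wav(
    path: str | Path, full_scale_db: float | None = None
) -> tuple[np.ndarray, float]:
    """Read a WAV back to calibrated µPa; calibration from sidecar or argument."""
    path = Path(path)
    if full_scale_db is None:
        sc = _sidecar(path)
        if sc.exists():
            full_scale_db = float(json.loads(sc.read_text())["full_scale_db_re_1uPa"])
        else:
            full_scale_db = DEFAULT_FULL_SCALE_DB
    fs, data = wavfile.read(path)
    if data.dtype == np.int16:
        x = data.astype(float) / 32767.0
    elif np.issubdtype(data.dtype, np.floating):
        x = data.astype(float)
    else:
        x = data.astype(float) / np.abs(np.iinfo(data.dtype)).max
    return x * 10.0 ** (full_scale_db / 20.0), float(fs)


def manifest_table(scene: AcousticScene) -> pd.DataFrame:
    """Scene ground truth as a selection table data frame."""
    rows = []
    for i, tr in enumerate(scene.manifest, start=1):
        spec = tr.spec
        rows.append(
            {
                "Selection": i,
                "Begin Time (s)": tr.start_s,
                "End Time (s)": tr.end_s,
                "Low Freq (Hz)": spec.peak_freq_hz - spec.bandwidth_hz / 2.0,
                "High Freq (Hz)": spec.peak_freq_hz + spec.bandwidth_hz / 2.0,
                "Subtype": spec.subtype or spec.category,
                "N Pulses": spec.n_pulses,
            }
        )
    return pd.DataFrame(rows, columns=SELECTION_COLUMNS)


def write_selection_table(path: str | Path, table: pd.DataFrame) -> Path:
    """Write a tab-separated selection table."""
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_selection_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
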