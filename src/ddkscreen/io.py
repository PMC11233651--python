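"""WAV and manifest I/O (PCM 16-bit via scipy.io.wavfile)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile


def write_wav(path: str | Path, waveform: np.ndarray, sample_rate: int) -> None:
    """Write a mono float waveform as 16-bit PCM, peak-normalized to -1 dBFS."""
    waveform = np.asarray(waveform, dtype=float)
    peak = np.max(np.abs(waveform))
    if peak > 0:
        waveform = waveform / peak * 0.891  # -1 dBFS headroom
    wavfile.write(str(path), int(sample_rate), (waveform * 32767).astype(np.int16))


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a WAV file as float64 in [-1, 1] (mono; first channel if multi)."""
    sample_rate, data = wavfile.read(str(path))
    if data.ndim > 1:
        data = data[:, 0]
    if data.dtype == np.int16:
        data = data / 32768.0
    elif data.dtype == np.int32:
        data = data / 2147483648.0
    elif data.dtype == np.uint8:
        data = (data.astype(float) - 128) / 128.0
    return np.asarray(data, dtype=float), int(sample_rate)


def write_manifest(path: str | Path, manifest: pd.DataFrame) -> None:
    manifest.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
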