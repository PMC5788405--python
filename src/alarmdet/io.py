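"""WAV and annotation file input/output.

WAV support covers mono PCM 16-bit and float32 files; any sample rate is
accepted on read and resampled to the requested working rate (a warning is
logged when this happens).  Annotations are CSV label files with one row per
alarm signal interval: ``onset_sec, offset_sec, class_id, version``.
"""

from __future__ import annotations

import logging
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

log = logging.getLogger(__name__)

__all__ = ["read_wav", "write_wav", "read_annotations", "write_annotations"]

ANNOTATION_COLUMNS = ["onset_sec", "offset_sec", "class_id", "version"]


def read_wav(path: str | Path, target_rate: float | None = None) -> tuple[np.ndarray, float]:
    """Read a mono WAV file as float64 in [-1, 1].

    If ``target_rate`` is given and differs from the file's rate, the signal is
    resampled (polyphase) and a warning is logged.
    """
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError("mono required")
    if data.dtype == np.int16:
        wave = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        wave = data.astype(np.float64) / 2147483648.0
    elif data.dtype in (np.float32, np.float64):
        wave = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV sample format: {data.dtype}")
    if target_rate is not None and rate != target_rate:
        frac = Fraction(int(target_rate), int(rate)).limit_denominator(1000)
        log.warning("resampling %s from %d Hz to %d Hz", path, rate, target_rate)
        wave = resample_poly(wave, frac.numerator, frac.denominator)
        rate = target_rate
    return wave, float(rate)


def write_wav(
    path: str | Path, wave: np.ndarray, sample_rate: float, subtype: str = "pcm16"
) -> None:
    """Write a mono waveform as PCM 16-bit (default) or float32 WAV."""
    wave = np.asarray(wave, dtype=np.float64)
    if wave.ndim != 1:
        raise ValueError("mono required")
    if subtype == "pcm16":
        clipped = np.clip(wave, -1.0, 32767.0 / 32768.0)
        data = np.round(clipped * 32768.0).astype(np.int16)
    elif subtype == "float32":
        data = wave.astype(np.float32)
    else:
        raise ValueError(f"unsupported subtype: {subtype}")
    wavfile.write(str(path), int(sample_rate), data)


def write_annotations(path: str | Path, annotations: pd.DataFrame) -> None:
    """Write an annotation table (one row per alarm signal interval) to CSV."""
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotations.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    annotations[ANNOTATION_COLUMNS].to_csv(path, index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read an annotation CSV written by :func:`write_annotations`."""
    df = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation file missing columns: {missing}")
    return df[ANNOTATION_COLUMNS].copy()
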