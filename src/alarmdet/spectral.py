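"""Short-time spectral front-end.

Framing, windowing, zero-padded DFT, frequency-bin geometry and the generic
FF-LFBE (frequency-filtered logarithmic filter-bank energy) baseline features.

All analysis runs at a fixed working sample rate (24 kHz by default throughout
the package); the spectrum is one-sided and bin ``k`` has centre frequency
``k * sample_rate / dft_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Spectrogram",
    "FeatureSequence",
    "compute_spectrogram",
    "region_bins",
    "compute_ff_lfbe",
    "mel_filterbank",
]

#: floor applied to band energies before taking logs, keeps silence finite
LOG_FLOOR = 1e-12

_WINDOWS = ("rectangular", "hann")


@dataclass(frozen=True)
class Spectrogram:
    """One-sided complex short-time spectrum.

    ``values`` is indexed ``(bin k, frame l)``.  ``dft_size`` may exceed
    ``frame_length`` when frames are zero-padded before the DFT.
    """

    values: np.ndarray
    sample_rate: float
    frame_length: int
    hop: int
    dft_size: int
    window: str = "rectangular"

    def __post_init__(self) -> None:
        if self.hop <= 0:
            raise ValueError("hop must be positive")
        if self.frame_length > self.dft_size:
            raise ValueError("frame_length must not exceed dft_size")
        if self.values.shape[0] != self.dft_size // 2 + 1:
            raise ValueError("bin count must be dft_size // 2 + 1")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def bin_hz(self) -> float:
        """Centre-frequency spacing between adjacent bins."""
        return self.sample_rate / self.dft_size

    @property
    def bin_freqs(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_hz

    @property
    def frame_times(self) -> np.ndarray:
        """Start time of each frame in seconds."""
        return np.arange(self.n_frames) * self.hop / self.sample_rate

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)


@dataclass
class FeatureSequence:
    """Per-frame real feature vectors, one row per spectrogram frame."""

    vectors: np.ndarray  # (n_frames, dim)
    feature_kind: str
    frame_times: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be a (frames, dim) matrix")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("feature vectors must be finite")

    @property
    def n_frames(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


def compute_spectrogram(
    wave: np.ndarray,
    sample_rate: float,
    window: str = "rectangular",
    frame_length: int = 2048,
    hop: int = 1024,
    zero_pad: int = 0,
) -> Spectrogram:
    """Split ``wave`` into frames and take the one-sided DFT of each.

    The number of frames is ``floor((len(wave) - frame_length) / hop) + 1`` and
    the DFT length is ``frame_length + zero_pad``.
    """
    wave = np.asarray(wave)
    if wave.ndim != 1:
        raise ValueError("mono required")
    if window not in _WINDOWS:
        raise ValueError(f"unknown window {window!r}; expected one of {_WINDOWS}")
    if len(wave) < frame_length:
        raise ValueError("input too short: need at least one full frame")
    if zero_pad < 0:
        raise ValueError("zero_pad must be non-negative")
    if hop <= 0:
        raise ValueError("hop must be positive")

    frames = np.lib.stride_tricks.sliding_window_view(wave, frame_length)[::hop]
    if window == "hann":
        frames = frames * np.hanning(frame_length)
    dft_size = frame_length + zero_pad
    values = np.fft.rfft(frames, n=dft_size, axis=1).T
    return Spectrogram(
        values=values,
        sample_rate=float(sample_rate),
        frame_length=frame_length,
        hop=hop,
        dft_size=dft_size,
        window=window,
    )


def region_bins(
    center_freq: float, tolerance: float, spec: Spectrogram
) -> tuple[int, int]:
    """Inclusive bin range whose centre frequencies lie within ``center_freq ± tolerance``.

    Never empty: degenerates to the single nearest bin when the tolerance is
    narrower than the bin spacing.
    """
    nyquist = spec.sample_rate / 2.0
    if not 0.0 < center_freq < nyquist:
        raise ValueError(f"frequency out of band: {center_freq} Hz (Nyquist {nyquist} Hz)")
    bw = spec.bin_hz
    lo = int(np.ceil((center_freq - tolerance) / bw - 1e-9))
    hi = int(np.floor((center_freq + tolerance) / bw + 1e-9))
    lo = max(lo, 0)
    hi = min(hi, spec.n_bins - 1)
    if lo > hi:
        nearest = int(np.clip(round(center_freq / bw), 0, spec.n_bins - 1))
        return nearest, nearest
    return lo, hi


def _hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_filters: int, n_bins: int, sample_rate: float, dft_size: int) -> np.ndarray:
    """Triangular Mel-scaled filters spanning 0 Hz to Nyquist with 50% overlap.

    Returns a ``(n_filters, n_bins)`` weight matrix applied to the power
    spectrum.
    """
    nyquist = sample_rate / 2.0
    mel_pts = np.linspace(0.0, _hz_to_mel(nyquist), n_filters + 2)
    hz_pts = np.asarray(_mel_to_hz(mel_pts))
    bin_freqs = np.arange(n_bins) * sample_rate / dft_size
    fb = np.zeros((n_filters, n_bins))
    for j in range(n_filters):
        left, center, right = hz_pts[j], hz_pts[j + 1], hz_pts[j + 2]
        rising = (bin_freqs - left) / max(center - left, 1e-9)
        falling = (right - bin_freqs) / max(right - center, 1e-9)
        fb[j] = np.clip(np.minimum(rising, falling), 0.0, None)
    return fb


def compute_ff_lfbe(spec: Spectrogram, n_filters: int = 18) -> FeatureSequence:
    """Frequency-filtered log filter-bank energies with temporal derivatives.

    Per frame: Mel filter-bank energies -> log (floored) -> frequency filtering
    (difference between the log energy of the following and the preceding
    filter; one-sided at the band edges) -> append first-order temporal
    derivatives.  With 18 filters the output is 36-dimensional.

    The frequency-difference operator cancels any global gain applied to the
    waveform, making the static part amplitude-scale invariant.
    """
    if n_filters < 3:
        raise ValueError("need at least 3 filters")
    power = spec.magnitude**2
    fb = mel_filterbank(n_filters, spec.n_bins, spec.sample_rate, spec.dft_size)
    log_e = np.log(np.maximum(fb @ power, LOG_FLOOR))  # (n_filters, n_frames)

    ff = np.empty_like(log_e)
    ff[0] = log_e[1] - log_e[0]
    ff[1:-1] = log_e[2:] - log_e[:-2]
    ff[-1] = log_e[-1] - log_e[-2]

    if spec.n_frames > 1:
        delta = np.gradient(ff, axis=1)  # replicate-edge symmetric difference
    else:
        delta = np.zeros_like(ff)
    vectors = np.vstack([ff, delta]).T
    return FeatureSequence(vectors=vectors, feature_kind="ff_lfbe", frame_times=spec.frame_times)
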