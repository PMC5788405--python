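"""Synthetic alarm soundscapes.

Real NICU recordings are proprietary, so every other module is exercised on
synthetic material that reproduces the *structure* of the corpus: periodic
alarms whose period is a tone (sum-of-sinusoids) signal interval followed by
silence, several device "versions" of a class with slightly shifted
frequencies and durations, up to four alarms overlapping, broadband
background noise, and a second ("inside the incubator") channel that is an
attenuated low-passed copy of the outside channel.

The default registry encodes the structural facts known about the seven alarm
classes studied (a1, a3, a6, a7, a8, a10, a16): all but a3 are simple
tone-silence alarms, a3 has consecutive tones, a16 shares its only frequency
with a1 and a8, a6 has a short period, and a1/a3/a7/a10 exist in more than
one version.  The frequency and duration *values* are synthetic fixtures
chosen in 300-4000 Hz (>= 100 Hz apart except the deliberate shared
frequency) and are fully overridable from a config file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.signal import butter, lfilter

from .spectral import compute_spectrogram, region_bins

log = logging.getLogger(__name__)

__all__ = [
    "Tone",
    "AlarmVersion",
    "AlarmClassSpec",
    "SceneEvent",
    "SceneSpec",
    "Scene",
    "CorpusExample",
    "default_registry",
    "registry_from_yaml",
    "registry_to_yaml",
    "synth_alarm",
    "render_scene",
    "synth_sinusoid_corpus",
    "synth_tone_in_noise",
]


@dataclass(frozen=True)
class Tone:
    """One stationary tone: simultaneous frequency components and a duration."""

    freqs: tuple[float, ...]
    duration: float  # seconds
    amplitude: float = 1.0


@dataclass(frozen=True)
class AlarmVersion:
    """One device version: consecutive tones followed by silence."""

    tones: tuple[Tone, ...]
    l_sil: float  # seconds

    @property
    def l_sig(self) -> float:
        return sum(t.duration for t in self.tones)

    @property
    def period(self) -> float:
        return self.l_sig + self.l_sil


@dataclass(frozen=True)
class AlarmClassSpec:
    """One alarm class: versions sharing tone count and overall structure."""

    class_id: str
    versions: tuple[AlarmVersion, ...]

    def __post_init__(self) -> None:
        if not self.versions:
            raise ValueError("alarm class needs at least one version")
        n_tones = {len(v.tones) for v in self.versions}
        if len(n_tones) != 1:
            raise ValueError("all versions must share the class's tone count")
        for v in self.versions:
            for t in v.tones:
                if any(f <= 0 for f in t.freqs):
                    raise ValueError("frequencies must be positive")

    @property
    def l_sig(self) -> float:
        return self.versions[0].l_sig

    @property
    def l_sil(self) -> float:
        return self.versions[0].l_sil

    @property
    def period(self) -> float:
        return self.versions[0].period

    @property
    def frequencies(self) -> tuple[float, ...]:
        """Sorted distinct alarm-specific frequencies (nominal version)."""
        freqs: set[float] = set()
        for t in self.versions[0].tones:
            freqs.update(t.freqs)
        return tuple(sorted(freqs))


def _versioned(tones: list[tuple[tuple[float, ...], float]], l_sil: float, n_versions: int):
    """Build versions; each extra version shifts frequencies +15 Hz and
    stretches durations +5% (still within the ±20 Hz detection tolerance)."""
    versions = []
    for v in range(n_versions):
        df = 15.0 * v
        stretch = 1.0 + 0.05 * v
        versions.append(
            AlarmVersion(
                tones=tuple(
                    Tone(freqs=tuple(f + df for f in fs), duration=d * stretch)
                    for fs, d in tones
                ),
                l_sil=l_sil * stretch,
            )
        )
    return tuple(versions)


#: the frequency deliberately shared by a1, a8 and a16
SHARED_FREQ = 960.0


def default_registry() -> list[AlarmClassSpec]:
    """Seven structurally faithful alarm classes with synthetic placeholder values."""
    return [
        AlarmClassSpec("a1", _versioned([((SHARED_FREQ, 1920.0), 0.20)], 0.80, 2)),
        AlarmClassSpec(
            "a3", _versioned([((560.0,), 0.15), ((760.0,), 0.15)], 0.50, 2)
        ),
        AlarmClassSpec("a6", _versioned([((2100.0,), 0.10)], 0.15, 1)),
        AlarmClassSpec("a7", _versioned([((1320.0, 2640.0), 0.25)], 0.75, 2)),
        AlarmClassSpec("a8", _versioned([((SHARED_FREQ, 1480.0), 0.30)], 0.70, 1)),
        AlarmClassSpec("a10", _versioned([((3200.0,), 0.40)], 0.60, 2)),
        AlarmClassSpec("a16", _versioned([((SHARED_FREQ,), 0.20)], 0.30, 1)),
    ]


def registry_to_yaml(registry: list[AlarmClassSpec], path: str | Path) -> None:
    data = {
        cls.class_id: [
            {
                "tones": [
                    {"freqs": list(t.freqs), "duration": t.duration, "amplitude": t.amplitude}
                    for t in v.tones
                ],
                "l_sil": v.l_sil,
            }
            for v in cls.versions
        ]
        for cls in registry
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def registry_from_yaml(path: str | Path) -> list[AlarmClassSpec]:
    data = yaml.safe_load(Path(path).read_text())
    registry = []
    for cid, versions in data.items():
        registry.append(
            AlarmClassSpec(
                class_id=cid,
                versions=tuple(
                    AlarmVersion(
                        tones=tuple(
                            Tone(
                                freqs=tuple(float(f) for f in t["freqs"]),
                                duration=float(t["duration"]),
                                amplitude=float(t.get("amplitude", 1.0)),
                            )
                            for t in v["tones"]
                        ),
                        l_sil=float(v["l_sil"]),
                    )
                    for v in versions
                ),
            )
        )
    return registry


def _ramp(n_samples: int, ramp_samples: int) -> np.ndarray:
    """Raised-cosine onset/offset envelope."""
    env = np.ones(n_samples)
    r = min(ramp_samples, n_samples // 2)
    if r > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(r) / r))
        env[:r] = ramp
        env[-r:] = ramp[::-1]
    return env


def synth_alarm(
    cls: AlarmClassSpec,
    version: int = 0,
    n_periods: int = 1,
    sample_rate: float = 24000.0,
    ramp_sec: float = 0.010,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesise ``n_periods`` of one alarm version.

    Each period concatenates the version's tones (equal-phase sums of
    sinusoids with 10 ms raised-cosine ramps) and silence.  Returns the
    waveform and the period-start times in seconds.
    """
    if n_periods < 1:
        raise ValueError("n_periods must be >= 1")
    if version >= len(cls.versions):
        raise ValueError(f"{cls.class_id} has no version {version}")
    v = cls.versions[version]
    nyquist = sample_rate / 2.0
    for t in v.tones:
        if any(f >= nyquist for f in t.freqs):
            raise ValueError("frequency out of band (>= Nyquist)")

    ramp_n = int(round(ramp_sec * sample_rate))
    pieces = []
    for tone in v.tones:
        n = int(round(tone.duration * sample_rate))
        t_ax = np.arange(n) / sample_rate
        wave = sum(np.sin(2.0 * np.pi * f * t_ax) for f in tone.freqs)
        wave *= tone.amplitude / max(len(tone.freqs), 1)
        pieces.append(wave * _ramp(n, ramp_n))
    pieces.append(np.zeros(int(round(v.l_sil * sample_rate))))
    one_period = np.concatenate(pieces)
    wave = np.tile(one_period, n_periods)
    onsets = np.arange(n_periods) * (len(one_period) / sample_rate)
    return wave, onsets


@dataclass(frozen=True)
class SceneEvent:
    class_id: str
    version: int
    start: float  # seconds
    n_periods: int
    snr_db: float  # target local SNR on the inside channel


@dataclass
class SceneSpec:
    duration: float
    events: list[SceneEvent]
    seed: int
    sample_rate: float = 24000.0
    background: str = "white"  # white | pink | mixture
    background_level: float = 0.05  # RMS of the outside-channel background
    inside_gain: float = 0.5
    inside_lowpass_hz: float = 2000.0


@dataclass
class Scene:
    """A rendered soundscape: two channels, annotations, reference events."""

    outside: np.ndarray
    inside: np.ndarray
    sample_rate: float
    annotations: pd.DataFrame  # onset_sec, offset_sec, class_id, version
    manifest: dict

    @property
    def duration(self) -> float:
        return len(self.outside) / self.sample_rate


def _background(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    n = int(round(spec.duration * spec.sample_rate))
    white = rng.standard_normal(n)
    if spec.background == "white":
        bg = white
    elif spec.background == "pink":
        # 1/f magnitude shaping in the frequency domain
        X = np.fft.rfft(white)
        f = np.fft.rfftfreq(n, 1.0 / spec.sample_rate)
        X[1:] /= np.sqrt(f[1:] / f[1])
        bg = np.fft.irfft(X, n)
    elif spec.background == "mixture":
        bg = white.copy()
        # frequent transient bursts (handling noise, clatter, movement) to
        # stress false-alarm behaviour; band-limited ones are spectrally
        # coloured and so are *not* cancelled by frequency-differencing
        # feature schemes, mimicking the non-stationary interference of a
        # real ward
        for _ in range(max(1, int(spec.duration * 1.5))):
            dur = int(rng.uniform(0.05, 0.3) * spec.sample_rate)
            pos = rng.integers(0, max(n - dur, 1))
            burst = rng.standard_normal(dur)
            if rng.random() < 0.8:  # band-limited burst
                center = rng.uniform(300.0, 6000.0)
                width = rng.uniform(150.0, 1500.0)
                lo = max(center - width / 2, 50.0)
                hi = min(center + width / 2, spec.sample_rate / 2 - 50.0)
                b, a = butter(2, [lo, hi], btype="band", fs=spec.sample_rate)
                burst = lfilter(b, a, burst)
                burst *= rng.uniform(4.0, 12.0) / max(np.sqrt(np.mean(burst**2)), 1e-12)
            else:  # broadband clatter
                burst *= rng.uniform(2.0, 6.0)
            burst *= np.hanning(dur)
            bg[pos : pos + dur] += burst
    else:
        raise ValueError(f"unknown background kind: {spec.background}")
    rms = np.sqrt(np.mean(bg**2))
    return bg * (spec.background_level / max(rms, 1e-300))


def _inside_transform(wave: np.ndarray, spec: SceneSpec) -> np.ndarray:
    b, a = butter(1, spec.inside_lowpass_hz / (spec.sample_rate / 2.0), btype="low")
    return lfilter(b, a, wave) * spec.inside_gain


def _band_power_per_bin(
    wave: np.ndarray, sample_rate: float, freqs, tolerance: float = 20.0
) -> float:
    """Mean per-bin power over the alarm-frequency bands of a waveform."""
    spec = compute_spectrogram(wave, sample_rate, "hann", 2048, 1024, 0)
    power = spec.magnitude**2
    vals = []
    for f in freqs:
        lo, hi = region_bins(f, tolerance, spec)
        vals.append(power[lo : hi + 1, :].mean())
    return float(np.mean(vals))


def _flank_power_per_bin(
    wave: np.ndarray, sample_rate: float, freqs, tolerance: float = 20.0, width: float = 100.0
) -> float:
    from .evaluate import _flank_bins

    spec = compute_spectrogram(wave, sample_rate, "hann", 2048, 1024, 0)
    power = spec.magnitude**2
    sig_bins: set[int] = set()
    for f in freqs:
        lo, hi = region_bins(f, tolerance, spec)
        sig_bins.update(range(lo, hi + 1))
    noise_bins = _flank_bins(spec, freqs, tolerance, width, guard=25.0) - sig_bins
    return float(power[sorted(noise_bins), :].mean())


def _band_power_total(
    wave: np.ndarray, sample_rate: float, freqs, tolerance: float = 20.0
) -> float:
    """Total (band-summed) per-frame power over the alarm-frequency bands."""
    spec = compute_spectrogram(wave, sample_rate, "hann", 2048, 1024, 0)
    power = spec.magnitude**2
    total = 0.0
    for f in freqs:
        lo, hi = region_bins(f, tolerance, spec)
        total += float(power[lo : hi + 1, :].mean(axis=1).sum())
    return total


def _flank_power_total(
    wave: np.ndarray, sample_rate: float, freqs, tolerance: float = 20.0, width: float = 100.0
) -> float:
    from .evaluate import _flank_bins

    spec = compute_spectrogram(wave, sample_rate, "hann", 2048, 1024, 0)
    power = spec.magnitude**2
    sig_bins: set[int] = set()
    for f in freqs:
        lo, hi = region_bins(f, tolerance, spec)
        sig_bins.update(range(lo, hi + 1))
    noise_bins = _flank_bins(spec, freqs, tolerance, width, guard=25.0) - sig_bins
    return float(power[sorted(noise_bins), :].mean(axis=1).sum())


def render_scene(spec: SceneSpec, registry: list[AlarmClassSpec]) -> Scene:
    """Mix alarms into background at per-event target local SNR.

    The alarm gain is calibrated component-wise on the inside channel: the
    alarm-only band power over its signal intervals is scaled to ``snr_db``
    decibels above the background's flanking-band power.  (The local SNR
    measured on the *mixture* additionally contains the in-band noise floor,
    so it reads ``10*log10(10^(t/10) + 1)`` — indistinguishable from the
    target above ~10 dB.)
    """
    if spec.background_level <= 0:
        raise ValueError("unsatisfiable SNR: zero background")
    by_id = {c.class_id: c for c in registry}
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.sample_rate))
    outside = _background(spec, rng)
    bg_inside = _inside_transform(outside, spec)

    rows = []
    measured = []
    for ev in spec.events:
        cls = by_id[ev.class_id]
        v = cls.versions[ev.version]
        wave, onsets = synth_alarm(cls, ev.version, ev.n_periods, spec.sample_rate)
        start_n = int(round(ev.start * spec.sample_rate))
        if start_n + len(wave) > n:
            raise ValueError(
                f"event {ev.class_id} at {ev.start}s exceeds the scene duration"
            )
        alarm_inside = _inside_transform(wave, spec)
        # calibrate on the signal intervals only (silence dilutes the estimate)
        sig_n = int(round(v.l_sig * spec.sample_rate))
        sig_samples = np.concatenate(
            [
                alarm_inside[int(round(o * spec.sample_rate)) : int(round(o * spec.sample_rate)) + sig_n]
                for o in onsets
            ]
        )
        bg_seg = bg_inside[start_n : start_n + len(wave)]
        p_alarm = _band_power_per_bin(sig_samples, spec.sample_rate, cls.frequencies)
        p_noise = _flank_power_per_bin(bg_seg, spec.sample_rate, cls.frequencies)
        gain = np.sqrt(10.0 ** (ev.snr_db / 10.0) * p_noise / max(p_alarm, 1e-300))
        outside[start_n : start_n + len(wave)] += gain * wave
        measured.append(
            {
                "class_id": ev.class_id,
                "target_snr_db": ev.snr_db,
                "gain": float(gain),
            }
        )
        for o in onsets:
            onset = ev.start + o
            rows.append(
                {
                    "onset_sec": onset,
                    "offset_sec": onset + v.l_sig,
                    "class_id": ev.class_id,
                    "version": ev.version,
                }
            )

    inside = _inside_transform(outside, spec)
    annotations = pd.DataFrame(
        rows, columns=["onset_sec", "offset_sec", "class_id", "version"]
    ).sort_values("onset_sec", kind="stable").reset_index(drop=True)
    manifest = {
        "seed": spec.seed,
        "duration": spec.duration,
        "sample_rate": spec.sample_rate,
        "background": spec.background,
        "events": measured,
    }
    return Scene(
        outside=outside,
        inside=inside,
        sample_rate=spec.sample_rate,
        annotations=annotations,
        manifest=manifest,
    )


@dataclass(frozen=True)
class CorpusExample:
    """One training segment: a noisy stationary sinusoid or noise only."""

    wave: np.ndarray
    is_sinusoid: bool
    freq: float  # 0.0 for noise-only examples
    snr_db: float


def synth_sinusoid_corpus(
    n_examples: int,
    snr_db: float = -7.0,
    sample_rate: float = 24000.0,
    seed: int = 0,
    noise_fraction: float = 0.5,
    n_frames: int = 8,
    frame_length: int = 2048,
    hop: int = 1024,
    freq_range: tuple[float, float] = (80.0, 11000.0),
    amp_range: tuple[float, float] = (0.1, 1.0),
    snr_reference: str = "per_example",
) -> list[CorpusExample]:
    """Training corpus for the peak models.

    Positive examples are stationary sinusoids with log-uniform random
    frequency and uniform random amplitude in broadband white noise; negatives
    are noise-only segments.  Every example is either positive or negative,
    never both.

    ``snr_reference`` controls what ``snr_db`` means:

    * ``"per_example"`` — the noise is scaled so every positive example's
      measured broadband SNR is exactly ``snr_db``;
    * ``"unit_amplitude"`` — the noise level is fixed at ``snr_db`` below a
      unit-amplitude sinusoid, so the amplitude randomisation produces a
      spread of effective SNRs (``snr_db + 20*log10(amp)``), covering weak
      peaks as well as strong ones.  This is the reference the peak-model
      training uses.
    """
    if n_examples < 1:
        raise ValueError("n_examples must be >= 1")
    if snr_reference not in ("per_example", "unit_amplitude"):
        raise ValueError(f"unknown snr_reference {snr_reference!r}")
    rng = np.random.default_rng(seed)
    n_noise = int(round(n_examples * noise_fraction))
    length = frame_length + n_frames * hop
    t_ax = np.arange(length) / sample_rate
    examples = []
    for i in range(n_examples):
        noise = rng.standard_normal(length)
        if i < n_noise:
            examples.append(
                CorpusExample(wave=noise, is_sinusoid=False, freq=0.0, snr_db=snr_db)
            )
            continue
        f = float(np.exp(rng.uniform(np.log(freq_range[0]), np.log(freq_range[1]))))
        amp = float(rng.uniform(*amp_range))
        phase = rng.uniform(0, 2 * np.pi)
        sin = amp * np.sin(2.0 * np.pi * f * t_ax + phase)
        if snr_reference == "per_example":
            p_ref = np.mean(sin**2)
        else:
            p_ref = 0.5  # power of the unit-amplitude sinusoid
        p_noise_target = p_ref / 10.0 ** (snr_db / 10.0)
        noise *= np.sqrt(p_noise_target / np.mean(noise**2))
        examples.append(
            CorpusExample(wave=sin + noise, is_sinusoid=True, freq=f, snr_db=snr_db)
        )
    return examples


def synth_tone_in_noise(
    local_snr_db: float,
    freq: float | None = None,
    sample_rate: float = 24000.0,
    seed: int = 0,
    noise_sec: float = 0.35,
    tone_sec: float = 0.45,
    tolerance: float = 20.0,
    freq_range: tuple[float, float] = (300.0, 8000.0),
) -> tuple[np.ndarray, tuple[float, float], float]:
    """A tone embedded in white noise at a target band-local SNR.

    Local SNR here is the classic band-power ratio: the tone's total power in
    its band (``freq ± tolerance``) against the noise's total power in the
    flanking 100 Hz bands.  The tone amplitude is calibrated component-wise so
    that this ratio equals ``local_snr_db``.  Returns the waveform, the
    (onset, offset) seconds of the tone, and the frequency.
    """
    rng = np.random.default_rng(seed)
    if freq is None:
        freq = float(np.exp(rng.uniform(np.log(freq_range[0]), np.log(freq_range[1]))))
    n_noise = int(round(noise_sec * sample_rate))
    n_tone = int(round(tone_sec * sample_rate))
    total = 2 * n_noise + n_tone
    noise = rng.standard_normal(total) * 0.05
    t_ax = np.arange(n_tone) / sample_rate
    tone = np.sin(2.0 * np.pi * freq * t_ax + rng.uniform(0, 2 * np.pi))
    tone *= _ramp(n_tone, int(0.01 * sample_rate))
    p_tone = _band_power_total(tone, sample_rate, [freq], tolerance)
    p_noise = _flank_power_total(noise, sample_rate, [freq], tolerance)
    gain = np.sqrt(10.0 ** (local_snr_db / 10.0) * p_noise / max(p_tone, 1e-300))
    wave = noise.copy()
    wave[n_noise : n_noise + n_tone] += gain * tone
    return wave, (noise_sec, noise_sec + tone_sec), freq
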