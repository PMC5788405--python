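"""Statistical sinusoid detection on spectral peaks.

Each local maximum of the short-time magnitude spectrum is a candidate
sinusoidal component, described by a feature vector ``y = (y1, y2)``:

* ``y1`` — the magnitude shape: ``|S_l(k_p + j)| / |S_l(k_p)|`` for
  ``j in [-M, M]`` (self-normalised, so the centre element is exactly 1);
* ``y2`` — the phase continuity: the inter-frame phase difference at those
  bins with the expected advance of a stationary sinusoid at the peak bin
  removed, ``wrap(phi_l(k) - phi_{l-1}(k) - 2*pi*k_p*hop/dft_size)``.

Two Gaussian mixture models are trained on a synthetic corpus — ``lambda_s``
on peaks of noisy stationary sinusoids, ``lambda_n`` on noise peaks — and a
peak is called sinusoidal when its log-likelihood under ``lambda_s`` exceeds
that under ``lambda_n``.  Detected peaks are linked over time into tracks,
and per-frame, per-alarm-frequency-region features (SD ratio / LLH /
LLH & Amp) are assembled for downstream classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.mixture import GaussianMixture

from .spectral import FeatureSequence, Spectrogram, compute_spectrogram, region_bins

log = logging.getLogger(__name__)

__all__ = [
    "PeakFeature",
    "PeakModels",
    "SinusoidTrack",
    "extract_peak_features",
    "train_peak_models",
    "score_peak",
    "score_peak_batch",
    "detect_sinusoid_tracks",
    "extract_sd_features",
    "save_peak_models",
    "load_peak_models",
]


def _wrap_phase(x: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return np.pi - np.mod(np.pi - x, 2.0 * np.pi)


@dataclass(frozen=True)
class PeakFeature:
    """One spectral peak: magnitude shape + phase continuity context."""

    k_p: int
    y1: np.ndarray  # length 2M+1, centre element == 1
    y2: np.ndarray  # length 2M+1, wrapped to (-pi, pi]
    frame_index: int

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.y1, self.y2])


@dataclass
class PeakModels:
    """Sinusoid (lambda_s) and noise (lambda_n) GMMs over peak features."""

    lambda_s: GaussianMixture
    lambda_n: GaussianMixture
    M: int
    training_snr_db: float

    @property
    def dim(self) -> int:
        return 2 * (2 * self.M + 1)


@dataclass
class SinusoidTrack:
    """A detected sinusoidal component: contiguous (frame, bin) trajectory."""

    frames: np.ndarray
    bins: np.ndarray
    mean_energy_db: float

    @property
    def onset(self) -> int:
        return int(self.frames[0])

    @property
    def offset(self) -> int:
        return int(self.frames[-1])

    @property
    def duration(self) -> int:
        return len(self.frames)


def _peak_mask(mag: np.ndarray) -> np.ndarray:
    """Strict-local-maximum mask over bins (axis 0); plateaus take the lowest bin."""
    mask = np.zeros_like(mag, dtype=bool)
    mask[1:-1] = (mag[1:-1] > mag[:-2]) & (mag[1:-1] >= mag[2:])
    return mask


def _gather_features(
    spec: Spectrogram, kp: np.ndarray, frames: np.ndarray, M: int
) -> np.ndarray:
    """Feature matrix (n_peaks, 2*(2M+1)) for peaks at (kp, frames); frames >= 1."""
    mag = spec.magnitude
    ph = spec.phase
    offs = np.arange(-M, M + 1)
    bins = kp[:, None] + offs[None, :]
    y1 = mag[bins, frames[:, None]] / mag[kp, frames][:, None]
    expected = 2.0 * np.pi * kp * spec.hop / spec.dft_size
    y2 = _wrap_phase(
        ph[bins, frames[:, None]] - ph[bins, frames[:, None] - 1] - expected[:, None]
    )
    return np.hstack([y1, y2])


def _frame_peaks(
    spec: Spectrogram, frame: int, M: int, lo: int = 0, hi: int | None = None
) -> np.ndarray:
    """Peak bin indices in one frame, restricted to [lo, hi] and the valid context."""
    mag = spec.magnitude[:, frame]
    if hi is None:
        hi = spec.n_bins - 1
    mask = np.zeros(spec.n_bins, dtype=bool)
    mask[1:-1] = (mag[1:-1] > mag[:-2]) & (mag[1:-1] >= mag[2:])
    kp = np.nonzero(mask)[0]
    kp = kp[(kp >= max(lo, M)) & (kp <= min(hi, spec.n_bins - 1 - M))]
    return kp[mag[kp] > 0]


def extract_peak_features(spec: Spectrogram, frame: int, M: int) -> list[PeakFeature]:
    """All peak features of one frame (needs the previous frame for ``y2``)."""
    if frame < 1:
        raise ValueError("no previous frame: peak features need frame >= 1")
    if M < 1:
        raise ValueError("context half-width M must be >= 1")
    kp = _frame_peaks(spec, frame, M)
    if len(kp) == 0:
        return []
    feats = _gather_features(spec, kp, np.full(len(kp), frame), M)
    n = 2 * M + 1
    return [
        PeakFeature(k_p=int(k), y1=f[:n], y2=f[n:], frame_index=frame)
        for k, f in zip(kp, feats)
    ]


def _all_peak_features(
    spec: Spectrogram, M: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised peak features for all frames >= 1.

    Returns (features, kp, frame_index) arrays.
    """
    mag = spec.magnitude
    mask = _peak_mask(mag)
    mask[:M] = False
    mask[mag.shape[0] - M :] = False
    mask[:, 0] = False  # no previous frame
    mask &= mag > 0
    kp, frames = np.nonzero(mask)
    if len(kp) == 0:
        return np.empty((0, 2 * (2 * M + 1))), kp, frames
    return _gather_features(spec, kp, frames, M), kp, frames


def train_peak_models(
    n_components: int = 32,
    M: int = 6,
    training_snr_db: float = -7.0,
    rng_seed: int = 0,
    n_sinusoid_examples: int = 800,
    n_noise_examples: int = 60,
    covariance_type: str = "diag",
    sample_rate: float = 24000.0,
    frame_length: int = 2048,
    hop: int = 1024,
    zero_pad: int = 2048,
    max_noise_features: int = 30000,
    amp_range: tuple[float, float] = (0.15, 1.0),
) -> PeakModels:
    """Fit the sinusoid/noise peak models on an internally synthesised corpus.

    Stationary random-frequency, random-amplitude sinusoids are mixed with
    white noise at ``training_snr_db`` (broadband); their spectral peaks
    nearest the true frequency are the positive examples, and all peaks of
    noise-only segments are the negatives.
    """
    from .synth import synth_sinusoid_corpus

    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    rng = np.random.default_rng(rng_seed)
    corpus = synth_sinusoid_corpus(
        n_examples=n_sinusoid_examples + n_noise_examples,
        snr_db=training_snr_db,
        sample_rate=sample_rate,
        seed=int(rng.integers(2**31 - 1)),
        noise_fraction=n_noise_examples / (n_sinusoid_examples + n_noise_examples),
        frame_length=frame_length,
        hop=hop,
        amp_range=amp_range,
        # noise fixed relative to the unit-amplitude sinusoid: the amplitude
        # randomisation then spans weak-to-strong peaks around training_snr_db
        snr_reference="unit_amplitude",
    )

    dft_size = frame_length + zero_pad
    pos_feats, neg_feats = [], []
    for ex in corpus:
        spec = compute_spectrogram(
            ex.wave, sample_rate, "rectangular", frame_length, hop, zero_pad
        )
        feats, kp, _ = _all_peak_features(spec, M)
        if len(kp) == 0:
            continue
        if ex.is_sinusoid:
            true_bin = round(ex.freq * dft_size / sample_rate)
            near = np.abs(kp - true_bin) <= 2
            if near.any():
                pos_feats.append(feats[near])
        else:
            neg_feats.append(feats)

    pos = np.vstack(pos_feats)
    neg = np.vstack(neg_feats)
    if len(neg) > max_noise_features:
        neg = neg[rng.choice(len(neg), max_noise_features, replace=False)]

    def _fit(data: np.ndarray, seed: int) -> GaussianMixture:
        gmm = GaussianMixture(
            n_components=n_components,
            covariance_type=covariance_type,
            reg_covar=1e-6,
            max_iter=200,
            tol=1e-4,
            random_state=seed,
        )
        gmm.fit(data)
        return gmm

    lambda_s = _fit(pos, int(rng.integers(2**31 - 1)))
    lambda_n = _fit(neg, int(rng.integers(2**31 - 1)))
    log.info(
        "trained peak models: %d sinusoid / %d noise features, %d components",
        len(pos), len(neg), n_components,
    )
    return PeakModels(lambda_s=lambda_s, lambda_n=lambda_n, M=M, training_snr_db=training_snr_db)


def score_peak_batch(features: np.ndarray, models: PeakModels) -> tuple[np.ndarray, np.ndarray]:
    """Log-densities (llh_s, llh_n) for a (n, dim) batch of peak feature vectors."""
    features = np.atleast_2d(features)
    if features.shape[1] != models.dim:
        raise ValueError(
            f"feature/model dimension mismatch: {features.shape[1]} vs {models.dim}"
        )
    if len(features) == 0:
        return np.empty(0), np.empty(0)
    return models.lambda_s.score_samples(features), models.lambda_n.score_samples(features)


def score_peak(pf: PeakFeature, models: PeakModels) -> tuple[float, float]:
    """Log-density of one peak under the sinusoid and the noise model."""
    s, n = score_peak_batch(pf.vector[None, :], models)
    return float(s[0]), float(n[0])


def detect_sinusoid_tracks(
    spec: Spectrogram,
    models: PeakModels,
    min_frames: int = 3,
    energy_floor_db: float = 40.0,
) -> list[SinusoidTrack]:
    """Detect sinusoidal components and link them over time.

    Peaks with ``llh_s > llh_n`` are marked sinusoidal; marks in consecutive
    frames are linked when their bin indices differ by at most 1.  Tracks
    shorter than ``min_frames`` and tracks whose mean energy lies more than
    ``energy_floor_db`` below the strongest track of the file are discarded.
    """
    if min_frames < 1:
        raise ValueError("min_frames must be >= 1")
    if spec.n_frames < 2:
        return []
    feats, kp, frames = _all_peak_features(spec, models.M)
    if len(kp) == 0:
        return []
    llh_s, llh_n = score_peak_batch(feats, models)
    sel = llh_s > llh_n
    kp, frames = kp[sel], frames[sel]

    # greedy frame-by-frame linking (bin drift <= 1)
    power = spec.magnitude**2
    open_tracks: list[tuple[list[int], list[int]]] = []  # (frames, bins)
    finished: list[tuple[list[int], list[int]]] = []
    order = np.argsort(frames, kind="stable")
    kp, frames = kp[order], frames[order]
    idx = 0
    for l in range(1, spec.n_frames):
        j = idx
        while j < len(frames) and frames[j] == l:
            j += 1
        bins_here = list(kp[idx:j])
        idx = j
        used = [False] * len(bins_here)
        still_open = []
        for trk_frames, trk_bins in open_tracks:
            if trk_frames[-1] != l - 1:
                finished.append((trk_frames, trk_bins))
                continue
            best, best_d = -1, 2
            for i, b in enumerate(bins_here):
                d = abs(b - trk_bins[-1])
                if not used[i] and d <= 1 and d < best_d:
                    best, best_d = i, d
            if best >= 0:
                used[best] = True
                trk_frames.append(l)
                trk_bins.append(bins_here[best])
                still_open.append((trk_frames, trk_bins))
            else:
                finished.append((trk_frames, trk_bins))
        for i, b in enumerate(bins_here):
            if not used[i]:
                still_open.append(([l], [int(b)]))
        open_tracks = still_open
    finished.extend(open_tracks)

    tracks = []
    for trk_frames, trk_bins in finished:
        if len(trk_frames) < min_frames:
            continue
        f = np.asarray(trk_frames)
        b = np.asarray(trk_bins)
        energy = float(np.mean(power[b, f]))
        tracks.append(
            SinusoidTrack(
                frames=f, bins=b, mean_energy_db=10.0 * np.log10(max(energy, 1e-300))
            )
        )
    if not tracks:
        return []
    max_e = max(t.mean_energy_db for t in tracks)
    return [t for t in tracks if t.mean_energy_db >= max_e - energy_floor_db]


def sinusoid_frame_decisions(
    spec: Spectrogram,
    models: PeakModels,
    center_freq: float,
    tolerance: float = 20.0,
    min_frames: int = 3,
    energy_floor_db: float = 40.0,
) -> np.ndarray:
    """Per-frame binary decision: does a detected sinusoid lie in the band?

    A frame is positive when a surviving sinusoid track passes through the
    ``center_freq ± tolerance`` region at that frame.  This is the frame-level
    detector benchmarked on synthetic tones.
    """
    lo, hi = region_bins(center_freq, tolerance, spec)
    covered = np.zeros(spec.n_frames, dtype=bool)
    for track in detect_sinusoid_tracks(spec, models, min_frames, energy_floor_db):
        in_band = (track.bins >= lo) & (track.bins <= hi)
        covered[track.frames[in_band]] = True
    return covered


def extract_sd_features(
    spec: Spectrogram,
    models: PeakModels,
    cls,
    mode: str = "llh_amp",
    tolerance: float = 20.0,
    floor_offset: float = 10.0,
) -> FeatureSequence:
    """Sinusoid-detection features over a class's alarm-frequency regions.

    Per frame and per alarm-specific frequency region (``f_b ± tolerance``),
    the spectral peak maximising ``llh_s`` is selected.  Modes:

    * ``ratio`` — ``llh_s - llh_n`` per region (dim ``N_f``);
    * ``llh`` — the pair ``(llh_s, llh_n)`` per region (dim ``2 N_f``);
    * ``llh_amp`` — the pairs plus per-region peak magnitudes normalised by
      their sum over regions, which removes overall alarm amplitude
      (dim ``3 N_f``).

    Regions with no peak receive a floor log-likelihood and the magnitude of
    the region's maximum bin.  The floor is the file's 1st-percentile
    log-likelihood minus ``floor_offset`` nats, and scored log-likelihoods are
    clipped from below at the same floor: occasional extreme outliers (a peak
    shape essentially impossible under one model) would otherwise dominate the
    downstream Gaussian fits and the period aggregation.
    """
    if mode not in ("ratio", "llh", "llh_amp"):
        raise ValueError(f"unknown SD feature mode: {mode}")
    freqs = cls.frequencies
    if len(freqs) < 1:
        raise ValueError("alarm class has no specific frequencies")
    regions = [region_bins(f, tolerance, spec) for f in freqs]
    n_f = len(regions)
    T = spec.n_frames
    mag = spec.magnitude

    # candidate peaks per region, all frames >= 1, scored in one batch
    cand_kp, cand_frame, cand_region = [], [], []
    for r, (lo, hi) in enumerate(regions):
        a = max(lo, 1, models.M)
        b = min(hi, spec.n_bins - 2, spec.n_bins - 1 - models.M)
        if a > b:
            continue
        sub = mag[a - 1 : b + 2, :]
        mask = (sub[1:-1] > sub[:-2]) & (sub[1:-1] >= sub[2:]) & (sub[1:-1] > 0)
        mask[:, 0] = False
        ks, ls = np.nonzero(mask)
        cand_kp.append(ks + a)
        cand_frame.append(ls)
        cand_region.append(np.full(len(ks), r))
    if cand_kp:
        kp = np.concatenate(cand_kp)
        frames = np.concatenate(cand_frame)
        regs = np.concatenate(cand_region)
        feats = _gather_features(spec, kp, frames, models.M)
        llh_s, llh_n = score_peak_batch(feats, models)
        floor = float(np.percentile(np.concatenate([llh_s, llh_n]), 1.0)) - floor_offset
        llh_s = np.maximum(llh_s, floor)
        llh_n = np.maximum(llh_n, floor)
    else:
        kp = frames = regs = np.empty(0, dtype=int)
        llh_s = llh_n = np.empty(0)
        floor = -100.0 - floor_offset

    # per (frame, region): peak maximising llh_s
    best_s = np.full((T, n_f), floor)
    best_n = np.full((T, n_f), floor)
    best_mag = np.zeros((T, n_f))
    for r, (lo, hi) in enumerate(regions):
        best_mag[:, r] = mag[lo : hi + 1, :].max(axis=0)
    if len(kp):
        order = np.lexsort((llh_s, regs, frames))  # best llh_s last per group
        f_o, r_o = frames[order], regs[order]
        last = np.ones(len(order), dtype=bool)
        last[:-1] = (f_o[1:] != f_o[:-1]) | (r_o[1:] != r_o[:-1])
        pick = order[last]
        best_s[frames[pick], regs[pick]] = llh_s[pick]
        best_n[frames[pick], regs[pick]] = llh_n[pick]
        best_mag[frames[pick], regs[pick]] = mag[kp[pick], frames[pick]]

    if mode == "ratio":
        vectors = best_s - best_n
    elif mode == "llh":
        vectors = np.empty((T, 2 * n_f))
        vectors[:, 0::2] = best_s
        vectors[:, 1::2] = best_n
    else:
        sums = best_mag.sum(axis=1, keepdims=True)
        norm = np.where(sums > 0, best_mag / np.maximum(sums, 1e-300), 1.0 / n_f)
        vectors = np.empty((T, 3 * n_f))
        vectors[:, 0::3] = best_s
        vectors[:, 1::3] = best_n
        vectors[:, 2::3] = norm
    return FeatureSequence(
        vectors=vectors, feature_kind=f"sd_{mode}", frame_times=spec.frame_times
    )


def save_peak_models(models: PeakModels, path: str | Path) -> None:
    """Serialise peak models (means, covariances, weights, metadata) to .npz."""
    np.savez(
        path,
        M=models.M,
        training_snr_db=models.training_snr_db,
        covariance_type=np.array(models.lambda_s.covariance_type),
        s_weights=models.lambda_s.weights_,
        s_means=models.lambda_s.means_,
        s_covariances=models.lambda_s.covariances_,
        n_weights=models.lambda_n.weights_,
        n_means=models.lambda_n.means_,
        n_covariances=models.lambda_n.covariances_,
    )


def _rebuild_gmm(weights, means, covariances, covariance_type: str) -> GaussianMixture:
    gmm = GaussianMixture(
        n_components=len(weights), covariance_type=covariance_type, reg_covar=1e-6
    )
    gmm.weights_ = weights
    gmm.means_ = means
    gmm.covariances_ = covariances
    from sklearn.mixture._gaussian_mixture import _compute_precision_cholesky

    gmm.precisions_cholesky_ = _compute_precision_cholesky(covariances, covariance_type)
    return gmm


def load_peak_models(path: str | Path) -> PeakModels:
    """Load peak models written by :func:`save_peak_models`."""
    data = np.load(path, allow_pickle=False)
    cov_type = str(data["covariance_type"])
    return PeakModels(
        lambda_s=_rebuild_gmm(data["s_weights"], data["s_means"], data["s_covariances"], cov_type),
        lambda_n=_rebuild_gmm(data["n_weights"], data["n_means"], data["n_covariances"], cov_type),
        M=int(data["M"]),
        training_snr_db=float(data["training_snr_db"]),
    )
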