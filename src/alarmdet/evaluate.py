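"""Frame-level and period-level evaluation.

Frame level: missing rate ``MR = N_M / N_A``, false-alarm rate
``FAR = N_FA / N_NA``, and detection-error-tradeoff (DET) curves with the
equal-error-rate point flagged.

Period level: the period-based error rate ``PB-ERR = 1 - F1`` over alarm-period
events, where a reference period is correct if a hypothesis falls within
``±T_tol`` frames of it; ``T_tol`` must stay below half the period so that no
two references can share one hypothesis.

Also provided: the local SNR of an annotated alarm interval (alarm-band power
against the flanking 100 Hz noise bands), SNR stratification utilities, and a
leave-one-session-out cross-validation harness that accumulates counts over
folds per class before computing rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .spectral import Spectrogram, region_bins
from .temporal import EventSet

log = logging.getLogger(__name__)

__all__ = [
    "FrameCounts",
    "PeriodCounts",
    "DetCurve",
    "frame_metrics",
    "det_curve",
    "pb_err",
    "plot_det_curve",
    "local_snr",
    "annotation_frames",
    "snr_bin_index",
    "stratify_by_snr",
    "cross_validate",
]

SNR_CAP_DB = 120.0


@dataclass(frozen=True)
class FrameCounts:
    n_alarm: int
    n_nonalarm: int
    n_miss: int
    n_false_alarm: int

    def __add__(self, other: "FrameCounts") -> "FrameCounts":
        return FrameCounts(
            self.n_alarm + other.n_alarm,
            self.n_nonalarm + other.n_nonalarm,
            self.n_miss + other.n_miss,
            self.n_false_alarm + other.n_false_alarm,
        )

    @property
    def miss_rate(self) -> float:
        return self.n_miss / self.n_alarm if self.n_alarm else float("nan")

    @property
    def false_alarm_rate(self) -> float:
        return self.n_false_alarm / self.n_nonalarm if self.n_nonalarm else float("nan")


@dataclass(frozen=True)
class PeriodCounts:
    n_correct: int
    n_miss: int
    n_false_alarm: int
    t_tol: int

    def __add__(self, other: "PeriodCounts") -> "PeriodCounts":
        return PeriodCounts(
            self.n_correct + other.n_correct,
            self.n_miss + other.n_miss,
            self.n_false_alarm + other.n_false_alarm,
            self.t_tol,
        )

    @property
    def pb_err(self) -> float:
        denom = 2 * self.n_correct + self.n_false_alarm + self.n_miss
        return 1.0 - 2.0 * self.n_correct / denom if denom else 0.0


@dataclass
class DetCurve:
    thresholds: np.ndarray
    miss_rate: np.ndarray
    false_alarm_rate: np.ndarray
    eer_index: int

    @property
    def eer(self) -> float:
        return 0.5 * (self.miss_rate[self.eer_index] + self.false_alarm_rate[self.eer_index])


def frame_metrics(ref: np.ndarray, hyp: np.ndarray) -> tuple[float, float, FrameCounts]:
    """Exact count-based MR and FAR; NaN when a class is absent."""
    ref = np.asarray(ref).astype(bool)
    hyp = np.asarray(hyp).astype(bool)
    if ref.shape != hyp.shape:
        raise ValueError("reference and hypothesis label lengths differ")
    counts = FrameCounts(
        n_alarm=int(ref.sum()),
        n_nonalarm=int((~ref).sum()),
        n_miss=int((ref & ~hyp).sum()),
        n_false_alarm=int((~ref & hyp).sum()),
    )
    return counts.miss_rate, counts.false_alarm_rate, counts


def det_curve(scores: np.ndarray, ref: np.ndarray) -> DetCurve:
    """One (threshold, MR, FAR) operating point per distinct score.

    Decision rule ``score >= threshold -> alarm``; MR is non-decreasing and
    FAR non-increasing along increasing thresholds.  The point closest to
    MR = FAR is flagged as the EER point.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(ref).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes required for a DET curve")
    thresholds = np.unique(scores)
    pos = np.sort(scores[y])
    neg = np.sort(scores[~y])
    mr = np.searchsorted(pos, thresholds, side="left") / len(pos)
    far = (len(neg) - np.searchsorted(neg, thresholds, side="left")) / len(neg)
    eer_index = int(np.argmin(np.abs(mr - far)))
    return DetCurve(thresholds=thresholds, miss_rate=mr, false_alarm_rate=far, eer_index=eer_index)


def plot_det_curve(curve: DetCurve, path, label: str = "") -> None:
    """Save a DET plot (MR vs FAR, log-log) with the EER point circled."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    far = np.maximum(curve.false_alarm_rate, 1e-4)
    mr = np.maximum(curve.miss_rate, 1e-4)
    ax.loglog(far, mr, label=label or None)
    ax.plot(far[curve.eer_index], mr[curve.eer_index], "o", fillstyle="none")
    ax.set_xlabel("false-alarm rate")
    ax.set_ylabel("miss rate")
    ax.grid(True, which="both", alpha=0.3)
    if label:
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def pb_err(
    ref: EventSet, hyp: EventSet, t_tol: int, period_frames: int
) -> tuple[float, PeriodCounts]:
    """Period-based error rate with one-to-one greedy chronological matching.

    References are scanned in order and each matched to the earliest unmatched
    hypothesis within ``±t_tol`` frames.  With ``t_tol < period_frames / 2``
    no hypothesis can serve two references.
    """
    if t_tol >= period_frames / 2:
        raise ValueError("tolerance violates half-period constraint")
    ref_ts = ref.timestamps
    hyp_ts = hyp.timestamps
    matched_hyp = np.zeros(len(hyp_ts), dtype=bool)
    n_correct = 0
    j = 0
    for t in ref_ts:
        while j < len(hyp_ts) and hyp_ts[j] < t - t_tol:
            j += 1
        k = j
        while k < len(hyp_ts) and hyp_ts[k] <= t + t_tol:
            if not matched_hyp[k]:
                matched_hyp[k] = True
                n_correct += 1
                break
            k += 1
    counts = PeriodCounts(
        n_correct=n_correct,
        n_miss=len(ref_ts) - n_correct,
        n_false_alarm=int((~matched_hyp).sum()),
        t_tol=int(t_tol),
    )
    return counts.pb_err, counts


def matched_offsets(ref: EventSet, hyp: EventSet, t_tol: int) -> np.ndarray:
    """Signed frame offsets (hyp - ref) of greedily matched event pairs."""
    offsets = []
    matched = np.zeros(len(hyp.timestamps), dtype=bool)
    for t in ref.timestamps:
        for k, h in enumerate(hyp.timestamps):
            if not matched[k] and abs(h - t) <= t_tol:
                matched[k] = True
                offsets.append(int(h - t))
                break
    return np.asarray(offsets, dtype=int)


def annotation_frames(
    onset_sec: float, offset_sec: float, sample_rate: float, hop: int
) -> tuple[int, int]:
    """Half-open frame range [l_on, l_off) covering an annotation interval."""
    l_on = int(round(onset_sec * sample_rate / hop))
    l_off = int(round(offset_sec * sample_rate / hop))
    return l_on, max(l_off, l_on + 1)


def local_snr(
    spec: Spectrogram,
    interval: tuple[float, float],
    cls,
    tolerance: float = 20.0,
    noise_width: float = 100.0,
    guard: float = 25.0,
) -> float:
    """Local SNR of one annotated alarm signal interval, in dB.

    Signal power: mean per-bin power over the class's alarm-frequency bands
    (``f_b ± tolerance``) across the interval's frames.  Noise power: mean
    per-bin power over the ``noise_width`` Hz bands flanking each signal band,
    excluding bins that belong to any signal band of the class.

    ``guard`` Hz separate each signal-band edge from its noise band: the
    analysis window's main lobe (about 23 Hz for a 2048-sample Hann frame at
    24 kHz) can spill the alarm's own energy past the ±tolerance margin, and
    counting that spill as noise would bias the SNR low for alarm versions
    whose frequency sits off the band centre.
    """
    l_on, l_off = annotation_frames(interval[0], interval[1], spec.sample_rate, spec.hop)
    l_on = max(l_on, 0)
    l_off = min(l_off, spec.n_frames)
    if l_off <= l_on:
        raise ValueError("interval outside the recording")
    power = spec.magnitude[:, l_on:l_off] ** 2

    sig_bins: set[int] = set()
    for f in cls.frequencies:
        lo, hi = region_bins(f, tolerance, spec)
        sig_bins.update(range(lo, hi + 1))
    noise_bins = _flank_bins(spec, cls.frequencies, tolerance, noise_width, guard)
    noise_bins -= sig_bins
    if not sig_bins or not noise_bins:
        raise ValueError("empty signal or noise bands")
    p_sig = float(power[sorted(sig_bins), :].mean())
    p_noise = float(power[sorted(noise_bins), :].mean())
    if p_noise <= 0:
        log.warning("zero noise power; SNR capped at %+.0f dB", SNR_CAP_DB)
        return SNR_CAP_DB
    return 10.0 * np.log10(max(p_sig, 1e-300) / p_noise)


def _flank_bins(
    spec: Spectrogram,
    freqs,
    tolerance: float,
    noise_width: float,
    guard: float,
) -> set[int]:
    """Bins of the noise bands flanking each signal band, beyond a guard."""
    noise_bins: set[int] = set()
    for f in freqs:
        lo_edge = f - tolerance - guard
        hi_edge = f + tolerance + guard
        n_lo, n_lo_hi = region_bins(
            max(lo_edge - noise_width / 2, spec.bin_hz), noise_width / 2, spec
        )
        n_hi_lo, n_hi = region_bins(
            min(hi_edge + noise_width / 2, spec.sample_rate / 2 - spec.bin_hz),
            noise_width / 2,
            spec,
        )
        noise_bins.update(range(n_lo, n_lo_hi + 1))
        noise_bins.update(range(n_hi_lo, n_hi + 1))
    return noise_bins


def snr_bin_index(snr_db: float, width: float = 5.0) -> int:
    """Index of the ``width``-dB interval containing ``snr_db``."""
    return int(np.floor(snr_db / width))


def stratify_by_snr(snr_values: np.ndarray, width: float = 5.0) -> dict[int, np.ndarray]:
    """Partition sample indices into ``width``-dB SNR bins (no overlap)."""
    snr_values = np.asarray(snr_values, dtype=float)
    bins = np.floor(snr_values / width).astype(int)
    return {b: np.nonzero(bins == b)[0] for b in np.unique(bins)}


def cross_validate(
    sessions: list,
    train_fn,
    eval_fn,
    class_ids: list[str],
) -> dict:
    """Leave-one-session-out cross-validation.

    ``train_fn(train_sessions) -> system`` and
    ``eval_fn(system, session) -> {class_id: (frame_counts, period_counts)}``.
    Counts are accumulated over folds per class before rates are computed; the
    overall score is the unweighted mean over classes.
    """
    if len(sessions) < 2:
        raise ValueError("need at least 2 sessions for cross-validation")
    frame_acc: dict[str, FrameCounts] = {}
    period_acc: dict[str, PeriodCounts] = {}
    fold_results = []
    for i, test_session in enumerate(sessions):
        train_sessions = [s for j, s in enumerate(sessions) if j != i]
        system = train_fn(train_sessions)
        per_class = eval_fn(system, test_session)
        fold_results.append(per_class)
        for cid, (fc, pc) in per_class.items():
            frame_acc[cid] = frame_acc[cid] + fc if cid in frame_acc else fc
            period_acc[cid] = period_acc[cid] + pc if cid in period_acc else pc
    missing = [cid for cid in class_ids if cid not in frame_acc]
    for cid in missing:
        log.warning("class %s absent from all folds; skipped", cid)
    present = [cid for cid in class_ids if cid in frame_acc]
    per_class = {
        cid: {
            "miss_rate": frame_acc[cid].miss_rate,
            "false_alarm_rate": frame_acc[cid].false_alarm_rate,
            "pb_err": period_acc[cid].pb_err,
            "frame_counts": frame_acc[cid],
            "period_counts": period_acc[cid],
        }
        for cid in present
    }
    overall = {
        key: float(np.nanmean([per_class[cid][key] for cid in present]))
        for key in ("miss_rate", "false_alarm_rate", "pb_err")
    }
    return {"per_class": per_class, "overall": overall, "folds": fold_results}
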